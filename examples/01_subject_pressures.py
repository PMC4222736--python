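"""Load the packaged subject and walk the cuff-to-ventricle pressure chain.

Builds aortic and peak-ventricular pressures from example brachial cuff
readings, then shows the packaged exercise series those transforms feed.
"""
import mplv

# a typical resting cuff reading
aortic_sys, aortic_dia = mplv.brachial_to_aortic(120.0, 80.0)
vsp = mplv.aortic_to_ventricular_systolic(aortic_sys)
print(f"cuff 120/80 mmHg -> aortic {aortic_sys:.2f}/{aortic_dia:.2f} mmHg "
      f"-> peak ventricular systolic {vsp:.2f} mmHg")
# the +2.25 / -5.45 corrections map oscillometric cuff pressures onto the
# invasive aortic scale; the ventricle peaks ~5 mmHg above the aorta.

series = mplv.load_fixture("subject")
print(f"\npackaged subject: {len(series)} exercise stages, "
      f"{series.heart_rates[0]:.0f}-{series.heart_rates[-1]:.0f} bpm")
for rec in series:
    print(f"  HR {rec.heart_rate:5.0f} bpm  VSP {rec.ventricular_systolic:5.0f} "
          f"ADP {rec.aortic_diastolic:4.0f} mmHg  "
          f"Doppler CO {rec.doppler_co:6.0f} ml/min")
# ventricular systolic pressure rises monotonically with exercise while
# aortic diastolic pressure dips mid-exercise and recovers (U-shape).
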