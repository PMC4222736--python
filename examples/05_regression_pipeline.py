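"""Full regression chain: fits, inter-method transforms, exercise summary."""
import mplv

series = mplv.load_fixture("subject")
fits = mplv.fit_series(series)

for key, fit in fits.items():
    print(f"{fit.output_name:>12}({fit.input_name}): "
          f"c2={fit.c2:.4g} c1={fit.c1:.4g} c0={fit.c0:.4g} "
          f"R^2={fit.r_squared:.4f}")
# the three re-estimated quadratics: both pressures versus model-predicted
# cardiac output, and Doppler cardiac output versus heart rate.

print(f"\nDoppler vs model CO correlation: "
      f"r = {mplv.doppler_numerical_correlation(series):.3f}")

summary = mplv.exercise_summary(series, fits)
print()
print(mplv.format_summary(summary))
# Doppler rows use measured pressures at the 98 and 169 bpm stages; the
# invasive-method rows evaluate the fitted pressure curves at the
# Christie-transformed Doppler cardiac output of those same stages.
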