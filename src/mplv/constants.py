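"""Physical constants and clinical transform defaults.

All clinical quantities are carried in the units used at the bedside
(mmHg, ml/min, bpm, s); the ejection model converts to SI internally.
"""

#: Pressure unit conversion (1 mmHg in Pa).
MMHG_TO_PA: float = 133.322

#: Offset added to aortic systolic pressure to obtain the peak left
#: ventricular systolic pressure (mmHg). Catheterization studies place the
#: systolic ventricular-aortic difference at about this value in healthy
#: subjects.
VENTRICULAR_OFFSET_MMHG: float = 5.0

#: Oscillometric brachial -> invasive aortic pressure corrections (mmHg).
BRACHIAL_TO_AORTIC_SYSTOLIC_MMHG: float = 2.25
BRACHIAL_TO_AORTIC_DIASTOLIC_MMHG: float = -5.45

#: Blood treated as incompressible and Newtonian.
BLOOD_DENSITY_KG_M3: float = 1056.0
BLOOD_VISCOSITY_PA_S: float = 3.5e-3

#: Linear systolic ejection-period model ET(s) = intercept + slope * HR(bpm),
#: clamped to a physiological window. Used whenever a record carries no
#: measured ejection time.
EJECTION_TIME_INTERCEPT_S: float = 0.413
EJECTION_TIME_SLOPE_S_PER_BPM: float = -0.0017
EJECTION_TIME_CLAMP_S: tuple[float, float] = (0.15, 0.40)
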