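# Methods

## Problem setting

Peak left-ventricular pressure varies with heart rate, but measuring it
requires catheterization, which is risky and impractical during exercise.
The package estimates it indirectly for one subject at a time: cardiac
output is measurable non-invasively at every exercise stage (Doppler
echocardiography), an ejection model ties cardiac output to the pressure
loads that produced it, and regression closes the loop so that pressure can
be read off as a function of heart rate for several cardiac-output
measurement conventions.

All clinical quantities are carried in bedside units (mmHg, ml/min, bpm,
s); the ejection model converts to SI internally (1 mmHg = 133.322 Pa).

## Pressure transforms

Cuff (oscillometric brachial) pressures are mapped to the aortic scale by
fixed affine corrections, +2.25 mmHg systolic and −5.45 mmHg diastolic,
taken from published cuff-versus-catheter comparisons. Peak ventricular
systolic pressure sits a constant offset above aortic systolic pressure;
the default is 5 mmHg (catheterization studies in healthy subjects place
the systolic ventricular–aortic difference around this value) and it is a
named, overridable constant. Both transforms are affine and strictly
monotone, which the tests assert as a property.

## Doppler chain

Standard stress-echo arithmetic: the velocity–time integral is a
trapezoidal integral of the sampled outflow envelope on its own grid (no
resampling; error is quadratic in the sampling step and tested by
refinement), the aortic cross-section is π(D/2)² with D the ascending
aortic diameter above the sinotubular junction, stroke volume is their
product and cardiac output is stroke volume times heart rate. The packaged
subject's annulus radius (11.5 mm) gives A = 4.155 cm².

## Valve geometry

Echo measures scalars, not surfaces: annulus radius, commissure radius,
sinus height, the sinus-of-Valsalva bulge (maximum radius and its axial
location) and leaflet dimensions. The sinus wall is reconstructed as a
surface of revolution of a monotone piecewise-cubic (PCHIP) interpolant
through the three measured radii — C¹, no overshoot, maximum exactly at
the bulge location. Tri-leaflet symmetry reduces the root to a 60° wedge;
meshes are structured revolution grids exportable as STL/OFF for
inspection. Leaflet surfaces are deliberately not reconstructed (no
free-edge curve is measured; any reconstruction would be conjecture), and
the leaflet dimensions plus the elastic constants (Young's modulus
6.885 MPa, Poisson ratio 0.4999) are validated metadata only. The single
geometric quantity consumed downstream is the annulus area, used as the
valve's maximum effective orifice area.

## Reduced-order ejection model

A full 3-D moving-mesh fluid–structure simulation of valve opening is far
too expensive for a per-stage pipeline (hours per solve). The package
replaces it with a two-state lumped model that preserves the
pressure-in/flow-out contract, with fidelity defined operationally:
reproduce the subject's model-predicted cardiac-output column within 5%
per record.

State variables: opening fraction ζ ∈ [0, 1] and transvalvular flow Q.
With ΔP = p_lv − p_ao in Pa:

    dζ/dt = k_open ΔP (1 − ζ)        if ΔP ≥ 0
    dζ/dt = k_close ΔP ζ             if ΔP < 0
    A(ζ)  = A_min + (A_max − A_min) ζ
    ρ l_eff / A(ζ) · dQ/dt + ρ/(2 A(ζ)²) · Q|Q| = ΔP

The steady limit is the Bernoulli orifice law Q = A√(2ΔP/ρ), which the
tests check in closed form. Integration is classic fixed-step RK4; the
step must resolve the ejection (dt ≤ T/200, default T/400), ζ is clipped
to [0, 1] against floating-point drift, halving dt moves cardiac output by
well under 0.1%, and a non-finite state aborts with the time reached.
Stroke volume integrates forward flow only (ejected volume); reverse flow
is representable but never occurs under the default loading.

Parameters and defaults: A_max = annulus area (4.155 cm²), blood density
1056 kg/m³, leakage fraction A_min/A_max ∈ (0, 0.05], opening rate k_open
and inertance length l_eff calibrated per subject, closing rate k_close
carried at 0.05 /(Pa·s).

**Boundary waveforms.** The true per-stage load curves are not measured,
so a stated convention is used: over the ejection time T both pressures
start and end at the aortic diastolic value; ventricular pressure is a
half-sine peaking at the stage's systolic value, and the aortic waveform
carries a reduced pulse — fraction 0.35 of the ventricular pulse, a config
knob. The gradient is then non-negative throughout ejection, which has one
structural consequence: the closing law never acts, so k_close is
unidentifiable from cardiac-output data and is excluded from calibration.

**Ejection time.** When unmeasured, ET follows the standard linear
systolic-ejection-period regression ET = 0.413 − 0.0017·HR (s), clamped to
[0.15, 0.40] s; a per-record CSV column overrides it.

**Calibration.** Bounded least squares on the relative cardiac-output
residuals, over log-scaled (k_open, l_eff, A_min fraction), with an
8-start seeded multistart (default seed 1729) for determinism. The generic
ejection-time line cannot reproduce the subject's flat stroke-volume
profile: under the half-sine convention the driving gradient scales with
pulse pressure, which grows only ~40% from rest to peak exercise while the
generic ET shrinks ~40%, so every admissible parameter set yields stroke
volume falling with heart rate and residuals near ±25%. Since the
subject's actual ejection times were measured but not recorded in the
packaged table, the calibration therefore also fits a subject-specific ET
line (intercept and slope, bounded to a physiological window and still
clamped) by default. With it, the fit reaches a maximum residual of 1.9%
and the fitted ET range (0.150–0.179 s over 98–169 bpm) remains
physiological for exercise. Noise-free self-consistency holds: calibrating
against surrogate-generated data recovers the generating parameters to
well under 2%. The frozen result is available as
`packaged_calibration()`; all tests recompute it.

## Regression chain

`fit_quadratic` is ordinary least squares on the Vandermonde basis with
R² = 1 − SS_res/SS_tot, requiring ≥ 4 points and a full-rank design.
Printed regression coefficients from the source tables are never
transcribed into the code — typeset sign errors would otherwise propagate
(e.g. a linear term whose printed sign implies negative cardiac output at
rest) — every fit is re-estimated from the packaged data and validated
against the published R² values instead. Pressure quadratics regress on
the model-predicted cardiac-output column; when a series lacks that
column, the calibrated ejection model supplies it (`co_source`
switch). The Doppler-CO-versus-heart-rate quadratic regresses the measured
Doppler column on heart rate.

The Christie inter-method transforms are positive-slope affine maps, so
composing them with a quadratic fit is coefficient-wise and leaves R²
exactly unchanged (asserted at machine precision under randomized maps).
Evaluation outside a fit's input range is flagged with a warning, not
forbidden — the transforms intentionally reach slightly past the fitted
CO range at the endpoint records.

**Exercise summary conventions.** Doppler rows use measured pressures at
the lowest- and highest-heart-rate records; Fick and thermodilution rows
evaluate the fitted VSP(CO)/ADP(CO) quadratics at the Christie-transformed
*measured* Doppler CO of those same two records. This convention — rather
than evaluating composed CO(Hr) curves at the endpoint heart rates — is
what reproduces the reference increments. Percent changes are relative to
the low-heart-rate value; gradients are endpoint difference quotients, not
regression slopes (for this subject the VSP-on-HR regression slope is
≈ 0.46 mmHg/bpm while the endpoint quotient 34/71 = 0.479 matches the
reported 0.48). Report rounding is centralized: integer percents (one
decimal where conventionally reported so), two-decimal gradients.

The Doppler ADP summary is honest but near-degenerate: the measured
diastolic pressure is U-shaped and returns to its resting value at peak
exercise, so the endpoint change is 0 mmHg. Reference accounts quoting a
small positive Doppler ADP rise are not reproducible from the packaged
data under any convention tried; the value is reported as computed.

## Synthetic generator

Emulates the subject-series structure: evenly spaced heart rates over
95–170 bpm, Doppler CO as a concave quadratic of heart rate (defaults
bracket 11–19 L/min), VSP monotone rising and ADP U-shaped as quadratics
of the noise-free CO (150–190 mmHg and mid-60s mmHg respectively), i.i.d.
Gaussian noise on the observed columns (defaults: 150 ml/min on CO, 1 mmHg
on pressures — the scale of Doppler and cuff measurement error), and the
noise-free CO standing in for the model-predicted column. A single seeded
stream makes every draw bit-reproducible; the seed is recorded in the
series metadata.

What it does *not* emulate: correlated (drift-like) measurement error,
beat-to-beat variability, arrhythmia, or any closed-loop circulatory
feedback between pressure and flow. Passing recovery tests therefore shows
the pipeline is correct and stable under the stated noise model, not that
it is robust to every failure mode of real stress-echo data.

## Problem sizes and numerical choices

The packaged subject series has 9 stages; quadratic fits and summaries are
exact-arithmetic-scale computations. Ejection simulations use 400 RK4
steps per ejection (800 for convergence checks); calibration evaluates
batches of 9 ejections vectorized, 8 multistarts. The
coefficient-recovery statistics use 200 generator seeds with the default
noise, asserting a sub-10% median relative coefficient error and ≥ 90% of
draws within 3 percentage points on the summary percent change.

## Known limitations

- Single-subject method: no population statistics, no uncertainty
  intervals on the Christie transforms (their 15-subject raw data is not
  available).
- The half-sine load convention and the 0.35 aortic pulse fraction are
  stated conventions, not measurements; the calibrated valve parameters
  absorb their arbitrariness and should not be interpreted biophysically.
- No leaflet mechanics: elastic constants are carried but unused, leaflet
  surfaces are not meshed, and stress/strain fields are out of scope.
- The Fick ADP percent change computed by the chain (≈ 15.6%) is
  internally consistent with its own 9.9 mmHg absolute change, but
  reference accounts pair that absolute change with a higher percent;
  the package reports the self-consistent value.
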