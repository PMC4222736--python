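"""Synthetic subject generator.

Emulates the statistical structure of a single-subject exercise series: a
smooth concave Doppler cardiac-output-versus-heart-rate relation, a
monotonically rising ventricular systolic pressure and a U-shaped aortic
diastolic pressure, each expressed as a quadratic of cardiac output, with
i.i.d. Gaussian measurement noise on the observed columns. The noise-free
cardiac output stands in for the model-predicted (numerical) column, so
generated series exercise the full regression pipeline and support
parameter-recovery tests without any external data.

Default truth coefficients bracket the packaged subject (heart rate 95-170
bpm, cardiac output roughly 11-19 L/min, ventricular systolic pressure
150-190 mmHg, U-shaped diastolic pressure in the 60s of mmHg).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .clinical_io import SubjectRecord, SubjectSeries
from .constants import EJECTION_TIME_INTERCEPT_S, EJECTION_TIME_SLOPE_S_PER_BPM
from .errors import DomainError, ValidationError
from .hemodynamics import VelocityTrace


@dataclass(frozen=True)
class SynthConfig:
    """Ground truth and noise model for a synthetic subject series."""

    seed: int = 1729
    n_records: int = 9
    hr_range: tuple[float, float] = (95.0, 170.0)
    #: Doppler CO (ml/min) vs heart rate (bpm); concave, c2 < 0.
    true_cod_coeffs: tuple[float, float, float] = (-0.7534, 300.73, -10714.0)
    #: VSP (mmHg) vs CO (ml/min); monotone rising over the generated range.
    true_vsp_coeffs: tuple[float, float, float] = (-4.497e-9, 3.868e-3, 110.56)
    #: ADP (mmHg) vs CO (ml/min); U-shaped over the generated range.
    true_adp_coeffs: tuple[float, float, float] = (2.560e-7, -7.788e-3, 122.32)
    noise_sd_co: float = 150.0  # ml/min
    noise_sd_pressure: float = 1.0  # mmHg
    ejection_time_model: tuple[float, float] = (
        EJECTION_TIME_INTERCEPT_S,
        EJECTION_TIME_SLOPE_S_PER_BPM,
    )

    def __post_init__(self) -> None:
        if self.n_records < 4:
            raise ValidationError("n_records must be >= 4")
        if self.noise_sd_co < 0 or self.noise_sd_pressure < 0:
            raise ValidationError("noise standard deviations must be >= 0")
        if not self.hr_range[1] > self.hr_range[0] > 0:
            raise ValidationError("hr_range must be an increasing positive interval")
        if not self.true_cod_coeffs[0] < 0:
            raise ValidationError("true CO-vs-HR relation must be concave (c2 < 0)")


def _quad(coeffs, x):
    c2, c1, c0 = coeffs
    return c2 * x * x + c1 * x + c0


def generate_series(config: SynthConfig) -> tuple[SubjectSeries, dict]:
    """Draw one synthetic subject series plus its ground truth.

    Heart rates are evenly spaced over ``hr_range``. Doppler CO is the true
    quadratic plus Gaussian noise; pressures are the true quadratics of the
    *noise-free* CO plus Gaussian noise; the numerical CO column carries the
    noise-free CO. Reproducible for a fixed seed (single stream, recorded in
    the series notes).
    """
    rng = np.random.default_rng(config.seed)
    hr = np.linspace(config.hr_range[0], config.hr_range[1], config.n_records)
    co_true = _quad(config.true_cod_coeffs, hr)
    if np.any(co_true <= 0):
        raise DomainError(
            "configured CO-vs-HR relation produces non-positive cardiac output"
        )
    cod = co_true + rng.normal(0.0, config.noise_sd_co, config.n_records)
    vsp = _quad(config.true_vsp_coeffs, co_true) + rng.normal(
        0.0, config.noise_sd_pressure, config.n_records
    )
    adp = _quad(config.true_adp_coeffs, co_true) + rng.normal(
        0.0, config.noise_sd_pressure, config.n_records
    )
    et = config.ejection_time_model[0] + config.ejection_time_model[1] * hr
    records = tuple(
        SubjectRecord(
            heart_rate=float(hr[i]),
            aortic_diastolic=float(adp[i]),
            ventricular_systolic=float(vsp[i]),
            doppler_co=float(cod[i]),
            numerical_co=float(co_true[i]),
            ejection_time=float(np.clip(et[i], 0.15, 0.40)),
        )
        for i in range(config.n_records)
    )
    truth = {
        "cod_coeffs": config.true_cod_coeffs,
        "vsp_coeffs": config.true_vsp_coeffs,
        "adp_coeffs": config.true_adp_coeffs,
        "co_true": co_true,
        "heart_rates": hr,
    }
    series = SubjectSeries(
        records,
        subject_id=f"synthetic-{config.seed}",
        notes=f"synthetic series, seed={config.seed}",
    )
    return series, truth


def generate_velocity_trace(
    peak: float,
    ejection_time: float,
    shape: str = "halfsine",
    n_samples: int = 256,
) -> VelocityTrace:
    """Deterministic sampled ejection-velocity waveform.

    ``halfsine`` is the textbook systolic envelope peak*sin(pi t/T);
    ``triangle`` ramps linearly to the peak at mid-ejection and back. The
    mid-ejection instant is always included so the sampled peak is exact.
    """
    if not (peak > 0 and ejection_time > 0):
        raise DomainError("peak and ejection_time must be positive")
    if n_samples < 16:
        raise DomainError("need at least 16 samples")
    times = np.union1d(
        np.linspace(0.0, ejection_time, n_samples), [ejection_time / 2.0]
    )
    if shape == "halfsine":
        velocities = peak * np.sin(np.pi * times / ejection_time)
    elif shape == "triangle":
        velocities = np.interp(
            times,
            [0.0, ejection_time / 2.0, ejection_time],
            [0.0, peak, 0.0],
        )
    else:
        raise DomainError(f"unknown waveform shape {shape!r}")
    return VelocityTrace(times=times, velocities=velocities)
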