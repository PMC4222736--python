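"""Pressure-flow regression chain and exercise summary statistics.

Three quadratic least-squares fits tie the system together: ventricular
systolic pressure VSP and aortic diastolic pressure ADP as functions of the
model-predicted cardiac output, and Doppler cardiac output COD as a
function of heart rate. Published inter-method regressions (Christie et
al., 15 subjects) map Doppler cardiac output onto the invasive conventions,

    COT = 1.41 COD - 2394     (thermodilution, ml/min)
    COF = 1.03 COD + 2165     (Fick oximetric, ml/min)

and composing them with the COD(HR) fit yields per-method cardiac-output
and pressure curves versus heart rate. All coefficients are re-estimated
from the data at run time -- never transcribed from typeset equations,
whose signs are not reliable -- and validated against the published
goodness-of-fit instead.

The exercise summary reports, per method and pressure, the absolute and
percent change between the lowest and highest recorded heart rates and the
endpoint gradient (difference quotient, mmHg per bpm). Doppler entries use
the measured pressures directly; Fick and thermodilution entries evaluate
the fitted pressure-CO quadratics at the transformed measured Doppler
cardiac output of the same two endpoint records.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .clinical_io import SubjectSeries
from .errors import DomainError, ValidationError


class ExtrapolationWarning(UserWarning):
    """A fit was evaluated outside the range it was estimated on."""


@dataclass(frozen=True)
class QuadraticFit:
    """Degree-2 least-squares fit y = c2 x^2 + c1 x + c0."""

    c2: float
    c1: float
    c0: float
    r_squared: float
    input_name: str = "x"
    output_name: str = "y"
    input_range: tuple[float, float] = (-np.inf, np.inf)

    @property
    def coefficients(self) -> tuple[float, float, float]:
        return (self.c2, self.c1, self.c0)

    def __call__(self, x):
        """Evaluate the fit; warns when x leaves the fitted input range."""
        x_arr = np.asarray(x, dtype=float)
        lo, hi = self.input_range
        if np.any(x_arr < lo) or np.any(x_arr > hi):
            warnings.warn(
                f"evaluating {self.output_name}({self.input_name}) outside the "
                f"fitted range [{lo:g}, {hi:g}]",
                ExtrapolationWarning,
                stacklevel=2,
            )
        out = self.c2 * x_arr**2 + self.c1 * x_arr + self.c0
        return float(out) if np.isscalar(x) else out


@dataclass(frozen=True)
class LinearMap:
    """Inter-method cardiac-output transform CO' = slope * COD + intercept."""

    slope: float
    intercept: float  # ml/min
    method_name: str

    def __post_init__(self) -> None:
        if not self.slope > 0:
            raise ValidationError("slope must be positive")

    def __call__(self, cod: float) -> float:
        return christie_transform(cod, self)


#: Published Doppler -> invasive-method transforms (ml/min).
THERMODILUTION_MAP = LinearMap(1.41, -2394.0, "thermodilution")
FICK_MAP = LinearMap(1.03, 2165.0, "fick")
DOPPLER_IDENTITY = LinearMap(1.0, 0.0, "doppler")

DEFAULT_MAPS: Mapping[str, LinearMap] = {
    "doppler": DOPPLER_IDENTITY,
    "fick": FICK_MAP,
    "thermodilution": THERMODILUTION_MAP,
}


def fit_quadratic(
    x: Sequence[float],
    y: Sequence[float],
    input_name: str = "x",
    output_name: str = "y",
) -> QuadraticFit:
    """Ordinary least-squares degree-2 polynomial fit with R^2.

    Requires at least 4 points (one residual degree of freedom) and a
    non-degenerate abscissa.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise DomainError("x and y must have equal length")
    if x.size < 4:
        raise DomainError(f"quadratic fit needs >= 4 points, got {x.size}")
    if np.ptp(x) == 0 or np.linalg.matrix_rank(np.vander(x, 3)) < 3:
        raise DomainError("design matrix is rank deficient (x values degenerate)")
    c2, c1, c0 = np.polyfit(x, y, 2)
    resid = y - (c2 * x**2 + c1 * x + c0)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r_squared = 1.0 - float(np.sum(resid**2)) / ss_tot
    return QuadraticFit(
        c2=float(c2),
        c1=float(c1),
        c0=float(c0),
        r_squared=r_squared,
        input_name=input_name,
        output_name=output_name,
        input_range=(float(x.min()), float(x.max())),
    )


def christie_transform(cod: float, linear_map: LinearMap) -> float:
    """Map a Doppler cardiac output (ml/min) onto another method's scale."""
    if not cod > 0:
        raise DomainError("Doppler cardiac output must be positive")
    out = linear_map.slope * cod + linear_map.intercept
    if out <= 0:
        raise DomainError(
            f"{linear_map.method_name} transform left its validity range "
            f"(CO {out:.0f} ml/min <= 0 at COD {cod:.0f})"
        )
    return out


def compose_co_vs_hr(cod_fit: QuadraticFit, linear_map: LinearMap) -> QuadraticFit:
    """Per-method CO(HR) curve: linear map applied to the Doppler CO fit.

    Affine maps commute with the polynomial coefficients, and a positive
    linear map leaves R^2 unchanged, so the composed fit inherits the
    Doppler fit's goodness of fit exactly.
    """
    return QuadraticFit(
        c2=linear_map.slope * cod_fit.c2,
        c1=linear_map.slope * cod_fit.c1,
        c0=linear_map.slope * cod_fit.c0 + linear_map.intercept,
        r_squared=cod_fit.r_squared,
        input_name=cod_fit.input_name,
        output_name=f"co_{linear_map.method_name}",
        input_range=cod_fit.input_range,
    )


def predict_pressure_curve(
    pressure_fit: QuadraticFit,
    method_co_vs_hr: QuadraticFit,
    hr_grid: Sequence[float],
) -> np.ndarray:
    """Pressure (mmHg) versus heart rate through the fitted chain.

    Evaluates pressure_fit(method_co_vs_hr(hr)) pointwise; extrapolation
    beyond either fitted range is flagged by a warning, not forbidden.
    """
    hr_grid = np.asarray(hr_grid, dtype=float)
    if hr_grid.size == 0:
        raise DomainError("heart-rate grid is empty")
    return pressure_fit(method_co_vs_hr(hr_grid))


def fit_series(
    series: SubjectSeries,
    co_source: str = "numerical",
    surrogate_params=None,
) -> dict[str, QuadraticFit]:
    """Estimate the three core fits from a subject series.

    Pressure quadratics regress on the model-predicted (numerical) cardiac
    output column; the CO(HR) quadratic regresses Doppler CO on heart rate.
    With ``co_source='surrogate'`` (or when the column is absent) the
    ejection model supplies the numerical column using ``surrogate_params``.
    """
    hr = np.array(series.heart_rates)
    cod = np.array(series.column("doppler_co"), dtype=float)
    numerical = series.column("numerical_co")
    if co_source == "surrogate" or any(v is None for v in numerical):
        from .ejection import SurrogateParams, predict_numerical_co

        params = surrogate_params or SurrogateParams()
        co = predict_numerical_co(series, params)
    elif co_source == "numerical":
        co = np.array(numerical, dtype=float)
    else:
        raise DomainError(f"unknown co_source {co_source!r}")
    vsp = np.array(series.column("ventricular_systolic"), dtype=float)
    adp = np.array(series.column("aortic_diastolic"), dtype=float)
    return {
        "vsp": fit_quadratic(co, vsp, "co_ml_min", "vsp_mmHg"),
        "adp": fit_quadratic(co, adp, "co_ml_min", "adp_mmHg"),
        "cod": fit_quadratic(hr, cod, "heart_rate_bpm", "cod_ml_min"),
    }


def doppler_numerical_correlation(series: SubjectSeries) -> float:
    """Pearson r between the Doppler and model-predicted CO columns."""
    cod = np.array(series.column("doppler_co"), dtype=float)
    con = np.array(series.column("numerical_co"), dtype=float)
    if np.any(~np.isfinite(con)):
        raise DomainError("series lacks a complete numerical CO column")
    return float(stats.pearsonr(cod, con).statistic)


@dataclass(frozen=True)
class SummaryEntry:
    """Change of one pressure over the heart-rate range, one method."""

    method: str
    pressure: str  # 'vsp' or 'adp'
    low_value: float  # mmHg at the lowest heart rate
    high_value: float  # mmHg at the highest heart rate
    hr_low: float
    hr_high: float

    @property
    def absolute_change(self) -> float:
        return self.high_value - self.low_value

    @property
    def percent_change(self) -> float:
        return 100.0 * self.absolute_change / self.low_value

    @property
    def endpoint_gradient(self) -> float:
        """Difference quotient over the heart-rate range (mmHg per bpm)."""
        return self.absolute_change / (self.hr_high - self.hr_low)


@dataclass(frozen=True)
class ExerciseSummary:
    """Per-method, per-pressure exercise changes."""

    entries: tuple[SummaryEntry, ...]
    hr_low: float
    hr_high: float

    def get(self, method: str, pressure: str) -> SummaryEntry:
        for e in self.entries:
            if e.method == method and e.pressure == pressure:
                return e
        raise KeyError(f"no summary entry for ({method}, {pressure})")


def exercise_summary(
    series: SubjectSeries,
    fits: Mapping[str, QuadraticFit],
    maps: Mapping[str, LinearMap] = DEFAULT_MAPS,
) -> ExerciseSummary:
    """Summarize pressure changes between the lowest and highest heart rate.

    Doppler rows come from the measured pressures at the two endpoint
    records. Invasive-method rows evaluate the fitted VSP(CO) / ADP(CO)
    quadratics at the transformed measured Doppler CO of those records.
    Percent changes are relative to the low-heart-rate value; gradients are
    endpoint difference quotients.
    """
    if len(series) < 2:
        raise DomainError("summary needs records at >= 2 heart rates")
    for key in ("vsp", "adp"):
        if key not in fits:
            raise DomainError(f"missing required fit {key!r}")
    low, high = series[0], series[len(series) - 1]
    entries = []
    for method, lin in maps.items():
        for pressure, fit_key, measured in (
            ("vsp", "vsp", "ventricular_systolic"),
            ("adp", "adp", "aortic_diastolic"),
        ):
            if method == "doppler":
                lo_val = getattr(low, measured)
                hi_val = getattr(high, measured)
            else:
                fit = fits[fit_key]
                with warnings.catch_warnings():
                    # the transforms intentionally reach just past the
                    # fitted CO range at the endpoints
                    warnings.simplefilter("ignore", ExtrapolationWarning)
                    lo_val = fit(christie_transform(low.doppler_co, lin))
                    hi_val = fit(christie_transform(high.doppler_co, lin))
            entries.append(
                SummaryEntry(
                    method=method,
                    pressure=pressure,
                    low_value=float(lo_val),
                    high_value=float(hi_val),
                    hr_low=low.heart_rate,
                    hr_high=high.heart_rate,
                )
            )
    return ExerciseSummary(
        entries=tuple(entries), hr_low=low.heart_rate, hr_high=high.heart_rate
    )


def round_percent(value: float, decimals: int = 0) -> float:
    """Centralized percent rounding for reports (integer by default)."""
    return float(np.round(value, decimals))


def round_gradient(value: float) -> float:
    """Centralized gradient rounding for reports (two decimals)."""
    return float(np.round(value, 2))


def format_summary(summary: ExerciseSummary) -> str:
    """Human-readable summary table.

    Absolute changes to one decimal; percents to one decimal; endpoint
    gradients to two decimals (mmHg per bpm).
    """
    lines = [
        f"Pressure changes from {summary.hr_low:.0f} to {summary.hr_high:.0f} bpm",
        f"{'method':<16}{'pressure':<10}{'change (mmHg)':>14}"
        f"{'change (%)':>12}{'gradient':>10}",
    ]
    for e in summary.entries:
        lines.append(
            f"{e.method:<16}{e.pressure.upper():<10}"
            f"{e.absolute_change:>14.1f}"
            f"{round_percent(e.percent_change, 1):>12.1f}"
            f"{round_gradient(e.endpoint_gradient):>10.2f}"
        )
    lines.append(
        "rounding: percents printed to one decimal (report integers for "
        "whole-percent summaries), gradients to two decimals"
    )
    return "\n".join(lines)
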