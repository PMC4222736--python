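"""Doppler-derived hemodynamics.

The non-invasive cardiac-output chain used in stress echocardiography:
the outflow velocity envelope is integrated over the ejection period to a
velocity-time integral (VTI), multiplied by the aortic cross-sectional area
to give stroke volume, and by heart rate to give cardiac output,

    SV = VTI * A,      CO = SV * HR,      A = pi (D/2)^2,

with D the ascending aortic diameter just above the sinotubular junction.
Internally everything is SI (m, s); stroke volume and cardiac output are
reported clinically (ml, ml/min).
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .errors import DomainError, ValidationError

ML_PER_M3 = 1e6


@dataclass(frozen=True)
class VelocityTrace:
    """Sampled outflow-velocity envelope over one ejection.

    ``times`` start at 0 and increase strictly; the last sample time is the
    ejection time.
    """

    times: np.ndarray  # s
    velocities: np.ndarray  # m/s

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        velocities = np.asarray(self.velocities, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "velocities", velocities)
        if times.ndim != 1 or times.shape != velocities.shape:
            raise ValidationError("times and velocities must be equal-length 1-D")
        if times.size < 2:
            raise ValidationError("a velocity trace needs at least 2 samples")
        if times[0] != 0.0:
            raise ValidationError("trace must start at t = 0")
        if not np.all(np.diff(times) > 0):
            raise ValidationError("sample times must be strictly increasing")

    @property
    def ejection_time(self) -> float:
        return float(self.times[-1])


@dataclass(frozen=True)
class FlowSummary:
    """Derived Doppler flow quantities for one exercise stage."""

    vti: float  # m
    aortic_diameter: float  # m
    aortic_area: float  # m2
    stroke_volume: float  # ml
    cardiac_output: float  # ml/min
    mean_velocity: float  # m/s


def aortic_area(diameter: float) -> float:
    """Aortic cross-sectional area pi (D/2)^2 in m^2, D in metres."""
    if not diameter > 0:
        raise DomainError(f"aortic diameter must be positive, got {diameter}")
    return math.pi * (diameter / 2.0) ** 2


def velocity_time_integral(trace: VelocityTrace) -> float:
    """Trapezoidal integral of velocity over the ejection period (m).

    Uses the trace's own grid, so the result is linear in the sampled
    velocities and second-order accurate in the sampling step.
    """
    return float(np.trapezoid(trace.velocities, trace.times))


def stroke_volume(vti: float, area: float) -> float:
    """Stroke volume VTI * area, reported in ml."""
    if not (vti > 0 and area > 0):
        raise DomainError("vti and area must be positive")
    return vti * area * ML_PER_M3


def cardiac_output(stroke_volume_ml: float, heart_rate: float) -> float:
    """Cardiac output SV * HR in ml/min."""
    if not (stroke_volume_ml > 0 and heart_rate > 0):
        raise DomainError("stroke volume and heart rate must be positive")
    return stroke_volume_ml * heart_rate


def mean_velocity(vti: float, ejection_time: float) -> float:
    """Mean ejection velocity VTI / ejection time (m/s)."""
    if not (vti > 0 and ejection_time > 0):
        raise DomainError("vti and ejection time must be positive")
    return vti / ejection_time


def summarize_flow(
    trace: VelocityTrace, diameter: float, heart_rate: float
) -> FlowSummary:
    """Run the full Doppler chain for one stage and collect the results."""
    area = aortic_area(diameter)
    vti = velocity_time_integral(trace)
    sv = stroke_volume(vti, area)
    return FlowSummary(
        vti=vti,
        aortic_diameter=diameter,
        aortic_area=area,
        stroke_volume=sv,
        cardiac_output=cardiac_output(sv, heart_rate),
        mean_velocity=mean_velocity(vti, trace.ejection_time),
    )


def read_velocity_trace(path: Union[str, Path]) -> VelocityTrace:
    """Read a two-column CSV trace (time_s, velocity_m_s)."""
    frame = pd.read_csv(path)
    for col in ("time_s", "velocity_m_s"):
        if col not in frame.columns:
            raise ValidationError(f"{path}: missing column {col!r}")
    return VelocityTrace(
        frame["time_s"].to_numpy(float), frame["velocity_m_s"].to_numpy(float)
    )


def write_velocity_trace(trace: VelocityTrace, path: Union[str, Path]) -> None:
    pd.DataFrame({"time_s": trace.times, "velocity_m_s": trace.velocities}).to_csv(
        path, index=False
    )
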