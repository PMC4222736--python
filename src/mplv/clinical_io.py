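"""Subject data model, CSV exchange, packaged fixtures and pressure transforms.

An exercise test produces one :class:`SubjectRecord` per stage (one heart
rate). Records are collected into a heart-rate-sorted :class:`SubjectSeries`,
the container every downstream stage consumes. Pressures travel the chain

    brachial cuff  ->  aortic  ->  peak ventricular systolic

through two fixed affine corrections: an oscillometric-to-invasive aortic
adjustment (+2.25 mmHg systolic, -5.45 mmHg diastolic) and a constant
ventricular-aortic systolic offset (5 mmHg by default).

Units in this module are clinical throughout: mmHg, ml/min, bpm, s.
"""
from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Union

import pandas as pd
import yaml

from .constants import (
    BRACHIAL_TO_AORTIC_DIASTOLIC_MMHG,
    BRACHIAL_TO_AORTIC_SYSTOLIC_MMHG,
    VENTRICULAR_OFFSET_MMHG,
)
from .errors import (
    DomainError,
    FixtureLookupError,
    ParseError,
    SchemaError,
    ValidationError,
)

#: Canonical CSV header, one row per exercise stage.
CSV_COLUMNS = (
    "subject_id",
    "heart_rate_bpm",
    "brachial_sys_mmHg",
    "brachial_dia_mmHg",
    "aortic_sys_mmHg",
    "aortic_dia_mmHg",
    "ventricular_sys_mmHg",
    "doppler_co_ml_min",
    "numerical_co_ml_min",
    "ejection_time_s",
)

_MANDATORY_VALUES = (
    "heart_rate_bpm",
    "aortic_dia_mmHg",
    "ventricular_sys_mmHg",
    "doppler_co_ml_min",
)

_FIXTURE_FILES = {
    "table1": "valve_geometry_table1.yaml",
    "table2": "material_properties_table2.yaml",
    "table3": "subject_exercise_table3.csv",
}
#: Descriptive aliases for the packaged fixtures.
_FIXTURE_ALIASES = {
    "geometry": "table1",
    "materials": "table2",
    "subject": "table3",
}


@dataclass(frozen=True)
class SubjectRecord:
    """One exercise stage of a subject's hemodynamic record.

    Mandatory fields are the ones every downstream computation needs:
    heart rate, aortic diastolic pressure, ventricular systolic pressure and
    Doppler cardiac output. Brachial pressures, aortic systolic pressure,
    model-predicted cardiac output and ejection time are optional.
    """

    heart_rate: float  # bpm
    aortic_diastolic: float  # mmHg
    ventricular_systolic: float  # mmHg
    doppler_co: float  # ml/min
    aortic_systolic: float | None = None  # mmHg
    brachial_systolic: float | None = None  # mmHg
    brachial_diastolic: float | None = None  # mmHg
    numerical_co: float | None = None  # ml/min
    ejection_time: float | None = None  # s

    def __post_init__(self) -> None:
        if not self.heart_rate > 0:
            raise ValidationError(f"heart_rate must be > 0, got {self.heart_rate}")
        for name in (
            "aortic_diastolic",
            "ventricular_systolic",
            "aortic_systolic",
            "brachial_systolic",
            "brachial_diastolic",
        ):
            value = getattr(self, name)
            if value is not None and not value > 0:
                raise ValidationError(f"pressure {name} must be > 0, got {value}")
        if not self.doppler_co > 0:
            raise ValidationError(f"doppler_co must be > 0, got {self.doppler_co}")
        if (
            self.aortic_systolic is not None
            and not self.aortic_systolic > self.aortic_diastolic
        ):
            raise ValidationError(
                "aortic systolic pressure must exceed aortic diastolic pressure "
                f"({self.aortic_systolic} <= {self.aortic_diastolic})"
            )
        if self.ejection_time is not None and not self.ejection_time > 0:
            raise ValidationError("ejection_time must be > 0")


@dataclass(frozen=True)
class SubjectSeries:
    """Heart-rate-sorted collection of :class:`SubjectRecord`.

    Heart rates must be strictly increasing (exercise stages are distinct);
    quadratic fits additionally require at least 4 records, which the fitting
    routines enforce themselves.
    """

    records: tuple[SubjectRecord, ...]
    subject_id: str = "anonymous"
    notes: str = ""

    def __post_init__(self) -> None:
        if len(self.records) == 0:
            raise ValidationError("a series needs at least one record")
        ordered = tuple(sorted(self.records, key=lambda r: r.heart_rate))
        object.__setattr__(self, "records", ordered)
        rates = [r.heart_rate for r in ordered]
        for lo, hi in zip(rates, rates[1:]):
            if hi <= lo:
                raise ValidationError(
                    f"duplicate heart rate {hi} bpm: stages must be distinct"
                )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SubjectRecord]:
        return iter(self.records)

    def __getitem__(self, i: int) -> SubjectRecord:
        return self.records[i]

    @property
    def heart_rates(self) -> list[float]:
        return [r.heart_rate for r in self.records]

    def column(self, name: str) -> list[float | None]:
        """Values of one record field across the series, in heart-rate order."""
        return [getattr(r, name) for r in self.records]

    def to_frame(self) -> pd.DataFrame:
        """Series as a DataFrame in the canonical CSV column layout."""
        rows = []
        for r in self.records:
            rows.append(
                {
                    "subject_id": self.subject_id,
                    "heart_rate_bpm": r.heart_rate,
                    "brachial_sys_mmHg": r.brachial_systolic,
                    "brachial_dia_mmHg": r.brachial_diastolic,
                    "aortic_sys_mmHg": r.aortic_systolic,
                    "aortic_dia_mmHg": r.aortic_diastolic,
                    "ventricular_sys_mmHg": r.ventricular_systolic,
                    "doppler_co_ml_min": r.doppler_co,
                    "numerical_co_ml_min": r.numerical_co,
                    "ejection_time_s": r.ejection_time,
                }
            )
        return pd.DataFrame(rows, columns=list(CSV_COLUMNS))

    def with_numerical_co(self, values) -> "SubjectSeries":
        """Copy of the series with the model-predicted cardiac-output column set."""
        if len(values) != len(self.records):
            raise ValidationError("need one numerical CO value per record")
        new = tuple(
            replace(r, numerical_co=float(v)) for r, v in zip(self.records, values)
        )
        return SubjectSeries(new, subject_id=self.subject_id, notes=self.notes)


@dataclass(frozen=True)
class MaterialProperties:
    """Blood and leaflet material constants.

    The elastic constants (Young's modulus, Poisson ratio) are validated and
    carried as metadata; only blood density (and optionally viscosity) feed
    the reduced-order ejection model.
    """

    blood_viscosity: float  # Pa s
    blood_density: float  # kg/m3
    leaflet_young_modulus: float  # N/m2
    leaflet_poisson_ratio: float  # dimensionless

    def __post_init__(self) -> None:
        for name in (
            "blood_viscosity",
            "blood_density",
            "leaflet_young_modulus",
            "leaflet_poisson_ratio",
        ):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be strictly positive")
        if not self.leaflet_poisson_ratio < 0.5:
            raise ValidationError("poisson ratio must be < 0.5")


def brachial_to_aortic(
    brachial_systolic: float,
    brachial_diastolic: float,
    *,
    systolic_offset: float = BRACHIAL_TO_AORTIC_SYSTOLIC_MMHG,
    diastolic_offset: float = BRACHIAL_TO_AORTIC_DIASTOLIC_MMHG,
) -> tuple[float, float]:
    """Convert oscillometric brachial pressures to aortic pressures (mmHg).

    The affine corrections come from published comparisons of cuff
    oscillometry against invasive aortic catheter pressure.
    """
    if not (brachial_systolic > 0 and brachial_diastolic > 0):
        raise DomainError("brachial pressures must be positive")
    if not brachial_systolic > brachial_diastolic:
        raise DomainError(
            f"systolic pressure must exceed diastolic "
            f"({brachial_systolic} <= {brachial_diastolic})"
        )
    aortic_systolic = brachial_systolic + systolic_offset
    aortic_diastolic = brachial_diastolic + diastolic_offset
    if aortic_diastolic <= 0:
        raise DomainError(
            f"corrected aortic diastolic pressure is non-positive "
            f"({aortic_diastolic:.2f} mmHg)"
        )
    return aortic_systolic, aortic_diastolic


def aortic_to_ventricular_systolic(
    aortic_systolic: float, *, offset: float = VENTRICULAR_OFFSET_MMHG
) -> float:
    """Peak ventricular systolic pressure from aortic systolic pressure (mmHg)."""
    if not aortic_systolic > 0:
        raise DomainError("aortic systolic pressure must be positive")
    return aortic_systolic + offset


def _parse_cell(value, column: str, row: int) -> float | None:
    if value is None or (isinstance(value, float) and pd.isna(value)) or value == "":
        return None
    try:
        return float(value)
    except (TypeError, ValueError) as exc:
        raise ParseError(
            f"non-numeric value {value!r} in column {column!r}, data row {row}"
        ) from exc


def _series_from_frame(frame: pd.DataFrame, source: str) -> SubjectSeries:
    missing = [c for c in CSV_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"{source}: missing column(s) {', '.join(missing)}")
    records = []
    subject_id = "anonymous"
    for i, (_, row) in enumerate(frame.iterrows(), start=1):
        if row["subject_id"] is not None and not pd.isna(row["subject_id"]):
            subject_id = str(row["subject_id"])
        values = {c: _parse_cell(row[c], c, i) for c in CSV_COLUMNS[1:]}
        for c in _MANDATORY_VALUES:
            if values[c] is None:
                raise ValidationError(f"{source}: row {i} is missing mandatory {c!r}")
        records.append(
            SubjectRecord(
                heart_rate=values["heart_rate_bpm"],
                brachial_systolic=values["brachial_sys_mmHg"],
                brachial_diastolic=values["brachial_dia_mmHg"],
                aortic_systolic=values["aortic_sys_mmHg"],
                aortic_diastolic=values["aortic_dia_mmHg"],
                ventricular_systolic=values["ventricular_sys_mmHg"],
                doppler_co=values["doppler_co_ml_min"],
                numerical_co=values["numerical_co_ml_min"],
                ejection_time=values["ejection_time_s"],
            )
        )
    return SubjectSeries(tuple(records), subject_id=subject_id)


def read_subject_csv(path: Union[str, Path]) -> SubjectSeries:
    """Read a subject exercise series from the canonical CSV schema.

    Optional columns may be empty; mandatory per-row values are heart rate,
    aortic diastolic pressure, ventricular systolic pressure and Doppler
    cardiac output.
    """
    path = Path(path)
    frame = pd.read_csv(path, dtype=object, keep_default_na=True)
    return _series_from_frame(frame, source=str(path))


def write_subject_csv(series: SubjectSeries, path: Union[str, Path]) -> None:
    """Write a series in the canonical CSV schema (6 significant digits)."""
    frame = series.to_frame()
    frame.to_csv(path, index=False, float_format="%.6g")


def load_config(path: Union[str, Path]) -> dict:
    """Load a flat YAML config (transform constants, fixture overrides)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise SchemaError(f"{path}: config must be a mapping")
    return cfg


def load_fixture(name: str):
    """Load one of the packaged in-study fixtures.

    ``table3`` (alias ``subject``) is the single-subject exercise series;
    ``table1`` (``geometry``) the echo-measured valve geometry; ``table2``
    (``materials``) the blood/leaflet material constants. Values are exactly
    the published measurements.
    """
    key = _FIXTURE_ALIASES.get(name, name)
    if key not in _FIXTURE_FILES:
        raise FixtureLookupError(
            name, tuple(_FIXTURE_FILES) + tuple(_FIXTURE_ALIASES)
        )
    resource = importlib.resources.files("mplv.data") / _FIXTURE_FILES[key]
    if key == "table3":
        with importlib.resources.as_file(resource) as p:
            return read_subject_csv(p)
    with resource.open() as fh:
        # coerce: pyyaml leaves exponents without a sign (6.885e6) as strings
        raw = {k: float(v) for k, v in yaml.safe_load(fh).items()}
    if key == "table2":
        return MaterialProperties(
            blood_viscosity=raw["blood_viscosity_pa_s"],
            blood_density=raw["blood_density_kg_m3"],
            leaflet_young_modulus=raw["leaflet_young_modulus_n_m2"],
            leaflet_poisson_ratio=raw["leaflet_poisson_ratio"],
        )
    from .geometry import ValveGeometryParams  # local import to avoid a cycle

    return ValveGeometryParams(
        base_radius=raw["base_radius_mm"],
        commissure_radius=raw["commissure_radius_mm"],
        valve_height=raw["valve_height_mm"],
        sinus_height=raw["sinus_height_mm"],
        leaflet_height=raw["leaflet_height_mm"],
        leaflet_free_edge=raw["leaflet_free_edge_mm"],
        sinus_max_radius=raw["sinus_max_radius_mm"],
        sinus_max_location=raw["sinus_max_location_mm"],
        leaflet_thickness=raw["leaflet_thickness_mm"],
    )
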