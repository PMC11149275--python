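"""Indentation time-series containers and delimited-text I/O.

Canonical internal units are seconds, micrometers and newtons; elastic
moduli are reported in MPa (1 N/um^2 == 1e6 MPa, conversion happens inside
the Hayes-equation evaluation).  Compressive load and downward indenter
displacement are positive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

MIN_SAMPLES = 50

#: multiplicative factors into canonical units
TIME_UNITS = {"s": 1.0, "ms": 1e-3, "min": 60.0}
DISPLACEMENT_UNITS = {"um": 1.0, "mm": 1e3, "m": 1e6, "nm": 1e-3}
LOAD_UNITS = {"N": 1.0, "mN": 1e-3, "kN": 1e3, "uN": 1e-6}

#: canonical column header used by :func:`write_curve`
CANONICAL_COLUMNS = ("t_s", "disp_um", "load_N")


@dataclass(frozen=True)
class CurveDialect:
    """Column mapping and source units for a delimited curve file."""

    time_column: str = "t_s"
    displacement_column: str = "disp_um"
    load_column: str = "load_N"
    time_unit: str = "s"
    displacement_unit: str = "um"
    load_unit: str = "N"
    delimiter: str = ","

    @classmethod
    def from_dict(cls, d: dict) -> "CurveDialect":
        return cls(**{k: v for k, v in d.items() if k in cls.__dataclass_fields__})


@dataclass(frozen=True)
class IndentationCurve:
    """One ramp-hold indentation record in canonical units (s, um, N)."""

    time: np.ndarray
    displacement: np.ndarray
    load: np.ndarray
    sample_id: str = ""
    sampling_rate_hint: float | None = None
    #: full records require >= 50 samples; phase slices relax this to 5
    min_samples: int = MIN_SAMPLES

    def __post_init__(self):
        t = np.asarray(self.time, dtype=float)
        x = np.asarray(self.displacement, dtype=float)
        p = np.asarray(self.load, dtype=float)
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "displacement", x)
        object.__setattr__(self, "load", p)
        if t.ndim != 1 or t.size < self.min_samples:
            raise ValidationError(
                f"curve {self.sample_id!r}: need >= {self.min_samples} samples, got {t.size}"
            )
        if x.shape != t.shape or p.shape != t.shape:
            raise ValidationError(
                f"curve {self.sample_id!r}: time/displacement/load lengths differ"
            )
        if not (np.isfinite(x).all() and np.isfinite(p).all() and np.isfinite(t).all()):
            raise ValidationError(f"curve {self.sample_id!r}: non-finite samples")
        dt = np.diff(t)
        bad = np.flatnonzero(dt <= 0)
        if bad.size:
            raise ValidationError(
                f"curve {self.sample_id!r}: time not strictly increasing at index {bad[0] + 1}"
            )

    def __len__(self) -> int:
        return self.time.size

    @property
    def duration(self) -> float:
        return float(self.time[-1] - self.time[0])

    @property
    def sampling_rate(self) -> float:
        """Median sampling rate in Hz."""
        return 1.0 / float(np.median(np.diff(self.time)))

    def with_arrays(self, **kw) -> "IndentationCurve":
        return replace(self, **kw)


@dataclass(frozen=True)
class SpecimenGeometry:
    """Indenter/layer geometry entering the Hayes correction.

    ``alpha = R/h`` is the indenter-radius to layer-thickness aspect ratio;
    thickness has no default because it must be measured per specimen.
    """

    thickness_um: float
    indenter_radius_um: float = 525.0
    poisson_nu: float = 0.4

    def __post_init__(self):
        if not (self.indenter_radius_um > 0):
            raise ValidationError("indenter radius must be > 0")
        if not (self.thickness_um > 0):
            raise ValidationError("layer thickness must be > 0")
        if not (0.0 <= self.poisson_nu < 0.5):
            raise ValidationError(
                f"Poisson ratio must lie in [0, 0.5), got {self.poisson_nu}"
            )

    @property
    def alpha(self) -> float:
        return self.indenter_radius_um / self.thickness_um


@dataclass(frozen=True)
class ProtocolSpec:
    """Strain-controlled ramp-hold-unload protocol parameters."""

    preload_n: float = 0.1
    ramp_rate_um_per_s: float = 25.0
    ramp_depth_um: float = 50.0
    hold_duration_s: float = 13.0

    def __post_init__(self):
        for name in ("preload_n", "ramp_rate_um_per_s", "ramp_depth_um", "hold_duration_s"):
            if not (getattr(self, name) > 0):
                raise ValidationError(f"protocol field {name} must be > 0")

    @property
    def ramp_duration_s(self) -> float:
        return self.ramp_depth_um / self.ramp_rate_um_per_s


def contact_pressure_kpa(load_n: float, radius_um: float) -> float:
    """Nominal contact pressure of a flat-ended cylindrical indenter, in kPa.

    ``P / (pi R^2)`` — e.g. the 0.1 N preload on a 525 um radius punch.
    """
    area_m2 = math.pi * (radius_um * 1e-6) ** 2
    return load_n / area_m2 / 1e3


def _factor(unit: str, table: dict, kind: str) -> float:
    try:
        return table[unit]
    except KeyError:
        raise ValidationError(f"unknown {kind} unit {unit!r}; known: {sorted(table)}")


def read_curve(path, dialect: CurveDialect | dict | None = None,
               sample_id: str | None = None) -> IndentationCurve:
    """Read a delimited-text indentation record into canonical units."""
    if dialect is None:
        dialect = CurveDialect()
    elif isinstance(dialect, dict):
        dialect = CurveDialect.from_dict(dialect)
    df = pd.read_csv(path, sep=dialect.delimiter)
    for col in (dialect.time_column, dialect.displacement_column, dialect.load_column):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r} (have {list(df.columns)})")
    t = df[dialect.time_column].to_numpy(float) * _factor(dialect.time_unit, TIME_UNITS, "time")
    x = df[dialect.displacement_column].to_numpy(float) * _factor(
        dialect.displacement_unit, DISPLACEMENT_UNITS, "displacement")
    p = df[dialect.load_column].to_numpy(float) * _factor(dialect.load_unit, LOAD_UNITS, "load")
    sid = sample_id if sample_id is not None else _stem(path)
    return IndentationCurve(time=t, displacement=x, load=p, sample_id=sid)


def write_curve(curve: IndentationCurve, path) -> None:
    """Write a curve as canonical CSV (``t_s,disp_um,load_N``).

    Values survive a read/write round trip to better than 1e-9 relative.
    """
    df = pd.DataFrame({
        CANONICAL_COLUMNS[0]: curve.time,
        CANONICAL_COLUMNS[1]: curve.displacement,
        CANONICAL_COLUMNS[2]: curve.load,
    })
    df.to_csv(path, index=False, float_format="%.17g")


def read_specimen_table(path) -> list[tuple[str, SpecimenGeometry, str]]:
    """Read the per-specimen geometry/group table.

    Expected columns: ``sample_id, R_um, h_um, nu, group``.  Thickness is
    mandatory — there is no physically defensible default.
    """
    df = pd.read_csv(path)
    required = {"sample_id", "h_um", "group"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing column(s) {sorted(missing)}")
    rows = []
    for i, row in df.iterrows():
        if pd.isna(row["h_um"]):
            raise ValidationError(
                f"{path} row {i}: thickness h_um is required (no default exists)")
        geom = SpecimenGeometry(
            thickness_um=float(row["h_um"]),
            indenter_radius_um=float(row.get("R_um", 525.0) if pd.notna(row.get("R_um")) else 525.0),
            poisson_nu=float(row.get("nu", 0.4) if pd.notna(row.get("nu")) else 0.4),
        )
        rows.append((str(row["sample_id"]), geom, str(row["group"])))
    return rows


def write_specimen_table(rows, path) -> None:
    df = pd.DataFrame(
        [(sid, g.indenter_radius_um, g.thickness_um, g.poisson_nu, grp)
         for sid, g, grp in rows],
        columns=["sample_id", "R_um", "h_um", "nu", "group"],
    )
    df.to_csv(path, index=False)


def _stem(path) -> str:
    import os
    return os.path.splitext(os.path.basename(str(path)))[0]
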