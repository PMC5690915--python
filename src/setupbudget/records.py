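"""Data model and delimited-text I/O for 6D setup shifts, isocenter QA logs,
and couch-sag phantom measurements.

A 6D shift is three translations (lateral x, longitudinal/superior-inferior y,
vertical/anterior-posterior z, in mm) plus three rotations (pitch about x,
roll about y, yaw about z, in degrees).  Components measured as "n/a" (e.g.
the vertical offset of a collimator Winston-Lutz run, or couch-sag yaw) are
stored as an explicit ``None`` — never silently zero-filled; arithmetic that
consumes them treats them as contributing zero and flags it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from typing import Iterable, Optional, Sequence

import pandas as pd

AXES = ("lat", "long", "vert", "pitch", "roll", "yaw")
TRANSLATION_AXES = AXES[:3]
ROTATION_AXES = AXES[3:]

STAGES = ("XC", "XV", "XV2")
ISO_AXES = ("gantry", "collimator", "couch_rotation", "kv_imager", "infrared")

#: Institutional tolerance gating the X-ray correction workflow.
DEFAULT_TRANS_TOL_MM = 0.7
DEFAULT_ROT_TOL_DEG = 1.0

#: Strings parsed as an absent ("n/a") measurement in delimited files.
NA_TOKENS = {"", "n/a", "na", "nan", "none"}


class ValidationError(ValueError):
    """A record or file violated the data contract."""


def _check_finite(name: str, value: Optional[float]) -> Optional[float]:
    if value is None:
        return None
    value = float(value)
    if not math.isfinite(value):
        raise ValidationError(f"{name} must be finite, got {value!r}")
    return value


@dataclass(frozen=True)
class ShiftVector6D:
    """One 6D translational + rotational displacement.

    Translations in mm, rotations in degrees.  Any component may be ``None``
    (absent), which downstream sums and quadratures treat as zero, flagged.
    """

    lat: Optional[float] = None
    long: Optional[float] = None
    vert: Optional[float] = None
    pitch: Optional[float] = None
    roll: Optional[float] = None
    yaw: Optional[float] = None

    def __post_init__(self) -> None:
        for f in fields(self):
            object.__setattr__(self, f.name, _check_finite(f.name, getattr(self, f.name)))

    @classmethod
    def zero(cls) -> "ShiftVector6D":
        return cls(0.0, 0.0, 0.0, 0.0, 0.0, 0.0)

    def as_dict(self) -> dict:
        return {a: getattr(self, a) for a in AXES}

    def translations(self) -> tuple:
        return (self.lat, self.long, self.vert)

    def rotations(self) -> tuple:
        return (self.pitch, self.roll, self.yaw)

    def is_complete(self) -> bool:
        """True when all six components are present."""
        return all(getattr(self, a) is not None for a in AXES)

    def scaled(self, c: float) -> "ShiftVector6D":
        return ShiftVector6D(*(None if v is None else c * v for v in (getattr(self, a) for a in AXES)))

    def __add__(self, other: "ShiftVector6D") -> "ShiftVector6D":
        def add(a, b):
            if a is None and b is None:
                return None
            return (a or 0.0) + (b or 0.0)

        return ShiftVector6D(*(add(getattr(self, n), getattr(other, n)) for n in AXES))


def radial(shift: ShiftVector6D) -> float:
    """Quadrature sum sqrt(lat² + long² + vert²) of the translations, in mm.

    Rotations are ignored; absent translational components contribute zero.
    """
    total = 0.0
    for v in shift.translations():
        if v is None:
            continue
        total += v * v
    return math.sqrt(total)


def within_tolerance(
    shift: ShiftVector6D,
    trans_tol: float = DEFAULT_TRANS_TOL_MM,
    rot_tol: float = DEFAULT_ROT_TOL_DEG,
) -> bool:
    """True iff every translation is within ``trans_tol`` mm and every
    rotation within ``rot_tol`` degrees, boundaries inclusive.

    Inclusive boundaries reflect the clinical reading of "within tolerance":
    a setup exactly at tolerance is treated.
    """
    if trans_tol <= 0 or rot_tol <= 0:
        raise ValidationError("tolerances must be positive")
    if not shift.is_complete():
        raise ValidationError("within_tolerance requires a complete 6D shift")
    return all(abs(v) <= trans_tol for v in shift.translations()) and all(
        abs(v) <= rot_tol for v in shift.rotations()
    )


@dataclass(frozen=True)
class SetupRecord:
    """One imaging event: an XC (correction) or XV (verification) shift for a
    given patient, treatment (isocenter) and fraction."""

    patient_id: str
    treatment_id: str
    fraction: int
    stage: str
    shift: ShiftVector6D

    def __post_init__(self) -> None:
        if self.fraction < 1:
            raise ValidationError(f"fraction must be >= 1, got {self.fraction}")
        if self.stage not in STAGES:
            raise ValidationError(f"stage must be one of {STAGES}, got {self.stage!r}")
        if not self.shift.is_complete():
            raise ValidationError("setup shifts must carry all six components")


@dataclass(frozen=True)
class IsoOffsetRecord:
    """One Winston-Lutz isocentricity measurement for a rotation axis or
    imaging system (translations only; vertical may be absent)."""

    axis: str
    offset: ShiftVector6D
    date: str = ""

    def __post_init__(self) -> None:
        if self.axis not in ISO_AXES:
            raise ValidationError(f"axis must be one of {ISO_AXES}, got {self.axis!r}")


@dataclass(frozen=True)
class CouchSagRecord:
    """Couch deflection at a given load and couch angle (yaw not measurable
    with the optical phantom setup and stored absent)."""

    load: float
    angle: float
    sag: ShiftVector6D

    def __post_init__(self) -> None:
        if self.load < 0:
            raise ValidationError(f"load must be >= 0 kg, got {self.load}")
        if not 0 <= self.angle < 360:
            raise ValidationError(f"angle must be in [0, 360), got {self.angle}")


# ---------------------------------------------------------------------------
# Delimited-text I/O.  Schemas (comma-separated, UTF-8, one header row;
# a tab dialect is available via ``delimiter="\t"``):
#
#   setup_shifts.csv: patient_id,treatment_id,fraction,stage,
#                     lat_mm,long_mm,vert_mm,pitch_deg,roll_deg,yaw_deg
#   wl_qa.csv:        date,axis,lat_mm,long_mm,vert_mm
#   couch_sag.csv:    load_kg,angle_deg,lat_mm,long_mm,vert_mm,pitch_deg,roll_deg
# ---------------------------------------------------------------------------

SETUP_COLUMNS = (
    "patient_id",
    "treatment_id",
    "fraction",
    "stage",
    "lat_mm",
    "long_mm",
    "vert_mm",
    "pitch_deg",
    "roll_deg",
    "yaw_deg",
)
WL_COLUMNS = ("date", "axis", "lat_mm", "long_mm", "vert_mm")
COUCH_COLUMNS = ("load_kg", "angle_deg", "lat_mm", "long_mm", "vert_mm", "pitch_deg", "roll_deg")


def _read_table(path, columns: Sequence[str], delimiter: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing column(s) {missing}")
    return df

def _parse_float(raw: str, *, column: str, row: int, allow_absent: bool) -> Optional[float]:
    if raw.strip().lower() in NA_TOKENS:
        if allow_absent:
            return None
        raise ValidationError(f"row {row}: column {column!r} may not be empty")
    try:
        value = float(raw)
    except ValueError:
        raise ValidationError(f"row {row}: column {column!r} is not numeric: {raw!r}") from None
    return _check_finite(f"row {row} {column}", value)


def read_setup_table(path, delimiter: str = ",") -> list[SetupRecord]:
    """Read a setup-shift table; row order preserved.

    Raises :class:`ValidationError` naming the offending data row (1-based)
    on a missing column, a non-numeric shift, or a duplicate
    (treatment, fraction, stage) key.
    """
    df = _read_table(path, SETUP_COLUMNS, delimiter)
    records: list[SetupRecord] = []
    seen: set[tuple] = set()
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            fraction = int(str(row.fraction))
        except ValueError:
            raise ValidationError(f"row {i}: fraction is not an integer: {row.fraction!r}") from None
        shift = ShiftVector6D(
            *(
                _parse_float(getattr(row, c), column=c, row=i, allow_absent=False)
                for c in SETUP_COLUMNS[4:]
            )
        )
        try:
            rec = SetupRecord(str(row.patient_id), str(row.treatment_id), fraction, str(row.stage), shift)
        except ValidationError as exc:
            raise ValidationError(f"row {i}: {exc}") from None
        key = (rec.treatment_id, rec.fraction, rec.stage)
        if key in seen:
            raise ValidationError(f"row {i}: duplicate (treatment, fraction, stage) {key}")
        seen.add(key)
        records.append(rec)
    return records


def _fmt(v: Optional[float]) -> str:
    return "n/a" if v is None else repr(float(v))


def write_setup_table(records: Iterable[SetupRecord], path, delimiter: str = ",") -> None:
    rows = [
        {
            "patient_id": r.patient_id,
            "treatment_id": r.treatment_id,
            "fraction": r.fraction,
            "stage": r.stage,
            **{c: _fmt(getattr(r.shift, a)) for c, a in zip(SETUP_COLUMNS[4:], AXES)},
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=list(SETUP_COLUMNS)).to_csv(path, sep=delimiter, index=False)


def read_wl_table(path, delimiter: str = ",") -> list[IsoOffsetRecord]:
    df = _read_table(path, WL_COLUMNS, delimiter)
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        offset = ShiftVector6D(
            lat=_parse_float(row.lat_mm, column="lat_mm", row=i, allow_absent=True),
            long=_parse_float(row.long_mm, column="long_mm", row=i, allow_absent=True),
            vert=_parse_float(row.vert_mm, column="vert_mm", row=i, allow_absent=True),
        )
        try:
            records.append(IsoOffsetRecord(axis=str(row.axis), offset=offset, date=str(row.date)))
        except ValidationError as exc:
            raise ValidationError(f"row {i}: {exc}") from None
    return records


def write_wl_table(records: Iterable[IsoOffsetRecord], path, delimiter: str = ",") -> None:
    rows = [
        {
            "date": r.date,
            "axis": r.axis,
            "lat_mm": _fmt(r.offset.lat),
            "long_mm": _fmt(r.offset.long),
            "vert_mm": _fmt(r.offset.vert),
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=list(WL_COLUMNS)).to_csv(path, sep=delimiter, index=False)


def read_couch_sag_table(path, delimiter: str = ",") -> list[CouchSagRecord]:
    df = _read_table(path, COUCH_COLUMNS, delimiter)
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        sag = ShiftVector6D(
            lat=_parse_float(row.lat_mm, column="lat_mm", row=i, allow_absent=False),
            long=_parse_float(row.long_mm, column="long_mm", row=i, allow_absent=False),
            vert=_parse_float(row.vert_mm, column="vert_mm", row=i, allow_absent=False),
            pitch=_parse_float(row.pitch_deg, column="pitch_deg", row=i, allow_absent=True),
            roll=_parse_float(row.roll_deg, column="roll_deg", row=i, allow_absent=True),
        )
        load = _parse_float(row.load_kg, column="load_kg", row=i, allow_absent=False)
        angle = _parse_float(row.angle_deg, column="angle_deg", row=i, allow_absent=False)
        try:
            records.append(CouchSagRecord(load=load, angle=angle, sag=sag))
        except ValidationError as exc:
            raise ValidationError(f"row {i}: {exc}") from None
    return records


def write_couch_sag_table(records: Iterable[CouchSagRecord], path, delimiter: str = ",") -> None:
    rows = [
        {
            "load_kg": repr(float(r.load)),
            "angle_deg": repr(float(r.angle)),
            "lat_mm": _fmt(r.sag.lat),
            "long_mm": _fmt(r.sag.long),
            "vert_mm": _fmt(r.sag.vert),
            "pitch_deg": _fmt(r.sag.pitch),
            "roll_deg": _fmt(r.sag.roll),
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=list(COUCH_COLUMNS)).to_csv(path, sep=delimiter, index=False)
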