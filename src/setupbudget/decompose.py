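"""Estimators mapping XC/XV record streams and QA logs onto named
systematic and random uncertainty components.

The estimator mapping is the core of the uncertainty model:

==============  ==========  =====================================================
component       type        estimator
==============  ==========  =====================================================
mask (ΣM)       systematic  mean of each treatment's XC shifts
setup (σS)      random      sample SD of each treatment's XC shifts
frame (ΣF)      systematic  mean of all XC shifts, pooled over the cohort
localizer (ΣL)  systematic  mean of all XV shifts
xray (σXR)      random      SD of all XV shifts (pooled; see below)
couch_sag (ΣC)  systematic  worst-case row of the phantom sag table
iso_mv          systematic  gantry + collimator + couch rotation WL means
iso_kv, iso_ir  systematic  WL means of the kV imager / infrared system
==============  ==========  =====================================================

Conventions, chosen once and documented:

* Sample SDs use ddof=1; a single-fraction treatment contributes SD = 0.
* The *radial* of a component estimated from a record stream is the mean (or
  SD, for random components) of the per-record radials — not the quadrature
  of the per-axis means, which is generally smaller and is reported
  separately as ``radial_of_means``.
* σXR defaults to the pooled SD of all XV shifts; the SD of per-treatment XV
  means is available via ``convention="sd_of_treatment_means"``.
* Components composed from means (the three isocentricities) take their
  radial as the norm of the composed mean vector; absent axes contribute
  zero and are flagged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats

from .records import (
    AXES,
    CouchSagRecord,
    ISO_AXES,
    IsoOffsetRecord,
    SetupRecord,
    ShiftVector6D,
    TRANSLATION_AXES,
    ValidationError,
    radial,
)

COMPONENT_NAMES = (
    "mask",
    "setup",
    "frame",
    "localizer",
    "xray",
    "couch_sag",
    "iso_mv",
    "iso_kv",
    "iso_ir",
)

#: Components removed by the X-ray correction step: patient positioning
#: within the mask is exactly what XC measures and corrects.
CORRECTED_BY_XRAY = frozenset({"mask", "setup"})


@dataclass(frozen=True)
class ComponentUncertainty:
    """One row of the uncertainty budget."""

    name: str
    utype: str  # "systematic" | "random"
    per_axis: ShiftVector6D
    radial: float
    n: int
    corrected_by_xray: bool = False
    #: quadrature of the per-axis means — the non-canonical radial, kept for
    #: comparison because the two differ whenever shifts change sign.
    radial_of_means: Optional[float] = None
    flags: tuple = ()

    def __post_init__(self) -> None:
        if self.utype not in ("systematic", "random"):
            raise ValidationError(f"utype must be systematic|random, got {self.utype!r}")
        if self.radial < 0:
            raise ValidationError("radial must be >= 0")
        if self.n < 1:
            raise ValidationError("n must be >= 1")
        if self.utype == "random" and any(
            v is not None and v < 0 for v in self.per_axis.as_dict().values()
        ):
            raise ValidationError("random components must have non-negative per-axis values")


@dataclass(frozen=True)
class AxisSummary:
    """Mean, SD, two-sided one-sample t-test p-value (H0: mean = 0), and
    range for one axis of a shift distribution."""

    mean: float
    sd: Optional[float]
    p_value: Optional[float]
    min: float
    max: float
    n: int
    flags: tuple = ()


def _axis_matrix(shifts: Sequence[ShiftVector6D]) -> np.ndarray:
    """(n, 6) array of shift components; absent -> nan."""
    return np.array(
        [[np.nan if v is None else v for v in (s.as_dict()[a] for a in AXES)] for s in shifts],
        dtype=float,
    )


def _mean_vector(shifts: Sequence[ShiftVector6D]) -> ShiftVector6D:
    m = _axis_matrix(shifts)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-nan column -> absent
        means = np.nanmean(m, axis=0)
    return ShiftVector6D(*(None if np.isnan(v) else float(v) for v in means))


def _sd_vector(shifts: Sequence[ShiftVector6D], ddof: int = 1) -> ShiftVector6D:
    m = _axis_matrix(shifts)
    if m.shape[0] <= ddof:
        return ShiftVector6D(*(0.0 if not np.isnan(v) else None for v in m[0]))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        sds = np.nanstd(m, axis=0, ddof=ddof)
    return ShiftVector6D(*(None if np.isnan(v) else float(v) for v in sds))


def _norm_of_means(vec: ShiftVector6D) -> float:
    return float(np.sqrt(sum((v or 0.0) ** 2 for v in vec.translations())))


def per_treatment_stats(
    records: Iterable[SetupRecord],
    group_by: str = "treatment_id",
    ddof: int = 1,
) -> dict:
    """Per-treatment mask systematic (ΣM) and setup random (σS) components
    from XC records.

    ΣM per axis is the mean of that treatment's XC shifts and its radial is
    the mean of the per-fraction radials; σS is the sample SD per axis (0 for
    single-fraction treatments) with radial the SD of per-fraction radials.
    Returns ``{group_key: (mask, setup)}`` in first-appearance order.
    """
    xc = [r for r in records if r.stage == "XC"]
    if not xc:
        raise ValidationError("no XC records")
    groups: dict[str, list[SetupRecord]] = {}
    for r in xc:
        groups.setdefault(getattr(r, group_by), []).append(r)
    out = {}
    for key, recs in groups.items():
        shifts = [r.shift for r in recs]
        radials = np.array([radial(s) for s in shifts])
        n = len(recs)
        mean_vec = _mean_vector(shifts)
        sd_vec = _sd_vector(shifts, ddof=ddof)
        mask = ComponentUncertainty(
            name="mask",
            utype="systematic",
            per_axis=mean_vec,
            radial=float(radials.mean()),
            n=n,
            corrected_by_xray=True,
            radial_of_means=_norm_of_means(mean_vec),
        )
        setup = ComponentUncertainty(
            name="setup",
            utype="random",
            per_axis=sd_vec,
            radial=float(radials.std(ddof=ddof)) if n > ddof else 0.0,
            n=n,
            corrected_by_xray=True,
        )
        out[key] = (mask, setup)
    return out


def frame_systematic(records: Iterable[SetupRecord]) -> ComponentUncertainty:
    """Infrared-frame systematic ΣF: per-axis mean over *all* XC setups,
    pooled over fractions (not treatment-averaged), radial = mean of the
    per-record radials."""
    xc = [r for r in records if r.stage == "XC"]
    if len(xc) < 2:
        raise ValidationError("frame_systematic requires >= 2 XC records")
    shifts = [r.shift for r in xc]
    mean_vec = _mean_vector(shifts)
    return ComponentUncertainty(
        name="frame",
        utype="systematic",
        per_axis=mean_vec,
        radial=float(np.mean([radial(s) for s in shifts])),
        n=len(xc),
        radial_of_means=_norm_of_means(mean_vec),
    )


def localizer_and_xray(
    records: Iterable[SetupRecord],
    convention: str = "pooled",
    ddof: int = 1,
) -> tuple:
    """Localizer systematic ΣL and X-ray registration random σXR from XV
    records.

    ΣL is the per-axis mean of all XV shifts.  σXR is by default the pooled
    per-axis SD of all XV shifts; ``convention="sd_of_treatment_means"``
    instead takes the SD across per-treatment XV mean vectors.
    """
    xv = [r for r in records if r.stage in ("XV", "XV2")]
    if len(xv) < 2:
        raise ValidationError("localizer_and_xray requires >= 2 XV records")
    shifts = [r.shift for r in xv]
    radials = np.array([radial(s) for s in shifts])
    mean_vec = _mean_vector(shifts)
    localizer = ComponentUncertainty(
        name="localizer",
        utype="systematic",
        per_axis=mean_vec,
        radial=float(radials.mean()),
        n=len(xv),
        radial_of_means=_norm_of_means(mean_vec),
    )
    if convention == "pooled":
        sd_vec = _sd_vector(shifts, ddof=ddof)
        rad = float(radials.std(ddof=ddof))
        n = len(xv)
        flags = ()
    elif convention == "sd_of_treatment_means":
        by_treatment: dict[str, list] = {}
        for r in xv:
            by_treatment.setdefault(r.treatment_id, []).append(r.shift)
        means = [_mean_vector(s) for s in by_treatment.values()]
        if len(means) < 2:
            raise ValidationError("sd_of_treatment_means requires >= 2 treatments with XV")
        sd_vec = _sd_vector(means, ddof=ddof)
        rad = float(np.std([_norm_of_means(m) for m in means], ddof=ddof))
        n = len(means)
        flags = ("sd_of_treatment_means",)
    else:
        raise ValidationError(f"unknown convention {convention!r}")
    xray = ComponentUncertainty(
        name="xray", utype="random", per_axis=sd_vec, radial=rad, n=n, flags=flags
    )
    return localizer, xray


def axis_summary(values: Sequence[float], ddof: int = 1) -> AxisSummary:
    """Summary statistics for one axis: mean, sample SD, two-sided one-sample
    t-test p-value against zero, min and max.

    For n < 2 the SD and p-value are absent (flag ``insufficient-n``).  A
    degenerate sample (SD = 0) has no t statistic: p is absent for an all-zero
    sample and reported as 0.0 — below any attainable floor — with flag
    ``degenerate-variance`` when the common value is nonzero.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValidationError("axis_summary requires at least one value")
    if not np.isfinite(arr).all():
        raise ValidationError("axis_summary values must be finite")
    mean = float(arr.mean())
    lo, hi = float(arr.min()), float(arr.max())
    if arr.size < 2:
        return AxisSummary(mean, None, None, lo, hi, int(arr.size), flags=("insufficient-n",))
    sd = float(arr.std(ddof=ddof))
    if sd == 0.0:
        if mean == 0.0:
            return AxisSummary(mean, sd, None, lo, hi, int(arr.size), flags=("degenerate-zero",))
        return AxisSummary(mean, sd, 0.0, lo, hi, int(arr.size), flags=("degenerate-variance",))
    p = float(stats.ttest_1samp(arr, 0.0).pvalue)
    return AxisSummary(mean, sd, p, lo, hi, int(arr.size))


def winston_lutz_components(records: Iterable[IsoOffsetRecord], ddof: int = 1) -> dict:
    """Isocentricity components from a Winston-Lutz QA log.

    The MV radiation-isocenter systematic is composed as the per-axis sum of
    the gantry, collimator and couch-rotation mean offsets (absent axes
    contribute zero, flagged); the kV-imager and infrared components are the
    per-axis means of their own records.  Returns a dict with keys among
    ``iso_mv``, ``iso_kv``, ``iso_ir`` — a key is missing (with a warning)
    when no record of the needed rotation axis exists.
    """
    by_axis: dict[str, list[ShiftVector6D]] = {a: [] for a in ISO_AXES}
    for r in records:
        by_axis[r.axis].append(r.offset)
    means = {a: _mean_vector(s) for a, s in by_axis.items() if s}
    sds = {a: _sd_vector(s, ddof=ddof) for a, s in by_axis.items() if s}

    out: dict[str, ComponentUncertainty] = {}
    mv_parts = [a for a in ("gantry", "collimator", "couch_rotation") if a in means]
    if mv_parts:
        flags = tuple(f"missing:{a}" for a in ("gantry", "collimator", "couch_rotation") if a not in means)
        per_axis_vals = []
        absent_seen = False
        for ax in TRANSLATION_AXES:
            vals = [getattr(means[a], ax) for a in mv_parts]
            absent_seen |= any(v is None for v in vals)
            per_axis_vals.append(sum(v or 0.0 for v in vals))
        if absent_seen:
            flags = flags + ("absent-contributed-zero",)
        vec = ShiftVector6D(*per_axis_vals)
        out["iso_mv"] = ComponentUncertainty(
            name="iso_mv",
            utype="systematic",
            per_axis=vec,
            radial=_norm_of_means(vec),
            n=sum(len(by_axis[a]) for a in mv_parts),
            radial_of_means=_norm_of_means(vec),
            flags=flags,
        )
    else:
        warnings.warn("no gantry/collimator/couch records: iso_mv absent")
    for name, axis in (("iso_kv", "kv_imager"), ("iso_ir", "infrared")):
        if axis not in means:
            warnings.warn(f"no {axis} records: {name} absent")
            continue
        vec = means[axis]
        flags = ("absent-contributed-zero",) if any(v is None for v in vec.translations()) else ()
        out[name] = ComponentUncertainty(
            name=name,
            utype="systematic",
            per_axis=vec,
            radial=_norm_of_means(vec),
            n=len(by_axis[axis]),
            radial_of_means=_norm_of_means(vec),
            flags=flags,
        )
    # per-axis-type spreads, useful for QA trending reports
    out["_wl_sd"] = sds  # type: ignore[assignment]
    return out


def couch_sag_component(
    records: Sequence[CouchSagRecord],
    policy: str = "worst_case",
    at: Optional[tuple] = None,
) -> ComponentUncertainty:
    """Couch-sag systematic ΣC from the phantom table.

    ``worst_case`` selects the record with maximal radial sag, breaking ties
    by larger load then larger angle; ``at_angle`` selects the record at
    ``at=(load, angle)`` exactly.
    """
    records = list(records)
    if not records:
        raise ValidationError("couch_sag_component requires at least one record")
    if policy == "worst_case":
        rec = max(records, key=lambda r: (radial(r.sag), r.load, r.angle))
    elif policy == "at_angle":
        if at is None:
            raise ValidationError("policy 'at_angle' requires at=(load, angle)")
        matches = [r for r in records if r.load == at[0] and r.angle == at[1]]
        if not matches:
            raise ValidationError(f"no couch-sag record at load={at[0]}, angle={at[1]}")
        rec = matches[0]
    else:
        raise ValidationError(f"unknown policy {policy!r}")
    flags = ("absent-contributed-zero",) if not rec.sag.is_complete() else ()
    return ComponentUncertainty(
        name="couch_sag",
        utype="systematic",
        per_axis=rec.sag,
        radial=radial(rec.sag),
        n=len(records),
        radial_of_means=radial(rec.sag),
        flags=flags,
    )


def summaries_by_axis(records: Iterable[SetupRecord], stage: str = "XC", ddof: int = 1) -> dict:
    """Per-axis :class:`AxisSummary` for one stage, plus a ``radial`` entry
    (no p-value: the radial is a magnitude and has no signed null)."""
    recs = [r for r in records if (r.stage == stage or (stage == "XV" and r.stage == "XV2"))]
    if not recs:
        return {}
    out = {}
    for a in AXES:
        out[a] = axis_summary([getattr(r.shift, a) for r in recs], ddof=ddof)
    radials = [radial(r.shift) for r in recs]
    arr = np.asarray(radials)
    out["radial"] = AxisSummary(
        mean=float(arr.mean()),
        sd=float(arr.std(ddof=ddof)) if arr.size > ddof else None,
        p_value=None,
        min=float(arr.min()),
        max=float(arr.max()),
        n=int(arr.size),
        flags=("magnitude",),
    )
    return out
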