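"""Synthetic cohort generator with known ground truth.

Clinical per-fraction shift databases are rarely shareable, so every
estimator in this package is exercised against simulated cohorts whose
generative parameters are known exactly.  The generative model mirrors the
measurement chain of a frameless 6D X-ray-guided workflow:

* each treatment (isocenter) carries a static per-axis mask bias drawn from a
  zero-mean normal with spread ``mask_sd`` — the immobilization-mask
  systematic, which varies between patients;
* every fraction adds the infrared-frame systematic ``frame_systematic``,
  per-fraction repositioning noise (``setup_sd``) and X-ray registration
  noise (``xray_sd``) to form the XC shift;
* when the XC shift exceeds the gating tolerance (0.7 mm / 1.0° by default)
  the couch is corrected and a verification image (XV) is taken whose
  residual is the localizer systematic plus fresh registration noise.

Winston-Lutz QA offsets are drawn per rotation axis from
normal(mean, sd); the couch-sag phantom study is a deterministic lookup
table, reproduced verbatim.

Everything is fully determined by ``CohortTruth.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .records import (
    AXES,
    CouchSagRecord,
    DEFAULT_ROT_TOL_DEG,
    DEFAULT_TRANS_TOL_MM,
    ISO_AXES,
    IsoOffsetRecord,
    SetupRecord,
    ShiftVector6D,
    ValidationError,
    within_tolerance,
)

# Study-scale defaults: 49 treatments over 35 patients, 1/3/5 fractions each,
# 203 XC setups in total.
_DEFAULT_FRACTIONS: tuple = tuple([5] * 30 + [3] * 17 + [1] * 2)

#: Default phantom couch-sag table: per-axis deflection (mm) and pitch/roll
#: (degrees) versus load (kg) and couch angle; yaw is not measurable with the
#: optical phantom and is stored absent.
DEFAULT_COUCH_SAG_TABLE: tuple = tuple(
    CouchSagRecord(load, angle, ShiftVector6D(lat, lon, vert, pitch, roll, None))
    for load, angle, lat, lon, vert, pitch, roll in [
        (0, 0, 0.01, 0.01, 0.01, 0.30, -0.10),
        (0, 45, -0.20, 0.60, -0.30, 0.40, -0.10),
        (0, 315, 0.20, 0.04, -0.75, 0.10, 0.10),
        (10, 0, 0.01, 0.01, 0.01, 0.20, -0.10),
        (10, 45, 0.00, 0.60, -0.30, 0.30, -0.10),
        (10, 315, 0.30, 0.07, -0.78, 0.00, 0.10),
        (50, 0, 0.01, 0.01, 0.01, 0.20, -0.10),
        (50, 45, 0.25, 0.50, -0.30, 0.30, -0.10),
        (50, 315, 0.48, 0.08, -0.78, 0.00, 0.10),
        (70, 0, 0.01, 0.01, 0.01, 0.10, -0.10),
        (70, 45, 0.01, 0.64, -0.20, 0.30, -0.10),
        (70, 90, -0.25, 0.37, -0.10, 0.00, 0.10),
        (70, 270, 0.40, -0.97, -0.29, 0.30, 0.00),
        (70, 315, 0.85, 0.01, -0.68, -0.10, 0.20),
    ]
)

#: Default Winston-Lutz generative parameters per rotation axis:
#: (mean, sd) per translational axis; ``None`` = not measurable on that axis.
DEFAULT_WL_MEAN: Mapping[str, tuple] = {
    "gantry": (0.27, 0.24, 0.34),
    "collimator": (0.32, 0.24, None),
    "couch_rotation": (0.32, 0.22, None),
    "kv_imager": (0.15, -0.40, 0.21),
    "infrared": (0.02, 0.02, 0.02),
}
DEFAULT_WL_SD: Mapping[str, tuple] = {
    "gantry": (0.27, 0.24, 0.34),
    "collimator": (0.21, 0.14, None),
    "couch_rotation": (0.21, 0.13, None),
    "kv_imager": (0.80, 0.16, 0.09),
    "infrared": (0.01, 0.01, 0.01),
}


@dataclass(frozen=True)
class CohortTruth:
    """Ground-truth generative parameters for one synthetic cohort.

    Per-axis tuples are ordered (lat, long, vert, pitch, roll, yaw) in
    mm / degrees.  Defaults reproduce the statistical structure of a
    49-treatment, 203-fraction cranial SRS/SRT cohort: mask-bias spreads of
    1-2 mm, per-fraction repositioning noise below 0.5 mm / 0.35°, and
    registration noise of ~0.25 mm / 0.25°.
    """

    n_treatments: int = 49
    fractions_per_treatment: Sequence[int] = _DEFAULT_FRACTIONS
    frame_systematic: ShiftVector6D = ShiftVector6D(0.18, 0.25, -1.27, -0.32, 0.18, 0.47)
    localizer_systematic: ShiftVector6D = ShiftVector6D(-0.03, -0.01, 0.03, -0.03, 0.00, -0.01)
    mask_sd: tuple = (1.2, 2.2, 1.9, 0.80, 0.90, 0.90)
    setup_sd: tuple = (0.42, 0.46, 0.20, 0.30, 0.33, 0.32)
    xray_sd: tuple = (0.25, 0.26, 0.21, 0.25, 0.24, 0.24)
    wl_mean: Mapping[str, tuple] = field(default_factory=lambda: dict(DEFAULT_WL_MEAN))
    wl_sd: Mapping[str, tuple] = field(default_factory=lambda: dict(DEFAULT_WL_SD))
    couch_sag_table: Sequence[CouchSagRecord] = DEFAULT_COUCH_SAG_TABLE
    trans_tol: float = DEFAULT_TRANS_TOL_MM
    rot_tol: float = DEFAULT_ROT_TOL_DEG
    force_xv: bool = False
    n_patients: int = 35
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_treatments < 1:
            raise ValidationError("n_treatments must be >= 1")
        if len(self.fractions_per_treatment) < self.n_treatments:
            raise ValidationError("fractions_per_treatment shorter than n_treatments")
        if any(f not in (1, 3, 5) for f in self.fractions_per_treatment):
            raise ValidationError("fractions_per_treatment entries must be in {1, 3, 5}")
        for name in ("mask_sd", "setup_sd", "xray_sd"):
            if any(s < 0 for s in getattr(self, name)):
                raise ValidationError(f"{name} spreads must be >= 0")

    def with_seed(self, seed: int) -> "CohortTruth":
        return replace(self, seed=seed)


def _draw6(rng: np.random.Generator, mean: ShiftVector6D, sd: Sequence[float]) -> ShiftVector6D:
    vals = [
        (getattr(mean, a) or 0.0) + (rng.normal(0.0, s) if s > 0 else 0.0)
        for a, s in zip(AXES, sd)
    ]
    return ShiftVector6D(*vals)


def generate_cohort(truth: CohortTruth):
    """Simulate per-fraction XC/XV setup shifts for one cohort.

    Returns ``(records, mask_truth)`` where ``mask_truth`` maps each
    treatment id to its true static mask bias.  An XV record is emitted for a
    fraction only when its XC shift fails the gating tolerance (unless
    ``truth.force_xv``), mirroring the clinical workflow in which infrared
    positioning occasionally suffices on its own.
    """
    rng = np.random.default_rng(truth.seed)
    zero = ShiftVector6D.zero()
    records: list[SetupRecord] = []
    mask_truth: dict[str, ShiftVector6D] = {}
    # Deterministic treatment -> patient map: some patients have several
    # isocenters, so the first patients carry two treatments each.
    n_doubles = max(0, truth.n_treatments - truth.n_patients)
    for t in range(truth.n_treatments):
        tid = f"T{t + 1:03d}"
        pid = f"P{(t // 2 if t < 2 * n_doubles else t - n_doubles) + 1:03d}"
        m_t = _draw6(rng, zero, truth.mask_sd)
        mask_truth[tid] = m_t
        for frac in range(1, truth.fractions_per_treatment[t] + 1):
            setup_noise = _draw6(rng, zero, truth.setup_sd)
            reg_noise = _draw6(rng, zero, truth.xray_sd)
            xc = m_t + truth.frame_systematic + setup_noise + reg_noise
            records.append(SetupRecord(pid, tid, frac, "XC", xc))
            if truth.force_xv or not within_tolerance(xc, truth.trans_tol, truth.rot_tol):
                xv = truth.localizer_systematic + _draw6(rng, zero, truth.xray_sd)
                records.append(SetupRecord(pid, tid, frac, "XV", xv))
    return records, mask_truth


def generate_wl_log(truth: CohortTruth, n_sessions: int) -> list[IsoOffsetRecord]:
    """Simulate ``n_sessions`` monthly Winston-Lutz QA sessions.

    Each session yields one offset record per rotation axis / imaging system,
    drawn per translational axis from normal(mean, sd); axes that are not
    measurable for a given rotation stay absent.
    """
    if n_sessions < 1:
        raise ValidationError("n_sessions must be >= 1")
    # Independent stream so WL draws do not perturb the cohort stream.
    rng = np.random.default_rng([truth.seed, 1])
    records = []
    for session in range(1, n_sessions + 1):
        date = f"S{session:03d}"
        for axis in ISO_AXES:
            mean = truth.wl_mean[axis]
            sd = truth.wl_sd[axis]
            vals = [
                None if m is None else m + (rng.normal(0.0, s) if s and s > 0 else 0.0)
                for m, s in zip(mean, sd)
            ]
            records.append(IsoOffsetRecord(axis=axis, offset=ShiftVector6D(*vals), date=date))
    return records


def generate_couch_sag(truth: CohortTruth) -> list[CouchSagRecord]:
    """Emit the configured (load, angle) sag grid verbatim — the phantom
    study is a deterministic lookup, not a random process."""
    return list(truth.couch_sag_table)
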