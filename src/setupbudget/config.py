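"""Run configuration with documented defaults.

Defaults reproduce the standard clinical analysis choices: gating tolerance
0.7 mm / 1.0°, treatment-level grouping, sample SDs (ddof=1), radial
combination basis, pooled σXR convention, coverage factor k = 2.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields, replace
from pathlib import Path
from typing import Sequence

import yaml

from .records import DEFAULT_ROT_TOL_DEG, DEFAULT_TRANS_TOL_MM, ValidationError
from .propagate import BASES, DEFAULT_AFTER_XC_COMPONENTS


@dataclass(frozen=True)
class RunConfig:
    trans_tol_mm: float = DEFAULT_TRANS_TOL_MM
    rot_tol_deg: float = DEFAULT_ROT_TOL_DEG
    group_by: str = "treatment_id"  # or "patient_id"
    ddof: int = 1
    xray_sd_convention: str = "pooled"  # or "sd_of_treatment_means"
    basis: str = "radial"  # or "per_axis"
    after_xc_components: Sequence[str] = DEFAULT_AFTER_XC_COMPONENTS
    couch_sag_policy: str = "worst_case"
    k: float = 2.0
    seed: int = 0
    delimiter: str = ","

    def __post_init__(self) -> None:
        if self.trans_tol_mm <= 0 or self.rot_tol_deg <= 0:
            raise ValidationError("tolerances must be positive")
        if self.group_by not in ("treatment_id", "patient_id"):
            raise ValidationError("group_by must be treatment_id or patient_id")
        if self.ddof not in (0, 1):
            raise ValidationError("ddof must be 0 or 1")
        if self.basis not in BASES:
            raise ValidationError(f"basis must be one of {BASES}")
        if self.xray_sd_convention not in ("pooled", "sd_of_treatment_means"):
            raise ValidationError("unknown xray_sd_convention")
        if self.k <= 0:
            raise ValidationError("k must be > 0")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config key(s): {sorted(unknown)}")
        if "after_xc_components" in raw:
            raw["after_xc_components"] = tuple(raw["after_xc_components"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["after_xc_components"] = list(self.after_xc_components)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    def replace(self, **kw) -> "RunConfig":
        return replace(self, **kw)
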