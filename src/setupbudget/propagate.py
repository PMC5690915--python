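"""Combination of uncertainty components into cumulative uncertainties (CU).

Two combination rules are implemented:

* the *model* rule — systematic components add linearly (as absolute
  magnitudes; signed cancellation across independent devices is physically
  unjustified) and random components add in quadrature:

      CU_model = Σ_i |Σ_i|  +  sqrt( Σ_j σ_j² )

* the *GUM* rule — every component, systematic or random, adds in
  quadrature, with an expanded uncertainty k · CU_GUM (k = 2 by default,
  ~95% coverage for a normal quantity):

      CU_GUM = sqrt( Σ_i Σ_i² + Σ_j σ_j² )

By the norm inequality ‖v‖₁ ≥ ‖v‖₂, CU_model ≥ CU_GUM for every
non-negative budget.

The canonical combination basis is the per-component *radial* magnitude (a
single mm number per component).  A ``per_axis`` basis — combine per
translational axis first, then take the radial of the per-axis results — is
provided as an alternative because published cumulative values cannot always
be attributed to one basis unambiguously.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .records import TRANSLATION_AXES, ValidationError
from .decompose import ComponentUncertainty

#: Components surviving the X-ray correction: device systematics that imaging
#: of the patient cannot see, plus the registration noise of the imaging
#: chain itself.
DEFAULT_AFTER_XC_COMPONENTS = (
    "frame",
    "localizer",
    "couch_sag",
    "iso_mv",
    "iso_kv",
    "iso_ir",
    "xray",
)

STAGES = ("before_XC", "after_XC")
BASES = ("radial", "per_axis")


@dataclass(frozen=True)
class UncertaintyBudget:
    """Ordered collection of components entering one CU calculation."""

    components: tuple
    stage: str = "before_XC"
    basis: str = "radial"

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValidationError(f"stage must be one of {STAGES}")
        if self.basis not in BASES:
            raise ValidationError(f"basis must be one of {BASES}")
        names = [c.name for c in self.components]
        if len(names) != len(set(names)):
            raise ValidationError(f"component names must be unique, got {names}")
        if self.stage == "after_XC":
            bad = [c.name for c in self.components if c.corrected_by_xray]
            if bad:
                raise ValidationError(f"after_XC budget may not contain X-ray-corrected components {bad}")

    @property
    def systematics(self) -> tuple:
        return tuple(c for c in self.components if c.utype == "systematic")

    @property
    def randoms(self) -> tuple:
        return tuple(c for c in self.components if c.utype == "random")


@dataclass(frozen=True)
class CumulativeResult:
    """Cumulative uncertainty under both combination rules, in mm."""

    systematic_sum: float
    random_quadrature: float
    cu_model: float
    cu_gum: float
    cu_gum_expanded: float
    k: float = 2.0
    stage: str = "before_XC"
    basis: str = "radial"
    component_names: tuple = ()

    def as_dict(self) -> dict:
        return {
            "systematic_sum": self.systematic_sum,
            "random_quadrature": self.random_quadrature,
            "cu_model": self.cu_model,
            "cu_gum": self.cu_gum,
            "cu_gum_expanded": self.cu_gum_expanded,
            "k": self.k,
            "stage": self.stage,
            "basis": self.basis,
        }


def combine_linear(systematics: Iterable[float]) -> float:
    """Arithmetic sum of systematic magnitudes (linear combination)."""
    return float(sum(systematics))


def combine_quadrature(randoms: Iterable[float]) -> float:
    """Square root of the sum of squares of random spreads."""
    vals = list(randoms)
    if any(v < 0 for v in vals):
        raise ValidationError("spreads must be >= 0")
    return math.sqrt(sum(v * v for v in vals))


def _axis_magnitudes(comp: ComponentUncertainty) -> list:
    return [abs(getattr(comp.per_axis, a) or 0.0) for a in TRANSLATION_AXES]


def cumulative(budget: UncertaintyBudget, k: float = 2.0) -> CumulativeResult:
    """Evaluate both combination rules on one budget.

    In the ``radial`` basis each component contributes its radial magnitude.
    In the ``per_axis`` basis systematics add linearly per translational axis
    and randoms in quadrature per axis; the reported scalars are the radials
    of the per-axis results.  Under either basis ``cu_model =
    systematic_sum + random_quadrature`` and ``cu_model >= cu_gum``.
    """
    if k <= 0:
        raise ValidationError("k must be > 0")
    if not budget.components:
        warnings.warn("empty budget: cumulative uncertainty is zero")
        return CumulativeResult(0.0, 0.0, 0.0, 0.0, 0.0, k, budget.stage, budget.basis)
    if budget.basis == "radial":
        sys_sum = combine_linear(abs(c.radial) for c in budget.systematics)
        rand_quad = combine_quadrature(c.radial for c in budget.randoms)
        gum = combine_quadrature(c.radial for c in budget.components)
    else:
        sys_axis = [combine_linear(m) for m in zip(*(_axis_magnitudes(c) for c in budget.systematics))] or [0.0] * 3
        rand_axis = [combine_quadrature(m) for m in zip(*(_axis_magnitudes(c) for c in budget.randoms))] or [0.0] * 3
        gum_axis = [combine_quadrature(m) for m in zip(*(_axis_magnitudes(c) for c in budget.components))]
        sys_sum = combine_quadrature(sys_axis)
        rand_quad = combine_quadrature(rand_axis)
        gum = combine_quadrature(gum_axis)
    return CumulativeResult(
        systematic_sum=sys_sum,
        random_quadrature=rand_quad,
        cu_model=sys_sum + rand_quad,
        cu_gum=gum,
        cu_gum_expanded=k * gum,
        k=k,
        stage=budget.stage,
        basis=budget.basis,
        component_names=tuple(c.name for c in budget.components),
    )


def cumulative_model(budget: UncertaintyBudget) -> float:
    """Model-rule CU: linear systematics + quadrature randoms."""
    return cumulative(budget).cu_model


def cumulative_gum(budget: UncertaintyBudget, k: float = 2.0) -> CumulativeResult:
    """GUM-rule CU (all components in quadrature) with k-expansion."""
    return cumulative(budget, k=k)


def per_treatment_cu(
    shared: Mapping[str, ComponentUncertainty],
    per_treatment: Mapping[str, tuple],
    k: float = 2.0,
    basis: str = "radial",
    after_xc_components: Sequence[str] = DEFAULT_AFTER_XC_COMPONENTS,
) -> tuple:
    """Per-treatment before-XC CU table plus the single after-XC result.

    ``shared`` maps component name -> cohort-level component (frame,
    localizer, xray, couch_sag, iso_*); ``per_treatment`` maps treatment ->
    (mask, setup) from :func:`setupbudget.decompose.per_treatment_stats`.
    The before-XC budget of a treatment holds its own mask systematic and
    setup random on top of the shared components; the after-XC budget holds
    only uncorrected shared components and is therefore identical for every
    treatment.

    Returns ``(DataFrame indexed by treatment, after_XC CumulativeResult)``.
    """
    shared_before = [c for name, c in shared.items() if not name.startswith("_")]
    rows = {}
    for tid, (mask, setup) in per_treatment.items():
        budget = UncertaintyBudget(tuple([mask, setup] + shared_before), stage="before_XC", basis=basis)
        res = cumulative(budget, k=k)
        rows[tid] = {
            "n_fractions": mask.n,
            "systematic_sum_mm": res.systematic_sum,
            "random_quadrature_mm": res.random_quadrature,
            "cu_model_mm": res.cu_model,
            "cu_gum_mm": res.cu_gum,
            "cu_gum_expanded_mm": res.cu_gum_expanded,
        }
    missing = [n for n in after_xc_components if n not in shared]
    if missing:
        warnings.warn(f"after-XC components missing from decomposition: {missing}")
    after_budget = UncertaintyBudget(
        tuple(shared[n] for n in after_xc_components if n in shared),
        stage="after_XC",
        basis=basis,
    )
    after = cumulative(after_budget, k=k)
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "treatment_id"
    return df, after
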