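"""Statsmodels-style front end: a model object built from record streams
whose ``fit()`` returns a results object carrying component estimates,
per-axis summaries, cumulative uncertainties and a ``summary()`` table.

Typical use::

    from setupbudget import SetupUncertaintyModel
    model = SetupUncertaintyModel.from_csv("setup_shifts.csv",
                                           wl_path="wl_qa.csv",
                                           couch_path="couch_sag.csv")
    res = model.fit()
    print(res.summary())
    res.cu_table          # per-treatment cumulative uncertainty
    res.margin_mm         # after-XC model CU rounded to 0.1 mm
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import pandas as pd

from .config import RunConfig
from .decompose import (
    AxisSummary,
    ComponentUncertainty,
    couch_sag_component,
    frame_systematic,
    localizer_and_xray,
    per_treatment_stats,
    summaries_by_axis,
    winston_lutz_components,
)
from .propagate import CumulativeResult, per_treatment_cu
from .records import (
    AXES,
    CouchSagRecord,
    IsoOffsetRecord,
    SetupRecord,
    ShiftVector6D,
    ValidationError,
    radial,
    read_couch_sag_table,
    read_setup_table,
    read_wl_table,
)
from .reporting import ReportBundle, components_frame, histogram, summaries_frame


class SetupUncertaintyModel:
    """Setup-uncertainty decomposition and propagation model.

    Parameters
    ----------
    setup_records
        Per-fraction XC/XV shift records.
    wl_records
        Winston-Lutz QA log (optional; isocentricity components are absent
        without it).
    couch_records
        Couch-sag phantom table (optional).
    config
        Analysis conventions; defaults are the standard clinical choices.
    """

    def __init__(
        self,
        setup_records: Sequence[SetupRecord],
        wl_records: Optional[Sequence[IsoOffsetRecord]] = None,
        couch_records: Optional[Sequence[CouchSagRecord]] = None,
        config: Optional[RunConfig] = None,
    ) -> None:
        self.setup_records = list(setup_records)
        self.wl_records = list(wl_records) if wl_records else []
        self.couch_records = list(couch_records) if couch_records else []
        self.config = config or RunConfig()
        if not self.setup_records:
            raise ValidationError("at least one setup record is required")

    @classmethod
    def from_csv(
        cls,
        setup_path,
        wl_path=None,
        couch_path=None,
        config: Optional[RunConfig] = None,
    ) -> "SetupUncertaintyModel":
        cfg = config or RunConfig()
        return cls(
            read_setup_table(setup_path, cfg.delimiter),
            read_wl_table(wl_path, cfg.delimiter) if wl_path else None,
            read_couch_sag_table(couch_path, cfg.delimiter) if couch_path else None,
            cfg,
        )

    @classmethod
    def from_dataframe(
        cls,
        setup_df: pd.DataFrame,
        wl_records=None,
        couch_records=None,
        config: Optional[RunConfig] = None,
    ) -> "SetupUncertaintyModel":
        """Build from a setup-shift DataFrame with the standard columns
        (patient_id, treatment_id, fraction, stage, lat_mm, ..., yaw_deg)."""
        records = [
            SetupRecord(
                str(r.patient_id),
                str(r.treatment_id),
                int(r.fraction),
                str(r.stage),
                ShiftVector6D(r.lat_mm, r.long_mm, r.vert_mm, r.pitch_deg, r.roll_deg, r.yaw_deg),
            )
            for r in setup_df.itertuples(index=False)
        ]
        return cls(records, wl_records, couch_records, config)

    def fit(self) -> "SetupUncertaintyResults":
        cfg = self.config
        per_treatment = per_treatment_stats(self.setup_records, group_by=cfg.group_by, ddof=cfg.ddof)
        shared: dict[str, ComponentUncertainty] = {}
        shared["frame"] = frame_systematic(self.setup_records)
        xv = [r for r in self.setup_records if r.stage in ("XV", "XV2")]
        if len(xv) >= 2:
            loc, xr = localizer_and_xray(self.setup_records, convention=cfg.xray_sd_convention, ddof=cfg.ddof)
            shared["localizer"] = loc
            shared["xray"] = xr
        if self.couch_records:
            shared["couch_sag"] = couch_sag_component(self.couch_records, policy=cfg.couch_sag_policy)
        wl_sd: Mapping = {}
        if self.wl_records:
            iso = winston_lutz_components(self.wl_records, ddof=cfg.ddof)
            wl_sd = iso.pop("_wl_sd", {})
            shared.update(iso)
        cu_table, after_xc = per_treatment_cu(
            shared,
            per_treatment,
            k=cfg.k,
            basis=cfg.basis,
            after_xc_components=cfg.after_xc_components,
        )
        summaries = {
            "XC": summaries_by_axis(self.setup_records, "XC", ddof=cfg.ddof),
            "XV": summaries_by_axis(self.setup_records, "XV", ddof=cfg.ddof),
        }
        summaries = {k: v for k, v in summaries.items() if v}
        return SetupUncertaintyResults(
            model=self,
            per_treatment=per_treatment,
            shared_components=shared,
            wl_sd=wl_sd,
            summaries=summaries,
            cu_table=cu_table,
            after_xc=after_xc,
        )


@dataclass
class SetupUncertaintyResults:
    """Fitted component estimates, summaries and cumulative uncertainties."""

    model: SetupUncertaintyModel
    per_treatment: Mapping[str, tuple]
    shared_components: Mapping[str, ComponentUncertainty]
    wl_sd: Mapping
    summaries: Mapping[str, Mapping[str, AxisSummary]]
    cu_table: pd.DataFrame
    after_xc: CumulativeResult

    @property
    def margin_mm(self) -> float:
        """PTV-margin recommendation: after-XC model CU rounded to 0.1 mm."""
        return round(self.after_xc.cu_model, 1)

    def component_table(self) -> pd.DataFrame:
        """Nine-row cohort-level component table.

        The mask row summarizes the spread across treatments of the
        per-treatment mean shifts (the mask-bias population); the setup row
        is the across-treatment mean of the per-treatment SDs.
        """
        import numpy as np

        comps = []
        masks = [m for m, _ in self.per_treatment.values()]
        setups = [s for _, s in self.per_treatment.values()]
        if masks:
            mask_mat = np.array([[getattr(m.per_axis, a) or 0.0 for a in AXES] for m in masks])
            mask_row = ComponentUncertainty(
                name="mask",
                utype="systematic",
                per_axis=ShiftVector6D(*(mask_mat.std(axis=0, ddof=1) if len(masks) > 1 else mask_mat[0])),
                radial=float(np.mean([m.radial for m in masks])),
                n=len(masks),
                corrected_by_xray=True,
                flags=("cohort-spread-of-treatment-means",),
            )
            setup_mat = np.array([[getattr(s.per_axis, a) or 0.0 for a in AXES] for s in setups])
            setup_row = ComponentUncertainty(
                name="setup",
                utype="random",
                per_axis=ShiftVector6D(*np.abs(setup_mat.mean(axis=0))),
                radial=float(np.mean([s.radial for s in setups])),
                n=len(setups),
                corrected_by_xray=True,
                flags=("cohort-mean-of-treatment-sds",),
            )
            comps.extend([mask_row, setup_row])
        order = ("frame", "localizer", "xray", "iso_mv", "iso_kv", "iso_ir", "couch_sag")
        comps.extend(self.shared_components[n] for n in order if n in self.shared_components)
        return components_frame(comps)

    def to_bundle(self, bin_width_mm: float = 0.5, bin_width_deg: float = 0.25) -> ReportBundle:
        recs = self.model.setup_records
        hists = {}
        for stage in ("XC", "XV"):
            sel = [r for r in recs if r.stage == stage or (stage == "XV" and r.stage == "XV2")]
            if not sel:
                continue
            for a in AXES:
                width = bin_width_mm if a in AXES[:3] else bin_width_deg
                hists[f"{stage}_{a}"] = histogram([getattr(r.shift, a) for r in sel], width)
            hists[f"{stage}_radial"] = histogram([radial(r.shift) for r in sel], bin_width_mm)
        n_records = {
            "XC": sum(r.stage == "XC" for r in recs),
            "XV": sum(r.stage in ("XV", "XV2") for r in recs),
            "treatments": len(self.per_treatment),
        }
        return ReportBundle(
            components=self.component_table(),
            summaries=summaries_frame(self.summaries),
            cu_table=self.cu_table,
            after_xc=self.after_xc,
            histograms=hists,
            n_records=n_records,
        )

    def summary(self) -> str:
        """Human-readable fit summary (2-decimal rounding)."""
        lines = [
            "Setup-uncertainty model fit",
            "===========================",
            f"treatments: {len(self.per_treatment)}   "
            f"XC records: {sum(r.stage == 'XC' for r in self.model.setup_records)}   "
            f"XV records: {sum(r.stage in ('XV', 'XV2') for r in self.model.setup_records)}",
            "",
            "Components (cohort level)",
            self.component_table().round(2).to_string(index=False),
            "",
            "Cumulative uncertainty before XC (per treatment):",
            f"  model CU mean ± SD: {self.cu_table['cu_model_mm'].mean():.2f} ± "
            f"{self.cu_table['cu_model_mm'].std(ddof=1):.2f} mm "
            f"(range {self.cu_table['cu_model_mm'].min():.2f}-{self.cu_table['cu_model_mm'].max():.2f})",
            f"  GUM CU mean ± SD:   {self.cu_table['cu_gum_mm'].mean():.2f} ± "
            f"{self.cu_table['cu_gum_mm'].std(ddof=1):.2f} mm",
            "",
            "Cumulative uncertainty after XC (treatment-independent):",
            f"  model CU: {self.after_xc.cu_model:.2f} mm",
            f"  GUM CU:   {self.after_xc.cu_gum:.2f} mm   "
            f"expanded (k={self.after_xc.k:g}): {self.after_xc.cu_gum_expanded:.2f} mm",
            f"  PTV margin recommendation: {self.margin_mm:.1f} mm",
        ]
        return "\n".join(lines)
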