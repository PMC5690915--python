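"""Tables, histograms and plain-text report rendering for pipeline outputs.

Machine-readable CSVs keep full float precision; the human-readable report
rounds to two decimals (the working precision of mm/degree shift tables).
Reports are pure functions of their inputs — no timestamps inside data
files — so re-running on the same inputs is byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .records import AXES, ValidationError
from .decompose import AxisSummary, ComponentUncertainty
from .propagate import CumulativeResult


def histogram(values: Sequence[float], bin_width: float) -> pd.DataFrame:
    """Half-open bins ``[lo, lo + w)`` anchored at the origin.

    Bin edges sit at integer multiples of ``bin_width`` so that zero is
    always an edge; counts conserve the number of input values.  Empty input
    yields an empty table.
    """
    if bin_width <= 0:
        raise ValidationError("bin_width must be > 0")
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        return pd.DataFrame(columns=["bin_lo", "bin_hi", "count"])
    idx = np.floor(arr / bin_width).astype(int)
    lo = np.arange(idx.min(), idx.max() + 1)
    counts = np.bincount(idx - idx.min(), minlength=lo.size)
    df = pd.DataFrame(
        {"bin_lo": lo * bin_width, "bin_hi": (lo + 1) * bin_width, "count": counts}
    )
    return df[df["count"] > 0].reset_index(drop=True)


@dataclass
class ReportBundle:
    """Everything a report needs: component rows, per-axis summaries,
    per-treatment CU table, the after-XC result, and histogram specs."""

    components: pd.DataFrame
    summaries: pd.DataFrame
    cu_table: pd.DataFrame
    after_xc: Optional[CumulativeResult] = None
    histograms: Mapping[str, pd.DataFrame] = field(default_factory=dict)
    n_records: Mapping[str, int] = field(default_factory=dict)


def components_frame(components: Sequence[ComponentUncertainty]) -> pd.DataFrame:
    rows = []
    for c in components:
        row = {"name": c.name, "type": c.utype}
        for a in AXES:
            row[a] = getattr(c.per_axis, a)
        row.update(
            radial_mm=c.radial,
            radial_of_means_mm=c.radial_of_means,
            n=c.n,
            corrected_by_xray=c.corrected_by_xray,
            flags=";".join(c.flags),
        )
        rows.append(row)
    return pd.DataFrame(rows)


def summaries_frame(summaries: Mapping[str, Mapping[str, AxisSummary]]) -> pd.DataFrame:
    """Long-format per-stage, per-axis summary table (Tables 2/3 analogue)."""
    rows = []
    for stage, by_axis in summaries.items():
        for axis, s in by_axis.items():
            rows.append(
                {
                    "stage": stage,
                    "axis": axis,
                    "mean": s.mean,
                    "sd": s.sd,
                    "p_value": s.p_value,
                    "min": s.min,
                    "max": s.max,
                    "n": s.n,
                    "flags": ";".join(s.flags),
                }
            )
    return pd.DataFrame(rows)


def _section(title: str, body: str) -> str:
    return f"{title}\n{'-' * len(title)}\n{body}\n"


def render_report(bundle: ReportBundle, out_dir, plots: bool = False) -> list:
    """Write components.csv, summaries.csv, budget.csv and report.txt (plus
    optional PNG histograms) into ``out_dir``; returns the paths written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    for name, df in (
        ("components.csv", bundle.components),
        ("summaries.csv", bundle.summaries),
        ("budget.csv", bundle.cu_table),
    ):
        path = out / name
        df.to_csv(path, index=name == "budget.csv" and bundle.cu_table.index.name is not None)
        written.append(path)

    parts = ["Setup-uncertainty report", "========================", ""]
    if bundle.n_records:
        counts = ", ".join(f"{k}: {v}" for k, v in bundle.n_records.items())
        parts.append(_section("Record counts", counts))
    for title, df in (
        ("Uncertainty components", bundle.components),
        ("Shift summaries", bundle.summaries),
        ("Per-treatment cumulative uncertainty (before XC)", bundle.cu_table),
    ):
        body = df.round(2).to_string() if len(df) else "no data"
        parts.append(_section(title, body))
    if bundle.after_xc is not None:
        a = bundle.after_xc
        body = (
            f"model CU: {a.cu_model:.2f} mm\n"
            f"GUM CU: {a.cu_gum:.2f} mm\n"
            f"GUM expanded (k={a.k:g}): {a.cu_gum_expanded:.2f} mm\n"
            f"components: {', '.join(a.component_names)}\n"
            f"basis: {a.basis}"
        )
        parts.append(_section("Cumulative uncertainty after XC (treatment-independent)", body))
        parts.append(
            _section(
                "Margin recommendation",
                f"PTV margin from after-XC model CU: {round(a.cu_model, 1):.1f} mm",
            )
        )
    else:
        parts.append(_section("Cumulative uncertainty after XC", "no data"))
    report = out / "report.txt"
    report.write_text("\n".join(parts))
    written.append(report)

    if plots and bundle.histograms:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        for name, hist in bundle.histograms.items():
            fig, ax = plt.subplots(figsize=(4, 3))
            if len(hist):
                width = float(hist["bin_hi"].iloc[0] - hist["bin_lo"].iloc[0])
                ax.bar(hist["bin_lo"], hist["count"], width=width, align="edge", edgecolor="k")
            ax.set_xlabel(name)
            ax.set_ylabel("count")
            fig.tight_layout()
            path = out / f"hist_{name}.png"
            fig.savefig(path)
            plt.close(fig)
            written.append(path)
    return written
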