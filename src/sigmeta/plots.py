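"""Matplotlib diagnostics: forest, volcano and QQ plots."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")  # headless by default; callers may switch backends first

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .meta import QQReport


def forest_plot(forest: pd.DataFrame, ax: plt.Axes | None = None) -> plt.Axes:
    """Forest plot from a :func:`sigmeta.meta.forest_data` table."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 0.5 * len(forest) + 1))
    y = np.arange(len(forest))[::-1]
    for yi, (_, row) in zip(y, forest.iterrows()):
        marker = "D" if row["row"] == "summary" else "s"
        ax.plot([row["ci_low"], row["ci_high"]], [yi, yi], color="k", lw=1)
        ax.plot(row["lfc"], yi, marker, color="k",
                markersize=4 + row["weight_pct"] / 15)
    ax.axvline(0, color="grey", lw=0.8, ls="--")
    ax.set_yticks(y)
    ax.set_yticklabels(forest["dataset_id"])
    ax.set_xlabel("log2 fold-change (95% CI)")
    gene = forest["gene"].iloc[0] if "gene" in forest else ""
    ax.set_title(f"Forest plot {gene}".strip())
    return ax


def volcano_plot(volcano: pd.DataFrame, lfc_cut: float = 1.0,
                 p_cut: float = 0.05, ax: plt.Axes | None = None) -> plt.Axes:
    """Volcano plot of pooled LFC vs −log10 p with the significance cuts."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    called = (volcano["pooled_lfc"].abs() > lfc_cut) & (
        volcano["neg_log10_p"] > -np.log10(p_cut)
    )
    ax.scatter(volcano.loc[~called, "pooled_lfc"], volcano.loc[~called, "neg_log10_p"],
               s=8, color="grey", alpha=0.6)
    ax.scatter(volcano.loc[called, "pooled_lfc"], volcano.loc[called, "neg_log10_p"],
               s=12, color="crimson")
    for x in (-lfc_cut, lfc_cut):
        ax.axvline(x, color="k", lw=0.6, ls=":")
    ax.axhline(-np.log10(p_cut), color="k", lw=0.6, ls=":")
    ax.set_xlabel("pooled log2 fold-change")
    ax.set_ylabel(r"$-\log_{10} p$")
    return ax


def qq_plot(report: QQReport, ax: plt.Axes | None = None) -> plt.Axes:
    """QQ plot of standardized per-gene statistics against N(0, 1)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    ax.scatter(report.theoretical_quantiles, report.statistics, s=6, color="k")
    lim = [report.theoretical_quantiles.min(), report.theoretical_quantiles.max()]
    ax.plot(lim, lim, color="crimson", lw=1)
    ax.set_xlabel("theoretical N(0,1) quantiles")
    ax.set_ylabel("standardized statistics")
    ax.set_title(f"{report.dataset_id} (KS={report.deviation:.3f})")
    return ax
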