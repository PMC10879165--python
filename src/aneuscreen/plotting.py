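"""Diagnostic plots: fold-increase scatter and prevalence-by-age chart."""

from __future__ import annotations

from typing import Sequence

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import pandas as pd

from .screen import EUPLOID, ScreenResult

__all__ = ["fold_scatter", "prevalence_age_plot"]


def fold_scatter(
    results: Sequence[ScreenResult],
    x_chrom: str = "18",
    y_chrom: str = "21",
    ax: plt.Axes | None = None,
) -> plt.Axes:
    """Scatter of per-sample fold-increases on two chromosomes.

    Samples with enough reads and at most one significantly
    overrepresented chromosome are plotted as filled circles; positive
    calls are labelled with their sample ids.
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 6))
    xs, ys, labels = [], [], []
    for r in results:
        if not r.fold or r.call == "ambiguous":
            continue
        xs.append(r.fold[x_chrom])
        ys.append(r.fold[y_chrom])
        labels.append(r.sample_id if r.call != EUPLOID else None)
    ax.scatter(xs, ys, s=12, c="black", alpha=0.6)
    for x, y, lab in zip(xs, ys, labels):
        if lab is not None:
            ax.annotate(lab, (x, y), textcoords="offset points", xytext=(4, 4))
    ax.axhline(1.0, lw=0.5, color="grey")
    ax.axvline(1.0, lw=0.5, color="grey")
    ax.set_xlabel(f"fold-increase chr{x_chrom}")
    ax.set_ylabel(f"fold-increase chr{y_chrom}")
    return ax


def prevalence_age_plot(
    table: pd.DataFrame,
    observed_rate: float,
    overall_modern_rate: float | None = None,
    ax: plt.Axes | None = None,
) -> plt.Axes:
    """Log-scale bar chart of modern rates by maternal age band.

    Overlays the observed premodern rate and, optionally, the overall
    modern rate as dashed reference lines.
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    ax.bar(table["age_band"], table["modern_rate"], color="#808fc0")
    ax.axhline(
        observed_rate, color="tab:blue", ls="--", label="observed premodern"
    )
    if overall_modern_rate is not None:
        ax.axhline(
            overall_modern_rate, color="tab:red", ls="--", label="overall modern"
        )
    ax.set_yscale("log")
    ax.set_ylabel("prevalence (per birth, log scale)")
    ax.set_xlabel("mother's age band")
    ax.legend()
    return ax
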