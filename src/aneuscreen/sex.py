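"""Genetic sex inference from X and Y read fractions.

Shotgun reads from an XY individual place a consistent fraction on the
Y chromosome, while XX individuals show only a small background of
mismapped reads there.  Samples are split into two clusters on the Y
fraction p_y (1-D 2-means); the cluster whose mean is consistent with
background noise is assigned XX, the other XY.  Samples that are too
shallow, or whose p_y lies within two binomial standard deviations of
the midpoint between the cluster means, are left unassigned.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .io_counts import CohortTable

__all__ = ["SexInferenceError", "SexCall", "assign_sex"]


class SexInferenceError(ValueError):
    """Sex inference is impossible on this cohort."""


@dataclass
class SexCall:
    sample_id: str
    p_x: float
    p_y: float
    sex: str  # "XX", "XY" or "unassigned"


def assign_sex(cohort: CohortTable, min_reads: int = 1000) -> list[SexCall]:
    """Cluster the cohort on p_y and assign genetic sex per sample.

    p_x and p_y are fractions of all mapped reads (autosomes + X + Y).
    Raises :class:`SexInferenceError` when no sample in the cohort has any
    X or Y reads (sex chromosomes absent from the input).
    """
    from sklearn.cluster import KMeans

    totals = np.array([p.n_total for p in cohort], dtype=float)
    xy_reads = np.array(
        [p.counts["X"] + p.counts["Y"] for p in cohort], dtype=float
    )
    if xy_reads.sum() == 0:
        raise SexInferenceError("no reads on X or Y anywhere in the cohort")

    p_x = np.divide(
        [p.counts["X"] for p in cohort], totals,
        out=np.zeros(len(cohort)), where=totals > 0,
    )
    p_y = np.divide(
        [p.counts["Y"] for p in cohort], totals,
        out=np.zeros(len(cohort)), where=totals > 0,
    )
    eligible = totals >= min_reads

    calls = [
        SexCall(p.sample_id, float(p_x[i]), float(p_y[i]), "unassigned")
        for i, p in enumerate(cohort)
    ]
    if eligible.sum() < 2:
        return calls

    km = KMeans(n_clusters=2, n_init=10, random_state=0)
    labels = km.fit_predict(p_y[eligible].reshape(-1, 1))
    centers = km.cluster_centers_.ravel()
    low, high = float(centers.min()), float(centers.max())
    if high <= low:  # degenerate split: all p_y identical
        return calls
    midpoint = 0.5 * (low + high)

    idx = np.flatnonzero(eligible)
    for i in idx:
        sd = math.sqrt(midpoint * (1.0 - midpoint) / totals[i])
        if abs(p_y[i] - midpoint) <= 2.0 * sd:
            continue  # within the buffer: leave unassigned
        calls[i].sex = "XX" if p_y[i] < midpoint else "XY"
    return calls
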