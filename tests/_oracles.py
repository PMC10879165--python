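"""Independent reference implementations used only as test oracles.

Everything here is deliberately written from first principles (lgamma
arithmetic, exhaustive summation, grid search) so that it shares no code
path with the package implementation it checks.
"""

from __future__ import annotations

import math
from typing import Mapping, Sequence

import numpy as np


def bb_logpmf(k: int, n: int, a: float, b: float) -> float:
    """Beta-binomial log-pmf via log-gamma identities.

    log C(n,k) + log B(k+a, n-k+b) - log B(a, b)
    """
    if k < 0 or k > n:
        return -math.inf
    lchoose = (
        math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)
    )
    lbeta_num = (
        math.lgamma(k + a) + math.lgamma(n - k + b) - math.lgamma(n + a + b)
    )
    lbeta_den = math.lgamma(a) + math.lgamma(b) - math.lgamma(a + b)
    return lchoose + lbeta_num - lbeta_den


def bb_moments_by_summation(n: int, a: float, b: float) -> tuple[float, float]:
    """Beta-binomial mean and variance by exhaustive pmf summation."""
    ks = np.arange(n + 1)
    pmf = np.exp([bb_logpmf(int(k), n, a, b) for k in ks])
    mean = float((ks * pmf).sum())
    var = float(((ks - mean) ** 2 * pmf).sum())
    return mean, var


def shifted_means(means: Sequence[float], j: int) -> list[float]:
    """Hypothesis means for a trisomy of chromosome j.

    The trisomic chromosome gains half a copy of its content; all
    proportions renormalise by 1/(1 + 0.5*m_j).
    """
    scale = 1.0 + 0.5 * means[j]
    out = [m / scale for m in means]
    out[j] = 1.5 * means[j] / scale
    return out


def posterior_by_enumeration(
    counts: Sequence[int],
    means: Sequence[float],
    concentrations: Sequence[float],
) -> dict[str, float]:
    """Ploidy posterior by direct (non-log) pmf products, uniform prior.

    Hypotheses: 'euploid' plus 'trisomy-<i>' for each chromosome index i
    (1-based, matching autosome naming on toy genomes).
    """
    n = int(sum(counts))
    n_chr = len(counts)
    likes: dict[str, float] = {}

    def product_likelihood(ms: Sequence[float]) -> float:
        out = 1.0
        for k, m, s in zip(counts, ms, concentrations):
            out *= math.exp(bb_logpmf(int(k), n, m * s, (1 - m) * s))
        return out

    likes["euploid"] = product_likelihood(means)
    for j in range(n_chr):
        likes[f"trisomy-{j + 1}"] = product_likelihood(shifted_means(means, j))
    total = sum(likes.values())
    return {h: v / total for h, v in likes.items()}


def toy_loglik(
    counts: Sequence[int],
    means: Sequence[float],
    concentrations: Sequence[float],
) -> float:
    """Log product-likelihood of one hypothesis on a toy genome."""
    n = int(sum(counts))
    return sum(
        bb_logpmf(int(k), n, m * s, (1 - m) * s)
        for k, m, s in zip(counts, means, concentrations)
    )


def binom_pvalue_by_summation(
    k: int, n: int, p: float, alternative: str = "two-sided"
) -> float:
    """Exact binomial test p-value by exhaustive pmf summation.

    Two-sided uses the minimum-likelihood rule: the sum of probabilities
    of all outcomes whose pmf does not exceed that of the observed one
    (with the customary 1+1e-7 relative tolerance for ties).
    """

    def logpmf(j: int) -> float:
        return (
            math.lgamma(n + 1)
            - math.lgamma(j + 1)
            - math.lgamma(n - j + 1)
            + j * math.log(p)
            + (n - j) * math.log1p(-p)
        )

    pmf = np.exp([logpmf(j) for j in range(n + 1)])
    if alternative == "less":
        return float(pmf[: k + 1].sum())
    if alternative == "greater":
        return float(pmf[k:].sum())
    return float(pmf[pmf <= pmf[k] * (1.0 + 1e-7)].sum())


def beta_loglik(a: float, b: float, x: np.ndarray) -> float:
    return float(
        len(x) * (math.lgamma(a + b) - math.lgamma(a) - math.lgamma(b))
        + (a - 1.0) * np.log(x).sum()
        + (b - 1.0) * np.log1p(-x).sum()
    )


def beta_mle_by_grid(
    x: np.ndarray,
    a_range: tuple[float, float],
    b_range: tuple[float, float],
    size: int = 200,
) -> tuple[float, float, float]:
    """Grid-search beta MLE; returns (alpha, beta, loglik at optimum)."""
    grid_a = np.exp(np.linspace(*np.log(a_range), size))
    grid_b = np.exp(np.linspace(*np.log(b_range), size))
    best = (-math.inf, math.nan, math.nan)
    for ga in grid_a:
        for gb in grid_b:
            ll = beta_loglik(ga, gb, x)
            if ll > best[0]:
                best = (ll, ga, gb)
    return best[1], best[2], best[0]
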