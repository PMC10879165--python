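"""Trisomy screening: fold-increases, ploidy posteriors and calls.

A full trisomy adds a third copy of one autosome, enriching its read
proportion by a factor 1.5 / (1 + 0.5 * m_c) relative to the euploid
mean m_c (the extra copy also inflates the total mappable content by
0.5 * m_c, deflating every other chromosome by 1 / (1 + 0.5 * m_c)).
For each sample the screen compares 23 hypotheses — euploid plus one
trisomy per autosome — by the product of beta-binomial likelihoods over
autosomes, with the hypothesis-specific beta means shifted as above and
the per-chromosome concentration alpha+beta preserved.  Posteriors are
computed in log space and normalised with log-sum-exp.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import betabinom, norm

from .dispersion import (
    MIN_SCREEN_READS,
    ProtocolModel,
    ZScoreMatrix,
    beta_binomial_moments,
)
from .io_counts import CohortTable, ReadCountProfile

__all__ = [
    "EUPLOID",
    "trisomy_hypothesis",
    "hypothesis_names",
    "ScreenThresholds",
    "ScreenResult",
    "fold_increase",
    "posterior_ploidy",
    "significance_count",
    "screen",
    "results_to_frame",
]

EUPLOID = "euploid"


def trisomy_hypothesis(chrom: str) -> str:
    return f"trisomy-{chrom}"


def hypothesis_names(autosomes: Sequence[str]) -> list[str]:
    return [EUPLOID] + [trisomy_hypothesis(c) for c in autosomes]


@dataclass(frozen=True)
class ScreenThresholds:
    """Decision gates for :func:`screen`.

    The posterior threshold and fold plausibility window are reporting
    gates layered on top of the posterior; the defaults are deliberately
    conservative and configurable.
    """

    min_screen_reads: int = MIN_SCREEN_READS
    call_threshold: float = 0.99
    fold_bounds: tuple[float, float] = (1.3, 1.7)
    alpha_level: float = 0.05


@dataclass
class ScreenResult:
    """Per-sample screening outcome over the 23 ploidy hypotheses."""

    sample_id: str
    protocol: str
    n_autosomal: int
    call: str
    z: dict[str, float] = field(default_factory=dict)
    fold: dict[str, float] = field(default_factory=dict)
    posterior: dict[str, float] = field(default_factory=dict)
    n_significant: int = 0

    @property
    def called_chromosome(self) -> str | None:
        if self.call.startswith("trisomy-"):
            return self.call.split("-", 1)[1]
        return None


def _hypothesis_shapes(
    model: ProtocolModel,
) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Beta shapes (alpha, beta) for every hypothesis.

    Returns (autosomes, A, B) with A and B of shape (n_hyp, n_autosomes);
    row 0 is the euploid null, row j+1 is trisomy of autosome j.  The
    trisomic chromosome's mean moves to 1.5*m/(1+0.5*m), every other
    chromosome's to m_d/(1+0.5*m); concentrations are preserved.
    """
    autosomes = model.autosomes
    m = np.array([model.mean_prop[c] for c in autosomes])
    s = np.array([model.concentration[c] for c in autosomes])
    n_chr = len(autosomes)
    means = np.tile(m, (n_chr + 1, 1))
    for j in range(n_chr):
        scale = 1.0 + 0.5 * m[j]
        means[j + 1] = m / scale
        means[j + 1, j] = 1.5 * m[j] / scale
    A = means * s
    B = (1.0 - means) * s
    return autosomes, A, B


def _log_likelihoods(
    k: np.ndarray, n: np.ndarray, A: np.ndarray, B: np.ndarray
) -> np.ndarray:
    """Log product-likelihood matrix of shape (n_samples, n_hypotheses)."""
    n_hyp = A.shape[0]
    out = np.empty((k.shape[0], n_hyp))
    n_col = n[:, None]
    for h in range(n_hyp):
        out[:, h] = betabinom.logpmf(k, n_col, A[h], B[h]).sum(axis=1)
    return out


def posterior_ploidy(
    profile: ReadCountProfile,
    model: ProtocolModel,
    prior: Mapping[str, float] | None = None,
) -> dict[str, float]:
    """Normalised posterior over euploid and per-autosome trisomy hypotheses.

    The prior defaults to uniform over the 23 hypotheses. With zero reads
    the likelihood is flat and the posterior equals the prior.
    """
    autosomes, A, B = _hypothesis_shapes(model)
    names = hypothesis_names(autosomes)
    if prior is None:
        log_prior = np.full(len(names), -np.log(len(names)))
    else:
        pvec = np.array([prior[h] for h in names], dtype=float)
        if abs(pvec.sum() - 1.0) > 1e-9 or np.any(pvec < 0):
            raise ValueError("prior must be a probability vector over hypotheses")
        with np.errstate(divide="ignore"):
            log_prior = np.log(pvec)
    k = np.array([[profile.counts[c] for c in autosomes]], dtype=float)
    n = np.array([float(profile.n_autosomal)])
    if n[0] == 0:
        log_post = log_prior
    else:
        log_post = log_prior + _log_likelihoods(k, n, A, B)[0]
    log_post = log_post - logsumexp(log_post)
    return dict(zip(names, np.exp(log_post)))


def fold_increase(
    profile: ReadCountProfile,
    model: ProtocolModel,
    center: str = "mean",
    negatives: ZScoreMatrix | pd.DataFrame | None = None,
) -> dict[str, float]:
    """Observed / expected read proportion per autosome.

    ``center="mean"`` divides by the protocol model's expected proportions;
    ``center="median"`` divides by the per-autosome median proportion of
    the supplied negative (non-carrier) samples.
    """
    autosomes = model.autosomes
    phat = profile.autosomal_proportions()
    if center == "mean":
        center_vec = model.mean_prop
    elif center == "median":
        if negatives is None:
            raise ValueError('center="median" requires negatives')
        frame = negatives.phat if isinstance(negatives, ZScoreMatrix) else negatives
        center_vec = frame.median(axis=0).to_dict()
    else:
        raise ValueError(f"unknown center {center!r}")
    if any(center_vec[c] <= 0 for c in autosomes):
        raise ValueError("centering proportions must be positive")
    return {c: phat[c] / center_vec[c] for c in autosomes}


def significance_count(
    z_row: Mapping[str, float], alpha_level: float = 0.05
) -> int:
    """Number of autosomes significantly overrepresented (one-sided).

    Bonferroni-corrects the one-sided normal test over the autosomes in
    the row: chromosome c counts when Z_c exceeds the upper-tail quantile
    at alpha_level / n_autosomes.
    """
    threshold = norm.isf(alpha_level / len(z_row))
    return int(sum(z > threshold for z in z_row.values()))


def screen(
    cohort: CohortTable,
    models: Mapping[str, ProtocolModel],
    thresholds: ScreenThresholds = ScreenThresholds(),
    prior: Mapping[str, float] | None = None,
) -> list[ScreenResult]:
    """Run the full per-sample trisomy screen over a cohort.

    Decision per sample:

    * fewer than ``min_screen_reads`` autosomal reads -> ``insufficient-reads``
    * more than one autosome significantly overrepresented -> ``ambiguous``
    * else ``trisomy-c`` when that hypothesis' posterior reaches
      ``call_threshold`` and the chromosome's fold-increase falls inside
      ``fold_bounds``; otherwise ``euploid``.
    """
    missing = sorted(cohort.protocols - set(models))
    if missing:
        raise ModelLookupError(f"no fitted model for protocol(s): {missing}")

    results: dict[str, ScreenResult] = {}
    by_protocol: dict[str, list[ReadCountProfile]] = {}
    for p in cohort:
        if p.n_autosomal < thresholds.min_screen_reads:
            results[p.sample_id] = ScreenResult(
                sample_id=p.sample_id,
                protocol=p.protocol,
                n_autosomal=p.n_autosomal,
                call="insufficient-reads",
            )
        else:
            by_protocol.setdefault(p.protocol, []).append(p)

    for protocol, profiles in by_protocol.items():
        model = models[protocol]
        autosomes, A, B = _hypothesis_shapes(model)
        names = hypothesis_names(autosomes)
        if prior is None:
            log_prior = np.full(len(names), -np.log(len(names)))
        else:
            log_prior = np.log(np.array([prior[h] for h in names]))
        k = np.array(
            [[p.counts[c] for c in autosomes] for p in profiles], dtype=float
        )
        n = np.array([float(p.n_autosomal) for p in profiles])
        log_post = log_prior[None, :] + _log_likelihoods(k, n, A, B)
        log_post -= logsumexp(log_post, axis=1, keepdims=True)
        post = np.exp(log_post)

        a0 = np.array([model.alpha[c] for c in autosomes])
        b0 = np.array([model.beta[c] for c in autosomes])
        mean, var = beta_binomial_moments(n[:, None], a0, b0)
        z = (k - mean) / np.sqrt(var)
        m0 = np.array([model.mean_prop[c] for c in autosomes])
        fold = (k / n[:, None]) / m0
        z_threshold = norm.isf(thresholds.alpha_level / len(autosomes))

        for i, p in enumerate(profiles):
            n_sig = int((z[i] > z_threshold).sum())
            tri_post = post[i, 1:]
            best = int(np.argmax(tri_post))
            lo, hi = thresholds.fold_bounds
            if n_sig > 1:
                call = "ambiguous"
            elif (
                tri_post[best] >= thresholds.call_threshold
                and lo <= fold[i, best] <= hi
            ):
                call = trisomy_hypothesis(autosomes[best])
            else:
                call = EUPLOID
            results[p.sample_id] = ScreenResult(
                sample_id=p.sample_id,
                protocol=protocol,
                n_autosomal=int(n[i]),
                call=call,
                z=dict(zip(autosomes, z[i])),
                fold=dict(zip(autosomes, fold[i])),
                posterior=dict(zip(names, post[i])),
                n_significant=n_sig,
            )

    return [results[p.sample_id] for p in cohort]


class ModelLookupError(KeyError):
    """A cohort protocol has no fitted model."""


def results_to_frame(results: Sequence[ScreenResult]) -> pd.DataFrame:
    """Flatten screen results into a calls table.

    One row per sample: call, posterior of the top trisomy hypothesis, and
    the fold/Z of the top chromosome (the called one for positives).
    """
    rows = []
    for r in results:
        if r.posterior:
            tri = {h: p for h, p in r.posterior.items() if h != EUPLOID}
            top_hyp = max(tri, key=tri.get)
            top_chrom = top_hyp.split("-", 1)[1]
            rows.append(
                {
                    "sample": r.sample_id,
                    "protocol": r.protocol,
                    "n_autosomal": r.n_autosomal,
                    "call": r.call,
                    "posterior_euploid": r.posterior[EUPLOID],
                    "top_trisomy": top_hyp,
                    "posterior_top": tri[top_hyp],
                    "fold_top": r.fold[top_chrom],
                    "z_top": r.z[top_chrom],
                    "n_significant": r.n_significant,
                }
            )
        else:
            rows.append(
                {
                    "sample": r.sample_id,
                    "protocol": r.protocol,
                    "n_autosomal": r.n_autosomal,
                    "call": r.call,
                    "posterior_euploid": np.nan,
                    "top_trisomy": "",
                    "posterior_top": np.nan,
                    "fold_top": np.nan,
                    "z_top": np.nan,
                    "n_significant": 0,
                }
            )
    return pd.DataFrame(rows)
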