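"""Per-protocol beta-binomial null models and Z-scores.

The proportion of reads a euploid sample places on autosome ``c`` is
modelled as binomial with a beta-distributed success probability
``p_c ~ Beta(alpha_c, beta_c)``, fitted independently per library
protocol.  The beta absorbs between-library overdispersion (protocol
chemistry, sequencing run, preservation artefacts); the binomial absorbs
counting noise.  A sample's chromosome count ``k`` at autosomal depth
``n`` is then beta-binomial, and its Z-score is the number of
beta-binomial standard deviations separating ``k`` from expectation.

Shape parameters are estimated by maximum likelihood of a beta on the
observed proportions of high-depth panel samples (at least
``min_fit_reads`` autosomal reads, default 10,000), one protocol at a
time.  Screening itself only requires ``min_screen_reads`` (default
1000) autosomal reads.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import digamma, gammaln

from .chromosomes import AUTOSOMES
from .io_counts import CohortTable

__all__ = [
    "ModelFitError",
    "ProtocolModel",
    "ZScoreMatrix",
    "beta_binomial_moments",
    "fit_beta_mle",
    "fit_protocol_model",
    "fit_models",
    "z_scores",
    "save_models",
    "load_models",
]

MIN_FIT_READS = 10_000
MIN_SCREEN_READS = 1_000


class ModelFitError(ValueError):
    """Null-model estimation failed or is unidentifiable."""


def beta_binomial_moments(
    n: int | np.ndarray, alpha: float | np.ndarray, beta: float | np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Exact mean and variance of the beta-binomial distribution.

    mean = n * a / (a + b)
    var  = n * a * b * (a + b + n) / ((a + b)^2 * (a + b + 1))

    Accepts broadcastable arrays; returns (mean, variance).
    """
    n = np.asarray(n, dtype=float)
    a = np.asarray(alpha, dtype=float)
    b = np.asarray(beta, dtype=float)
    if np.any(a <= 0) or np.any(b <= 0):
        raise ValueError("beta-binomial shape parameters must be positive")
    if np.any(n < 0):
        raise ValueError("n must be non-negative")
    s = a + b
    mean = n * a / s
    var = n * a * b * (s + n) / (s**2 * (s + 1.0))
    return mean, var


def fit_beta_mle(
    x: Sequence[float] | np.ndarray, gtol: float = 1e-8
) -> tuple[float, float, bool]:
    """Maximum-likelihood beta fit to proportions in the open interval (0,1).

    Optimises the beta log-likelihood in (log alpha, log beta) with BFGS
    and an analytic gradient, started from method-of-moments estimates.
    Returns ``(alpha, beta, converged)``.

    Raises :class:`ModelFitError` if fewer than two observations are given,
    any observation lies outside (0, 1), or the sample variance is zero
    (overdispersion unidentifiable).
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ModelFitError("beta MLE needs at least two observations")
    if np.any(~np.isfinite(x)) or np.any(x <= 0.0) or np.any(x >= 1.0):
        raise ModelFitError("proportions must lie strictly inside (0, 1)")
    m = float(x.mean())
    v = float(x.var(ddof=1))
    if v <= 0.0:
        raise ModelFitError(
            "all proportions identical: beta dispersion unidentifiable"
        )

    # method-of-moments start; guard against v >= m(1-m) (s0 <= 0)
    s0 = m * (1.0 - m) / v - 1.0
    if s0 <= 0.0:
        s0 = 1.0
    theta0 = np.log([m * s0, (1.0 - m) * s0])

    n_obs = x.size
    sum_log_x = float(np.log(x).sum())
    sum_log_1mx = float(np.log1p(-x).sum())

    def negloglik_and_grad(theta: np.ndarray) -> tuple[float, np.ndarray]:
        a, b = np.exp(theta)
        ll = (
            n_obs * (gammaln(a + b) - gammaln(a) - gammaln(b))
            + (a - 1.0) * sum_log_x
            + (b - 1.0) * sum_log_1mx
        )
        dll_da = n_obs * (digamma(a + b) - digamma(a)) + sum_log_x
        dll_db = n_obs * (digamma(a + b) - digamma(b)) + sum_log_1mx
        # chain rule to log-parameters
        grad = -np.array([a * dll_da, b * dll_db])
        return -ll, grad

    res = minimize(
        negloglik_and_grad,
        theta0,
        jac=True,
        method="BFGS",
        options={"gtol": gtol, "maxiter": 500},
    )
    alpha, beta = np.exp(res.x)
    # convergence on the gradient norm, scaled by the objective magnitude
    # (an absolute norm is unattainable in float64 when |loglik| is large)
    grad_tol = 100.0 * gtol * max(1.0, abs(float(res.fun)))
    converged = bool(res.success) or float(np.linalg.norm(res.jac)) <= grad_tol
    return float(alpha), float(beta), converged


@dataclass
class ProtocolModel:
    """Fitted beta parameters per autosome for one library protocol."""

    protocol: str
    alpha: dict[str, float]
    beta: dict[str, float]
    n_ref: int
    converged: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_ref < 2:
            raise ModelFitError(
                f"protocol {self.protocol!r}: n_ref must be >= 2"
            )
        for c in self.alpha:
            if self.alpha[c] <= 0 or self.beta.get(c, 0.0) <= 0:
                raise ModelFitError(
                    f"protocol {self.protocol!r}: non-positive shape for chr{c}"
                )
        if set(self.alpha) != set(self.beta):
            raise ModelFitError("alpha and beta must cover the same autosomes")

    @property
    def autosomes(self) -> list[str]:
        """Autosome names in canonical order."""
        return [c for c in AUTOSOMES if c in self.alpha] or list(self.alpha)

    @property
    def mean_prop(self) -> dict[str, float]:
        """Expected read proportion per autosome, alpha/(alpha+beta)."""
        return {
            c: self.alpha[c] / (self.alpha[c] + self.beta[c])
            for c in self.autosomes
        }

    @property
    def concentration(self) -> dict[str, float]:
        """alpha+beta per autosome (inverse overdispersion)."""
        return {c: self.alpha[c] + self.beta[c] for c in self.autosomes}


def fit_protocol_model(
    panel: CohortTable,
    protocol: str,
    min_fit_reads: int = MIN_FIT_READS,
    autosomes: Sequence[str] = AUTOSOMES,
) -> ProtocolModel:
    """Fit the per-autosome beta null model for one protocol.

    Only panel samples with the given protocol and at least
    ``min_fit_reads`` autosomal reads enter the fit.
    """
    qualifying = [
        p
        for p in panel
        if p.protocol == protocol and p.n_autosomal >= min_fit_reads
    ]
    if len(qualifying) < 2:
        raise ModelFitError(
            f"protocol {protocol!r}: {len(qualifying)} sample(s) with >= "
            f"{min_fit_reads} autosomal reads; need at least 2"
        )
    props = pd.DataFrame(
        [p.autosomal_proportions() for p in qualifying],
        index=[p.sample_id for p in qualifying],
    )
    alpha: dict[str, float] = {}
    beta: dict[str, float] = {}
    converged: dict[str, bool] = {}
    for c in autosomes:
        try:
            a, b, ok = fit_beta_mle(props[c].to_numpy())
        except ModelFitError as err:
            raise ModelFitError(f"protocol {protocol!r}, chr{c}: {err}") from err
        alpha[c], beta[c], converged[c] = a, b, ok
    return ProtocolModel(
        protocol=protocol,
        alpha=alpha,
        beta=beta,
        n_ref=len(qualifying),
        converged=converged,
    )


def fit_models(
    panel: CohortTable, min_fit_reads: int = MIN_FIT_READS
) -> dict[str, ProtocolModel]:
    """Fit one :class:`ProtocolModel` per protocol present in the panel."""
    return {
        protocol: fit_protocol_model(panel, protocol, min_fit_reads)
        for protocol in sorted(panel.protocols)
    }


@dataclass
class ZScoreMatrix:
    """Per-sample, per-autosome Z-scores and observed proportions.

    Defined only for samples passing the screening read floor; the ids of
    excluded samples are kept for reporting.
    """

    z: pd.DataFrame
    phat: pd.DataFrame
    excluded: list[str] = field(default_factory=list)


def z_scores(
    cohort: CohortTable,
    models: Mapping[str, ProtocolModel],
    min_screen_reads: int = MIN_SCREEN_READS,
) -> ZScoreMatrix:
    """Standardise each sample's autosome counts against its protocol null.

    Z_{i,c} = (k_{i,c} - E[k]) / sd(k) with beta-binomial moments at the
    sample's autosomal depth n_i and the protocol's (alpha_c, beta_c).
    """
    missing = sorted(cohort.protocols - set(models))
    if missing:
        raise ModelFitError(f"no fitted model for protocol(s): {missing}")

    kept = [p for p in cohort if p.n_autosomal >= min_screen_reads]
    excluded = [
        p.sample_id for p in cohort if p.n_autosomal < min_screen_reads
    ]
    if not kept:
        return ZScoreMatrix(
            z=pd.DataFrame(columns=list(AUTOSOMES)),
            phat=pd.DataFrame(columns=list(AUTOSOMES)),
            excluded=excluded,
        )
    autosomes = models[kept[0].protocol].autosomes
    k = np.array([[p.counts[c] for c in autosomes] for p in kept], dtype=float)
    n = np.array([p.n_autosomal for p in kept], dtype=float)
    z = np.empty_like(k)
    for i, p in enumerate(kept):
        model = models[p.protocol]
        a = np.array([model.alpha[c] for c in autosomes])
        b = np.array([model.beta[c] for c in autosomes])
        mean, var = beta_binomial_moments(n[i], a, b)
        z[i] = (k[i] - mean) / np.sqrt(var)
    ids = [p.sample_id for p in kept]
    return ZScoreMatrix(
        z=pd.DataFrame(z, index=ids, columns=autosomes),
        phat=pd.DataFrame(k / n[:, None], index=ids, columns=autosomes),
        excluded=excluded,
    )


def save_models(
    models: Mapping[str, ProtocolModel], path: str | Path
) -> None:
    """Serialise fitted nulls to JSON for reuse across runs."""
    payload = {
        name: {
            "protocol": m.protocol,
            "alpha": m.alpha,
            "beta": m.beta,
            "n_ref": m.n_ref,
            "converged": m.converged,
        }
        for name, m in models.items()
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_models(path: str | Path) -> dict[str, ProtocolModel]:
    payload = json.loads(Path(path).read_text())
    return {
        name: ProtocolModel(
            protocol=d["protocol"],
            alpha={c: float(v) for c, v in d["alpha"].items()},
            beta={c: float(v) for c, v in d["beta"].items()},
            n_ref=int(d["n_ref"]),
            converged={c: bool(v) for c, v in d.get("converged", {}).items()},
        )
        for name, d in payload.items()
    }
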