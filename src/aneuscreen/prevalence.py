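"""Prevalence statistics: observed trisomy rates vs modern reference rates.

Observed case counts among the screened cohort are compared with modern
per-birth prevalence rates by an exact binomial test.  The two-sided
p-value follows the minimum-likelihood convention (sum of the
probabilities of all outcomes no more likely than the observed one), the
same convention as R's ``binom.test``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import pandas as pd
from scipy.stats import binomtest

__all__ = [
    "MODERN_RATES",
    "UNDER_20_RATE_T21",
    "PrevalenceReport",
    "rate_string",
    "prevalence_test",
    "age_stratified_table",
]

#: Modern prevalence per birth (live births, stillbirths and terminations).
MODERN_RATES: dict[str, float] = {
    "T21": 1 / 705,   # Down syndrome
    "T18": 1 / 3226,  # Edwards syndrome
    "T13": 1 / 7143,  # Patau syndrome
}

#: Modern Down-syndrome rate for mothers under 20 years of age.
UNDER_20_RATE_T21: float = 1 / 1282

_ALTERNATIVES = {"two-sided", "less", "greater"}


@dataclass
class PrevalenceReport:
    syndrome: str
    n_cases: int
    n_screened: int
    rate_string: str | None
    modern_rate: float
    p_value: float
    alternative: str

    @property
    def observed_rate(self) -> float:
        return self.n_cases / self.n_screened


def rate_string(n_cases: int, n_screened: int) -> str | None:
    """Format an observed rate as ``1:N`` with N rounded half-up.

    Undefined (None) when no cases were observed.
    """
    if n_cases < 1:
        return None
    return f"1:{math.floor(n_screened / n_cases + 0.5)}"


def prevalence_test(
    n_cases: int,
    n_screened: int,
    modern_rate: float,
    alternative: str = "two-sided",
    syndrome: str = "",
) -> PrevalenceReport:
    """Exact binomial test of the observed rate against a modern rate."""
    if not 0 <= n_cases <= n_screened:
        raise ValueError("need 0 <= n_cases <= n_screened")
    if not 0.0 < modern_rate < 1.0:
        raise ValueError("modern_rate must lie in (0, 1)")
    if alternative not in _ALTERNATIVES:
        raise ValueError(f"alternative must be one of {sorted(_ALTERNATIVES)}")
    result = binomtest(n_cases, n_screened, modern_rate, alternative=alternative)
    return PrevalenceReport(
        syndrome=syndrome,
        n_cases=n_cases,
        n_screened=n_screened,
        rate_string=rate_string(n_cases, n_screened),
        modern_rate=modern_rate,
        p_value=float(result.pvalue),
        alternative=alternative,
    )


def age_stratified_table(
    observed: PrevalenceReport,
    modern_by_age: Mapping[str, float],
) -> pd.DataFrame:
    """Compare the observed premodern rate against per-age-band modern rates.

    Returns one row per maternal age band: the band's modern rate, the
    observed rate, their ratio, and the exact two-sided binomial p-value
    of the observed counts against the band's rate.
    """
    if not modern_by_age:
        raise ValueError("modern_by_age must supply at least one age band")
    rows = []
    for band, rate in modern_by_age.items():
        test = prevalence_test(
            observed.n_cases,
            observed.n_screened,
            rate,
            alternative=observed.alternative,
            syndrome=observed.syndrome,
        )
        rows.append(
            {
                "age_band": band,
                "modern_rate": rate,
                "observed_rate": observed.observed_rate,
                "rate_ratio": observed.observed_rate / rate,
                "p_value": test.p_value,
            }
        )
    return pd.DataFrame(rows)
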