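"""Synthetic read-count cohorts with the screen's generative structure.

Each sample's 24-chromosome counts are drawn Dirichlet-multinomially:
a per-sample proportion vector from Dirichlet(s * w) — s the protocol's
concentration, w the protocol- and sex-specific base weights — then
counts multinomially at the sample's total depth.  The per-chromosome
marginals of this scheme are beta-binomial, which is exactly the null
the screen fits; trisomy carriers have the affected autosome's base
weight multiplied by 1.5 before renormalisation, reproducing the
~1.5-fold read enrichment of a third copy.

Defaults emulate the screening study conditions: base autosome weights
proportional to GRCh37 chromosome lengths, total depths log-uniform over
10^3..10^7 reads (survey-style shotgun data), two library protocols with
slightly different chromosome-proportion profiles, and concentration
s = 1e5 per protocol, so that the between-library scatter of a small
autosome's proportion is a few percent of its mean (carrier fold spread
about +-0.05, matching the tight fold range reported for real positives).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .chromosomes import AUTOSOMES, CHROMOSOMES, GRCH37_LENGTHS
from .dispersion import ProtocolModel
from .io_counts import CohortTable, ReadCountProfile
from .screen import ScreenThresholds, screen, trisomy_hypothesis

__all__ = [
    "ProtocolSpec",
    "SimScenario",
    "default_scenario",
    "simulate_cohort",
    "power_curve",
    "scenario_from_yaml",
    "scenario_to_yaml",
]


@dataclass(frozen=True)
class ProtocolSpec:
    """Generative parameters for one library protocol.

    ``autosome_weights`` default to GRCh37 lengths; ``tilt_power`` raises
    them to a power and renormalises, a one-parameter way of giving
    protocols distinct mean chromosome proportions. ``y_mappability``
    models the poor mappability of the repeat-rich Y (XY samples);
    ``y_background`` is the fraction of reads mismapped to Y in XX
    samples.
    """

    name: str
    concentration: float = 1e5
    tilt_power: float = 1.0
    autosome_weights: Mapping[str, float] | None = None
    y_mappability: float = 0.3
    y_background: float = 5e-4

    def weights(self, sex: str, trisomic: str | None = None) -> np.ndarray:
        """Base proportion vector over the 24 chromosomes (sums to 1)."""
        if self.concentration <= 0:
            raise ValueError("concentration must be positive")
        base = self.autosome_weights or {
            c: float(GRCH37_LENGTHS[c]) for c in AUTOSOMES
        }
        w = np.array([base[c] ** self.tilt_power for c in AUTOSOMES])
        if trisomic is not None:
            w[AUTOSOMES.index(trisomic)] *= 1.5
        x = GRCH37_LENGTHS["X"] * (1.0 if sex == "XX" else 0.5)
        x *= w.sum() / sum(base[c] for c in AUTOSOMES)  # keep X/autosome scale
        if sex == "XY":
            y = 0.5 * GRCH37_LENGTHS["Y"] * self.y_mappability
            y *= w.sum() / sum(base[c] for c in AUTOSOMES)
        else:
            y = self.y_background * (w.sum() + x) / (1.0 - self.y_background)
        full = np.concatenate([w, [x, y]])
        full /= full.sum()
        if np.any(full <= 0):
            raise ValueError("proportion weights must be strictly positive")
        return full


@dataclass(frozen=True)
class SimScenario:
    """A reproducible cohort-simulation scenario."""

    protocols: tuple[ProtocolSpec, ...] = ()
    n_samples: int = 1000
    depth_range: tuple[float, float] = (1e3, 1e7)  # log-uniform bounds
    carriers: tuple[tuple[int, str], ...] = ()  # (sample index, autosome)
    p_xy: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.protocols:
            object.__setattr__(
                self, "protocols", (ProtocolSpec(name="ds_library"),)
            )
        lo, hi = self.depth_range
        if not (0 < lo <= hi):
            raise ValueError("depth_range must satisfy 0 < lo <= hi")
        for idx, chrom in self.carriers:
            if not 0 <= idx < self.n_samples:
                raise ValueError(f"carrier index {idx} out of range")
            if chrom not in AUTOSOMES:
                raise ValueError(f"carrier chromosome {chrom!r} not an autosome")


def default_scenario(
    n_samples: int = 1000,
    carriers: Sequence[tuple[int, str]] = (),
    depth_range: tuple[float, float] = (1e3, 1e7),
    seed: int = 0,
) -> SimScenario:
    """The default two-protocol study scenario."""
    return SimScenario(
        protocols=(
            ProtocolSpec(name="ds_library", concentration=1e5, tilt_power=1.0),
            ProtocolSpec(name="ss_library", concentration=1e5, tilt_power=1.02),
        ),
        n_samples=n_samples,
        depth_range=depth_range,
        carriers=tuple(carriers),
        seed=seed,
    )


def simulate_cohort(
    scenario: SimScenario, rng: np.random.Generator | None = None
) -> tuple[CohortTable, pd.DataFrame]:
    """Draw a cohort and its truth table.

    Returns ``(cohort, truth)`` where truth has one row per sample with
    its protocol, genetic sex, total depth and true ploidy. Bit-identical
    for a fixed scenario (the seed lives in the scenario).
    """
    rng = rng or np.random.default_rng(scenario.seed)
    carrier_of = dict(scenario.carriers)
    lo, hi = np.log10(scenario.depth_range[0]), np.log10(scenario.depth_range[1])

    profiles: list[ReadCountProfile] = []
    truth_rows: list[dict[str, object]] = []
    width = len(str(max(scenario.n_samples - 1, 1)))
    for i in range(scenario.n_samples):
        spec = scenario.protocols[rng.integers(len(scenario.protocols))]
        sex = "XY" if rng.random() < scenario.p_xy else "XX"
        depth = int(round(10.0 ** rng.uniform(lo, hi)))
        trisomic = carrier_of.get(i)
        w = spec.weights(sex, trisomic)
        p = rng.dirichlet(spec.concentration * w)
        counts = rng.multinomial(depth, p)
        sample_id = f"S{i:0{width}d}"
        profiles.append(
            ReadCountProfile(
                sample_id=sample_id,
                protocol=spec.name,
                counts=dict(zip(CHROMOSOMES, (int(v) for v in counts))),
            )
        )
        truth_rows.append(
            {
                "sample": sample_id,
                "protocol": spec.name,
                "sex": sex,
                "depth": depth,
                "ploidy": trisomy_hypothesis(trisomic) if trisomic else "euploid",
            }
        )
    return CohortTable(profiles), pd.DataFrame(truth_rows)


def power_curve(
    models: Mapping[str, ProtocolModel],
    depths: Sequence[float],
    replicates: int,
    protocol: ProtocolSpec,
    target: str = "21",
    thresholds: ScreenThresholds = ScreenThresholds(),
    seed: int = 0,
) -> pd.DataFrame:
    """Detection probability of a trisomy-``target`` carrier vs depth.

    For each depth, simulates ``replicates`` carriers at exactly that
    depth under ``protocol`` and reports the fraction that the screen
    calls correctly against the supplied fitted models.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rows = []
    for j, depth in enumerate(depths):
        scenario = SimScenario(
            protocols=(protocol,),
            n_samples=replicates,
            depth_range=(depth, depth),
            carriers=tuple((i, target) for i in range(replicates)),
            seed=seed + j,
        )
        cohort, _ = simulate_cohort(scenario)
        results = screen(cohort, models, thresholds)
        detected = sum(
            r.call == trisomy_hypothesis(target) for r in results
        )
        rows.append(
            {"depth": depth, "power": detected / replicates, "n": replicates}
        )
    return pd.DataFrame(rows)


def scenario_to_yaml(scenario: SimScenario, path: str | Path) -> None:
    doc = {
        "n_samples": scenario.n_samples,
        "depth_range": list(scenario.depth_range),
        "carriers": [[i, c] for i, c in scenario.carriers],
        "p_xy": scenario.p_xy,
        "seed": scenario.seed,
        "protocols": [
            {
                "name": s.name,
                "concentration": s.concentration,
                "tilt_power": s.tilt_power,
                "y_mappability": s.y_mappability,
                "y_background": s.y_background,
                **(
                    {"autosome_weights": dict(s.autosome_weights)}
                    if s.autosome_weights
                    else {}
                ),
            }
            for s in scenario.protocols
        ],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def scenario_from_yaml(path: str | Path) -> SimScenario:
    doc = yaml.safe_load(Path(path).read_text())
    protocols = tuple(
        ProtocolSpec(
            name=p["name"],
            concentration=float(p.get("concentration", 1e5)),
            tilt_power=float(p.get("tilt_power", 1.0)),
            autosome_weights=p.get("autosome_weights"),
            y_mappability=float(p.get("y_mappability", 0.3)),
            y_background=float(p.get("y_background", 5e-4)),
        )
        for p in doc.get("protocols", [])
    )
    return SimScenario(
        protocols=protocols,
        n_samples=int(doc["n_samples"]),
        depth_range=tuple(float(v) for v in doc.get("depth_range", (1e3, 1e7))),
        carriers=tuple((int(i), str(c)) for i, c in doc.get("carriers", [])),
        p_xy=float(doc.get("p_xy", 0.5)),
        seed=int(doc.get("seed", 0)),
    )
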