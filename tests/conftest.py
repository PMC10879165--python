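"""Shared fixtures: simulated panels, fitted nulls and true generating models."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from aneuscreen import (
    ProtocolModel,
    default_scenario,
    fit_models,
    simulate_cohort,
)
from aneuscreen.chromosomes import AUTOSOMES
from aneuscreen.simulate import ProtocolSpec

settings.register_profile("suite", derandomize=True, max_examples=25)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_spec() -> ProtocolSpec:
    return ProtocolSpec(name="ds_library")


@pytest.fixture(scope="session")
def panel_and_models():
    """A 600-sample euploid panel under default conditions plus fitted nulls."""
    scenario = default_scenario(n_samples=600, depth_range=(1e4, 1e7), seed=11)
    panel, truth = simulate_cohort(scenario)
    models = fit_models(panel)
    return panel, truth, models


@pytest.fixture(scope="session")
def fitted_models(panel_and_models):
    return panel_and_models[2]


def make_true_model(spec: ProtocolSpec, sex: str = "XX") -> ProtocolModel:
    """The exact generating beta parameters of the autosomal composition.

    The Dirichlet sub-composition over autosomes has parameters s*w_c, so
    chromosome c's proportion of the autosomal total is
    Beta(s*w_c, s*(sum_auto w) - s*w_c) exactly.
    """
    w = spec.weights(sex)
    alpha = {c: spec.concentration * w[i] for i, c in enumerate(AUTOSOMES)}
    s_auto = sum(alpha.values())
    beta = {c: s_auto - alpha[c] for c in AUTOSOMES}
    return ProtocolModel(protocol=spec.name, alpha=alpha, beta=beta, n_ref=2)


@pytest.fixture(scope="session")
def true_model(default_spec) -> ProtocolModel:
    return make_true_model(default_spec)
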