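"""Fold-increases, ploidy posteriors and screening calls."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, strategies as st

from aneuscreen import (
    CohortTable,
    ProtocolModel,
    ReadCountProfile,
    ScreenThresholds,
    SimScenario,
    fold_increase,
    posterior_ploidy,
    screen,
    significance_count,
    simulate_cohort,
    trisomy_hypothesis,
)
from aneuscreen.chromosomes import AUTOSOMES, CHROMOSOMES
from aneuscreen.screen import EUPLOID, _hypothesis_shapes, _log_likelihoods
from _oracles import posterior_by_enumeration, shifted_means, toy_loglik


def toy_model(means=(0.5, 0.3, 0.2), s=50.0) -> ProtocolModel:
    """A 3-chromosome pseudo-genome model on autosome names '1','2','3'."""
    alpha = {str(i + 1): m * s for i, m in enumerate(means)}
    beta = {str(i + 1): (1 - m) * s for i, m in enumerate(means)}
    return ProtocolModel(protocol="toy", alpha=alpha, beta=beta, n_ref=2)


def toy_profile(k1, k2, k3, sample_id="t") -> ReadCountProfile:
    counts = {c: 0 for c in CHROMOSOMES}
    counts["1"], counts["2"], counts["3"] = k1, k2, k3
    return ReadCountProfile(sample_id, "toy", counts)


def test_posterior_equals_prior_with_zero_reads(true_model):
    profile = ReadCountProfile("empty", true_model.protocol, {c: 0 for c in CHROMOSOMES})
    post = posterior_ploidy(profile, true_model)
    assert all(p == pytest.approx(1 / 23) for p in post.values())


def test_posterior_matches_enumeration_on_toy_genome():
    """23-way machinery reduced to a 3-chromosome genome agrees with a
    direct pmf-product enumeration oracle."""
    model = toy_model()
    for counts in [(14, 9, 7), (20, 6, 4), (10, 10, 10), (25, 3, 2)]:
        profile = toy_profile(*counts)
        post = posterior_ploidy(profile, model)
        ref = posterior_by_enumeration(counts, (0.5, 0.3, 0.2), (50.0, 50.0, 50.0))
        for h, p_ref in ref.items():
            assert post[h] == pytest.approx(p_ref, abs=1e-12)


def test_log_likelihoods_match_oracle_to_1e10():
    """Hypothesis log-likelihoods agree with lgamma-based products."""
    model = toy_model()
    autosomes, A, B = _hypothesis_shapes(model)
    counts = (18, 8, 4)
    k = np.array([list(counts)], dtype=float)
    n = np.array([float(sum(counts))])
    ll = _log_likelihoods(k, n, A, B)[0]
    means = [0.5, 0.3, 0.2]
    assert ll[0] == pytest.approx(toy_loglik(counts, means, [50] * 3), abs=1e-10)
    for j in range(3):
        ref = toy_loglik(counts, shifted_means(means, j), [50] * 3)
        assert ll[j + 1] == pytest.approx(ref, abs=1e-10)


@given(
    k1=st.integers(0, 30),
    k2=st.integers(0, 30),
    k3=st.integers(0, 30),
)
def test_posterior_normalised(k1, k2, k3):
    post = posterior_ploidy(toy_profile(k1, k2, k3), toy_model())
    assert sum(post.values()) == pytest.approx(1.0, abs=1e-12)
    assert all(0.0 <= p <= 1.0 for p in post.values())


def test_posterior_monotone_in_target_count():
    """With n fixed, the trisomy posterior is non-decreasing as the target
    chromosome's count sweeps from its mean towards 1.6x the mean."""
    model = toy_model(means=(0.2, 0.5, 0.3), s=200.0)
    n = 200
    posts = []
    for k1 in range(int(0.2 * n), int(0.2 * 1.6 * n) + 1):
        rest = n - k1
        k2 = int(round(rest * 5 / 8))
        k3 = rest - k2
        posts.append(posterior_ploidy(toy_profile(k1, k2, k3), model)["trisomy-1"])
    assert all(b >= a - 1e-12 for a, b in zip(posts, posts[1:]))


def test_posterior_rejects_bad_prior(true_model):
    profile = ReadCountProfile("p", true_model.protocol, {c: 1 for c in CHROMOSOMES})
    bad = {h: 0.5 for h in ["euploid"] + [trisomy_hypothesis(c) for c in AUTOSOMES]}
    with pytest.raises(ValueError, match="prior"):
        posterior_ploidy(profile, true_model, prior=bad)


def test_fold_is_one_at_protocol_mean(true_model):
    """A profile sitting exactly on the protocol means self-normalises."""
    n = 1_000_000
    counts = {c: 0 for c in CHROMOSOMES}
    for c in AUTOSOMES:
        counts[c] = int(round(true_model.mean_prop[c] * n))
    profile = ReadCountProfile("avg", true_model.protocol, counts)
    folds = fold_increase(profile, true_model)
    assert all(f == pytest.approx(1.0, abs=2e-3) for f in folds.values())


def test_carrier_fold_matches_renormalised_weights(true_model):
    """A deep carrier's fold approaches 1.5/(1 + 0.5*m_21) in closed form."""
    m21 = true_model.mean_prop["21"]
    expected = 1.5 / (1.0 + 0.5 * m21)
    n = 5_000_000
    scale = 1.0 + 0.5 * m21
    counts = {c: 0 for c in CHROMOSOMES}
    for c in AUTOSOMES:
        target = true_model.mean_prop[c] / scale
        if c == "21":
            target = 1.5 * m21 / scale
        counts[c] = int(round(target * n))
    profile = ReadCountProfile("carrier", true_model.protocol, counts)
    fold = fold_increase(profile, true_model)["21"]
    assert fold == pytest.approx(expected, abs=1e-3)
    assert expected == pytest.approx(1.49, abs=0.01)


def test_fold_median_centering_uses_negatives(true_model, default_spec):
    scenario = SimScenario(
        protocols=(default_spec,), n_samples=50, depth_range=(1e5, 1e5), seed=8
    )
    cohort, _ = simulate_cohort(scenario)
    from aneuscreen import z_scores

    zm = z_scores(cohort, {default_spec.name: true_model})
    profile = cohort.profiles[0]
    fold_med = fold_increase(profile, true_model, center="median", negatives=zm)
    fold_mean = fold_increase(profile, true_model, center="mean")
    for c in AUTOSOMES:
        assert fold_med[c] == pytest.approx(fold_mean[c], rel=0.05)
    with pytest.raises(ValueError, match="negatives"):
        fold_increase(profile, true_model, center="median")


def test_significance_count_trivial_rows():
    zeros = {c: 0.0 for c in AUTOSOMES}
    assert significance_count(zeros) == 0
    one_hot = dict(zeros, **{"21": 50.0})
    assert significance_count(one_hot) == 1
    # one-sided: a strongly *under*-represented chromosome never counts
    low = dict(zeros, **{"21": -50.0})
    assert significance_count(low) == 0


def test_significance_count_calibrated_on_euploids(true_model, default_spec):
    """Fraction of euploids with any significant autosome stays near the
    nominal family-wise level.

    The rule compares Z-scores against a normal quantile while the null is
    a (right-skewed) beta-binomial, so the realised family-wise rate runs
    a little above nominal; the check bounds it to the nominal level plus
    a skewness allowance, and from below to rule out gross conservatism.
    """
    scenario = SimScenario(
        protocols=(default_spec,), n_samples=10_000,
        depth_range=(1e5, 1e5), seed=6,
    )
    cohort, _ = simulate_cohort(scenario)
    from aneuscreen import z_scores

    zm = z_scores(cohort, {default_spec.name: true_model})
    frac = np.mean([
        significance_count(dict(row)) >= 1 for _, row in zm.z.iterrows()
    ])
    assert 0.02 <= frac <= 0.075


def test_screen_read_floor_boundary(fitted_models, default_spec):
    """999 autosomal reads is insufficient; the floor itself (1000) screens."""
    counts_low = {c: 0 for c in CHROMOSOMES}
    counts_low["1"] = 999
    counts_ok = dict(counts_low, **{"1": 900, "2": 100})
    cohort = CohortTable([
        ReadCountProfile("low", default_spec.name, counts_low),
        ReadCountProfile("ok", default_spec.name, counts_ok),
    ])
    results = screen(cohort, fitted_models)
    assert results[0].call == "insufficient-reads"
    assert results[1].call != "insufficient-reads"


def test_screen_flags_multiple_overrepresentation_as_ambiguous(
    fitted_models, default_spec
):
    """Two wildly overrepresented chromosomes trigger the ambiguity rule."""
    model = fitted_models[default_spec.name]
    n = 100_000
    counts = {c: 0 for c in CHROMOSOMES}
    for c in AUTOSOMES:
        counts[c] = int(round(model.mean_prop[c] * n))
    counts["21"] = int(counts["21"] * 1.5)
    counts["18"] = int(counts["18"] * 1.5)
    cohort = CohortTable([ReadCountProfile("two", default_spec.name, counts)])
    results = screen(cohort, fitted_models)
    assert results[0].call == "ambiguous"
    assert results[0].n_significant >= 2


def test_end_to_end_recovery_of_carriers(fitted_models, default_spec):
    """simulate -> fit -> screen finds exactly the planted carriers across
    depths from 3e4 to 3e6 and calls no one else."""
    depths = [3e4, 1e5, 3e5, 1e6, 3e6]
    results_all = []
    truth_all = []
    for j, depth in enumerate(depths):
        scenario = SimScenario(
            protocols=(default_spec,),
            n_samples=40,
            depth_range=(depth, depth),
            carriers=((0, "21"),),
            seed=20 + j,
        )
        cohort, truth = simulate_cohort(scenario)
        results_all.extend(screen(cohort, fitted_models))
        truth_all.extend(truth["ploidy"])
    for result, ploidy in zip(results_all, truth_all):
        if ploidy == "trisomy-21":
            assert result.call == "trisomy-21"
            assert result.posterior["trisomy-21"] > 0.99
        else:
            assert result.call == EUPLOID


def test_screen_unknown_protocol_is_named(fitted_models):
    counts = {c: 100 for c in CHROMOSOMES}
    cohort = CohortTable([ReadCountProfile("s", "mystery_prep", counts)])
    from aneuscreen.screen import ModelLookupError

    with pytest.raises(ModelLookupError, match="mystery_prep"):
        screen(cohort, fitted_models)
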