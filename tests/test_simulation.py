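"""The Monte-Carlo engine: determinism, consistency, and exact oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import binom

from brierlab import (
    PerturbationSpec,
    RejectedReplicateError,
    ScenarioSpec,
    TruthDistributionSpec,
    ValidationError,
    compare_models,
    epsilon_sweep,
    run_scenario,
    summarize_scenario,
)


def _scenario(truth, pert, n, reps, seed=0, **kw):
    return ScenarioSpec(
        label="test", truth=truth, perturbation=pert, n=n, replicates=reps,
        master_seed=seed, **kw,
    )


def constant_q_event_probabilities(q: float, n: int) -> dict:
    """Exact binomial enumeration for constant-q truth with p = q.

    With every prediction equal to the shared q, the realised Brier score
    is BS = q² + ȳ(1 − 2q), so ȳ − ȳ² − BS = −(ȳ − q)² ≤ 0: the reference
    can never strictly exceed the score, while the score exceeds the
    reference whenever ȳ ≠ q.  Summing Binomial(n, q) probabilities over
    every outcome count k gives both event probabilities exactly.
    """
    k = np.arange(n + 1)
    pmf = binom.pmf(k, n, q)
    ybar = k / n
    bs = q**2 + ybar * (1 - 2 * q)
    ref = ybar - ybar**2
    # margin so the ȳ = q tie (exactly zero difference) is never flipped
    # by float round-off in this closed form
    return {
        "p_ref_exceeds_bs": float(pmf[ref - bs > 1e-12].sum()),
        "p_bs_exceeds_ref": float(pmf[bs - ref > 1e-12].sum()),
    }


def test_two_point_truth_perfect_predictions_score_zero():
    truth = TruthDistributionSpec("two_point", {"v0": 0.0, "v1": 1.0, "weight": 0.5}, n=50)
    table = run_scenario(_scenario(truth, PerturbationSpec("identity"), 50, 100))
    assert (table["brier"] == 0.0).all()


def test_constant_half_identity_brier_is_exactly_quarter():
    # (0.5 − y)² = 0.25 whatever y: the score is deterministic here
    truth = TruthDistributionSpec("constant", {"value": 0.5}, n=1000)
    table = run_scenario(_scenario(truth, PerturbationSpec("identity"), 1000, 200))
    assert (table["brier"] == 0.25).all()
    summary = summarize_scenario(table, bootstrap_reps=10)
    assert summary.metrics["brier"]["median"] == 0.25


def test_mean_consistency_with_analytic_expectation():
    """Replicate mean of BS matches the per-replicate analytic expectation."""
    truth = TruthDistributionSpec("uniform", {"low": 0.0, "high": 1.0}, n=300)
    table = run_scenario(
        _scenario(truth, PerturbationSpec("uniform_noise", 0.1), 300, 400, seed=5)
    )
    diff = table["brier"] - table["expected_brier"]
    se = diff.std(ddof=1) / np.sqrt(len(diff))
    assert abs(diff.mean()) < 4 * se


def test_determinism_identical_spec_identical_table():
    truth = TruthDistributionSpec("beta", {"alpha": 1.0, "beta": 3.0}, n=100)
    spec = _scenario(truth, PerturbationSpec("uniform_noise", 0.1), 100, 50, seed=9)
    pd.testing.assert_frame_equal(run_scenario(spec), run_scenario(spec))


def test_fixed_truth_policy_reuses_one_q_vector():
    truth = TruthDistributionSpec("uniform", {"low": 0.0, "high": 1.0}, n=80)
    spec = _scenario(truth, PerturbationSpec("identity"), 80, 30, seed=2, redraw_truth=False)
    table = run_scenario(spec)
    # one shared q ⇒ one shared q̄ − q̄² across replicates
    assert table["truth_reference"].nunique() == 1
    redrawn = run_scenario(
        _scenario(truth, PerturbationSpec("identity"), 80, 30, seed=2)
    )
    assert redrawn["truth_reference"].nunique() > 1


def test_variance_shrinks_with_sample_size():
    truth_small = TruthDistributionSpec("uniform", {"low": 0.0, "high": 1.0}, n=300)
    truth_big = TruthDistributionSpec("uniform", {"low": 0.0, "high": 1.0}, n=1000)
    sd_small = run_scenario(
        _scenario(truth_small, PerturbationSpec("identity"), 300, 300, seed=3)
    )["brier"].std()
    sd_big = run_scenario(
        _scenario(truth_big, PerturbationSpec("identity"), 1000, 300, seed=4)
    )["brier"].std()
    assert sd_big < sd_small


def test_summary_degenerate_and_validation():
    table = pd.DataFrame(
        {
            "replicate": [0, 1, 2],
            "brier": [0.2, 0.2, 0.2],
            "brier_perfect": [0.2] * 3,
            "cil": [0.0] * 3,
            "prevalence_reference": [0.25] * 3,
            "gap": [0.05] * 3,
            "exceed": [True] * 3,
            "brier_exceeds_reference": [False] * 3,
            "expected_brier": [0.2] * 3,
            "truth_reference": [0.25] * 3,
        }
    )
    summary = summarize_scenario(table, bootstrap_reps=100, seed=0)
    stats = summary.metrics["brier"]
    assert stats["median"] == stats["p5"] == stats["p95"] == 0.2
    assert summary.exceedance_probability == 1.0
    assert summary.exceedance_ci == (1.0, 1.0)
    with pytest.raises(ValidationError):
        summarize_scenario(table, bootstrap_reps=0)
    with pytest.raises(ValidationError):
        summarize_scenario(table.iloc[:0])


@pytest.mark.parametrize("q", [0.5, 0.3])
def test_exceedance_matches_exact_binomial_enumeration(q):
    """Engine frequencies of both score/reference orderings vs enumeration."""
    n, reps = 300, 400
    oracle = constant_q_event_probabilities(q, n)
    truth = TruthDistributionSpec("constant", {"value": q}, n=n)
    table = run_scenario(_scenario(truth, PerturbationSpec("identity"), n, reps, seed=13))
    # the reference never strictly exceeds the score for constant truth
    assert oracle["p_ref_exceeds_bs"] == 0.0
    assert table["exceed"].mean() == 0.0
    emp = table["brier_exceeds_reference"].mean()
    p = oracle["p_bs_exceeds_ref"]
    se = np.sqrt(p * (1 - p) / reps)
    assert abs(emp - p) < 4 * se + 1e-12


def test_epsilon_sweep_exact_squares():
    q = np.full(10, 0.5)
    sweep = epsilon_sweep(q, [0.0, 0.1, 0.2], signs="alternating")
    np.testing.assert_allclose(
        sweep["expected_increase"], [0.0, 0.01, 0.04], atol=1e-12
    )
    with pytest.raises(ValidationError):
        epsilon_sweep(q, [0.6])  # would leave [0, 1]; no silent clipping
    with pytest.raises(ValidationError):
        epsilon_sweep(q, [-0.1])


def test_compare_models_tie_and_expected_winner():
    truth = TruthDistributionSpec("constant", {"value": 0.5}, n=1000)
    spec = _scenario(truth, PerturbationSpec("identity"), 1000, 100, seed=21)
    table = run_scenario(spec)
    tie = compare_models(table, run_scenario(spec))
    assert tie["ties"] == 1.0 and tie["mean_diff"] == 0.0

    biased = run_scenario(
        _scenario(truth, PerturbationSpec("additive_bias", 0.1), 1000, 100, seed=21)
    )
    result = compare_models(table, biased)
    assert result["a_wins"] > 0.5  # the perfect model usually wins
    with pytest.raises(ValidationError):
        compare_models(table, biased.iloc[:50])


def test_compare_models_single_observation_worked_example():
    """1-obs example at q = 0.1: predicting 0 beats predicting 0.25 in
    expectation (0.1 vs 0.1125), yet the worse model wins whenever y = 1."""
    reps = 5000
    rng = np.random.default_rng(30)
    y = (rng.random(reps) < 0.1).astype(float)  # shared outcomes, paired
    table_zero = pd.DataFrame({"brier": (0.0 - y) ** 2})
    table_quarter = pd.DataFrame({"brier": (0.25 - y) ** 2})
    for table, expect in ((table_zero, 0.1), (table_quarter, 0.1125)):
        se = table["brier"].std(ddof=1) / np.sqrt(reps)
        assert abs(table["brier"].mean() - expect) < 4 * se
    result = compare_models(table_zero, table_quarter)
    # model 1 wins exactly when y = 0, model 2 when y = 1 (≈10% of replicates)
    assert result["a_wins"] == pytest.approx(1 - y.mean())
    assert 0.0 < result["b_wins"] < 0.5


def test_reject_policy_abort_names_replicate():
    truth = TruthDistributionSpec("constant", {"value": 0.99}, n=10)
    spec = _scenario(
        truth, PerturbationSpec("additive_bias", 0.1, clip_policy="reject"), 10, 5
    )
    with pytest.raises(RejectedReplicateError, match="replicate 0"):
        run_scenario(spec)


def test_summary_percentile_ordering_invariant():
    truth = TruthDistributionSpec("uniform", {"low": 0.0, "high": 1.0}, n=200)
    table = run_scenario(_scenario(truth, PerturbationSpec("identity"), 200, 150, seed=17))
    summary = summarize_scenario(table, bootstrap_reps=50)
    for stats in summary.metrics.values():
        assert stats["p5"] <= stats["median"] <= stats["p95"]
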