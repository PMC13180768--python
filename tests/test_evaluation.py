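"""Bias metrics, stratified truth sampling and magnitude mapping."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ergmflow.evaluation import (
    BiasDesign,
    EvaluationError,
    bias_metrics,
    magnitude_assessment,
    posterior_predictive,
    stratified_truths,
)
from ergmflow.exchange import PosteriorSamples
from ergmflow.priors import PriorSpec
from ergmflow.simulator import SimulatorConfig

TOY_SIM = SimulatorConfig(n_vertices=12, aux_iterations=400, seed=17)


class TestBiasMetrics:
    def test_perfect_estimates_zero_everywhere(self):
        t = np.random.default_rng(0).standard_normal((6, 3))
        rep = bias_metrics(t, t.copy())
        np.testing.assert_array_equal(rep.me, np.zeros(3))
        np.testing.assert_array_equal(rep.mae, np.zeros(3))
        np.testing.assert_array_equal(rep.rmse, np.zeros(3))

    def test_symmetric_errors_cancel_in_me_only(self):
        truths = np.zeros((2, 3))
        est = np.array([[1.0, 0, 0], [-1.0, 0, 0]])
        rep = bias_metrics(truths, est)
        assert rep.me[0] == pytest.approx(0.0)
        assert rep.mae[0] == pytest.approx(1.0)
        assert rep.rmse[0] == pytest.approx(1.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(EvaluationError):
            bias_metrics(np.zeros((3, 3)), np.zeros((2, 3)))

    @settings(max_examples=50, deadline=None)
    @given(st.integers(min_value=1, max_value=20), st.integers(min_value=0, max_value=10_000))
    def test_metric_ordering_holds_on_random_inputs(self, k, seed):
        rng = np.random.default_rng(seed)
        truths = rng.standard_normal((k, 3))
        est = truths + rng.standard_normal((k, 3)) * rng.exponential(1.0)
        rep = bias_metrics(truths, est)
        assert (np.abs(rep.me) <= rep.mae + 1e-12).all()
        assert (rep.mae <= rep.rmse + 1e-12).all()


class TestStratifiedTruths:
    def test_small_design_fills_each_stratum(self):
        # strata scaled to the 12-vertex dyad count (66 dyads)
        design = BiasDesign(
            K=3, M=1, strata=(0.0, 11.0, 22.0, 33.0), per_stratum=1,
            edge_cap=33.0, pilot_sims=10, seed=1,
        )
        prior = PriorSpec(np.zeros(3), np.diag([4.0, 0.25, 0.25]))
        truths, labels = stratified_truths(prior, design, TOY_SIM)
        assert truths.shape == (3, 3)
        np.testing.assert_array_equal(labels, [0, 1, 2])

    def test_inconsistent_design_rejected(self):
        with pytest.raises(EvaluationError):
            BiasDesign(K=40, per_stratum=3)
        with pytest.raises(EvaluationError):
            BiasDesign(strata=(0.0, 5.0, 5.0, 10.0, 20.0))

    def test_impossible_stratum_raises_budget_error(self):
        design = BiasDesign(
            K=1, M=1, strata=(0.0, 0.5), per_stratum=1, edge_cap=0.0,
            pilot_sims=2, max_attempts_per_stratum=10, seed=0,
        )
        with pytest.raises(EvaluationError, match="stratum"):
            stratified_truths(PriorSpec(), design, TOY_SIM)


class TestMagnitudeAssessment:
    def test_predictive_at_truth_is_small_bias_with_high_coverage(self):
        theta = np.array([-0.5, 0.2, -0.1])
        rep = magnitude_assessment(
            theta, np.tile(theta, (5, 1)), TOY_SIM,
            n_reference=400, per_mean_sims=80, seed=3,
        )
        assert rep.small_bias.all()
        assert (rep.coverage_percent > 95.0).all()

    def test_disjoint_regimes_flag_large_bias_with_no_coverage(self):
        sparse = np.array([-6.0, 0.0, 0.0])
        dense = np.array([6.0, 0.0, 0.0])
        rep = magnitude_assessment(
            dense, np.tile(sparse, (3, 1)), TOY_SIM,
            n_reference=150, per_mean_sims=40, seed=4,
        )
        assert not rep.small_bias[0]
        assert rep.coverage_percent[0] < 5.0

    def test_invariant_to_posterior_mean_ordering(self):
        rng = np.random.default_rng(5)
        means = rng.normal(0, 0.3, size=(6, 3))
        theta = np.array([0.2, 0.1, -0.1])
        a = magnitude_assessment(theta, means, TOY_SIM, n_reference=100, per_mean_sims=20, seed=6)
        b = magnitude_assessment(
            theta, means[::-1], TOY_SIM, n_reference=100, per_mean_sims=20, seed=6
        )
        np.testing.assert_allclose(a.coverage_percent, b.coverage_percent, atol=2.0)

    def test_zero_budget_rejected(self):
        with pytest.raises(EvaluationError):
            magnitude_assessment(np.zeros(3), np.zeros((1, 3)), TOY_SIM, n_reference=0)


class TestPosteriorPredictive:
    def test_point_mass_matches_replicate_distribution(self):
        theta = np.array([0.3, 0.1, -0.1])
        post = PosteriorSamples(
            draws=np.tile(theta, (100, 1)), method="test", x_obs=None,
            acceptance_rate=1.0, seed=0,
        )
        preds = posterior_predictive(post, TOY_SIM, n_draws=150, seed=7)
        from dataclasses import replace

        from ergmflow.simulator import simulate_network

        direct = np.array(
            [
                simulate_network(theta, replace(TOY_SIM, seed=1000 + r))[1]
                for r in range(150)
            ]
        )
        se = direct.std(axis=0, ddof=1) * np.sqrt(2.0 / 150)
        assert (np.abs(preds.mean(axis=0) - direct.mean(axis=0)) < 4 * se + 0.5).all()

    def test_seeded_reproducibility(self):
        post = PosteriorSamples(
            draws=np.random.default_rng(1).normal(0, 0.2, (50, 3)),
            method="test", x_obs=None, acceptance_rate=1.0, seed=0,
        )
        a = posterior_predictive(post, TOY_SIM, n_draws=30, seed=9)
        b = posterior_predictive(post, TOY_SIM, n_draws=30, seed=9)
        np.testing.assert_array_equal(a, b)
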