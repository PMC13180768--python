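"""Auxiliary-MCMC simulator against closed forms and the enumeration oracle."""

from dataclasses import replace

import numpy as np
import pytest
from scipy.special import expit

from ergmflow.priors import PriorSpec
from ergmflow.simulator import (
    SimulatorConfig,
    SimulatorError,
    enumerate_exact,
    simulate_network,
    simulate_training_pairs,
)


def _mean_stats(theta, cfg, reps):
    out = np.empty((reps, 3))
    for r in range(reps):
        _, out[r] = simulate_network(theta, replace(cfg, seed=cfg.seed + r))
    return out


class TestSimulateNetwork:
    def test_seed_determinism(self):
        cfg = SimulatorConfig(n_vertices=12, aux_iterations=500, seed=5)
        g1, s1 = simulate_network([0.1, 0.05, -0.05], cfg)
        g2, s2 = simulate_network([0.1, 0.05, -0.05], cfg)
        assert g1 == g2
        np.testing.assert_array_equal(s1, s2)

    def test_non_finite_theta_rejected(self):
        cfg = SimulatorConfig(n_vertices=5, aux_iterations=10)
        with pytest.raises(SimulatorError):
            simulate_network([np.nan, 0, 0], cfg)

    def test_uniform_model_mean_edges(self):
        # theta = 0: every graph equally likely, E[edges] = C(5,2)/2 = 5
        cfg = SimulatorConfig(n_vertices=5, aux_iterations=300, seed=100)
        stats = _mean_stats(np.zeros(3), cfg, reps=400)
        se = stats[:, 0].std(ddof=1) / np.sqrt(len(stats))
        assert abs(stats[:, 0].mean() - 5.0) < 3 * se + 0.05

    @pytest.mark.parametrize("kernel", ["plain", "tnt"])
    def test_edges_only_model_matches_independent_bernoulli(self, kernel):
        # with zero geometric coefficients, dyads are iid Bernoulli(logistic(t))
        t = -1.0
        n = 15
        # chain long enough to forget the empty start at this density
        cfg = SimulatorConfig(
            n_vertices=n, aux_iterations=5_000, seed=7, kernel=kernel
        )
        stats = _mean_stats([t, 0.0, 0.0], cfg, reps=100)
        ndyads = n * (n - 1) / 2
        p = expit(t)
        expected = ndyads * p
        sd = np.sqrt(ndyads * p * (1 - p))
        se = sd / np.sqrt(len(stats))
        assert abs(stats[:, 0].mean() - expected) < 3 * se

    def test_boundary_monotone_in_edge_parameter(self):
        cfg = SimulatorConfig(n_vertices=12, aux_iterations=2_000, seed=0)
        means = [
            _mean_stats([t, 0, 0], cfg, reps=20)[:, 0].mean()
            for t in (-4.0, -1.0, 1.0, 4.0)
        ]
        assert means == sorted(means)
        assert means[0] < 5 and means[-1] > 60  # near-empty to near-full

    def test_init_modes(self):
        full = SimulatorConfig(n_vertices=8, aux_iterations=0, init_mode="full")
        g, s = simulate_network([0, 0, 0], full)
        assert g.n_edges == 28
        from ergmflow.graph import Graph

        init = Graph.from_edges(4, [(0, 1)])
        prov = SimulatorConfig(
            n_vertices=4, aux_iterations=0, init_mode="provided", init_graph=init
        )
        g2, _ = simulate_network([0, 0, 0], prov)
        assert g2 == init
        with pytest.raises(SimulatorError):
            SimulatorConfig(n_vertices=4, init_mode="provided")
        with pytest.raises(SimulatorError):
            simulate_network([0, 0, 0], SimulatorConfig(n_vertices=4, init_mode="observed"))


class TestOracleEquivalence:
    def test_simulator_moments_match_enumeration(self):
        theta = np.array([0.2, 0.1, -0.1])
        exact = enumerate_exact(5, theta)
        cfg = SimulatorConfig(n_vertices=5, aux_iterations=400, seed=900)
        sims = _mean_stats(theta, cfg, reps=400)
        se = np.sqrt(np.diag(exact.stats_cov())) / np.sqrt(len(sims))
        diff = np.abs(sims.mean(axis=0) - exact.expected_stats())
        assert (diff < 3 * se + 0.05).all(), (diff, 3 * se)


class TestEnumeration:
    def test_two_vertex_closed_form(self):
        t = 0.7
        exact = enumerate_exact(2, [t, 0, 0])
        assert exact.log_normaliser == pytest.approx(np.log(1 + np.exp(t)))
        # P(edge) = logistic(t)
        p_edge = exact.probabilities[exact.stats_table[:, 0] == 1].sum()
        assert p_edge == pytest.approx(expit(t))

    @pytest.mark.parametrize("n", [3, 4, 5])
    def test_uniform_log_normaliser(self, n):
        exact = enumerate_exact(n, [0, 0, 0])
        assert exact.log_normaliser == pytest.approx(n * (n - 1) / 2 * np.log(2))
        assert exact.probabilities.sum() == pytest.approx(1.0, abs=1e-9)

    def test_independent_dyad_expected_edges(self):
        exact = enumerate_exact(4, [0.5, 0, 0])
        assert exact.expected_stats()[0] == pytest.approx(6 * expit(0.5))

    def test_refuses_large_n(self):
        with pytest.raises(SimulatorError):
            enumerate_exact(8, [0, 0, 0])


class TestTrainingPairs:
    def test_empty_budget(self):
        cfg = SimulatorConfig(n_vertices=5, aux_iterations=10)
        pairs = simulate_training_pairs(PriorSpec(), 0, cfg)
        assert len(pairs) == 0

    def test_identical_seed_bit_identical(self):
        cfg = SimulatorConfig(n_vertices=8, aux_iterations=100, seed=3)
        p1 = simulate_training_pairs(PriorSpec(), 20, cfg)
        p2 = simulate_training_pairs(PriorSpec(), 20, cfg)
        np.testing.assert_array_equal(p1.thetas, p2.thetas)
        np.testing.assert_array_equal(p1.stats, p2.stats)

    def test_theta_marginal_follows_proposal(self):
        # CLT bound on the sample mean under N(0, 10 I)
        cfg = SimulatorConfig(n_vertices=5, aux_iterations=20, seed=8)
        pairs = simulate_training_pairs(PriorSpec(), 2_000, cfg)
        bound = 4 * np.sqrt(10) / np.sqrt(2_000)
        assert (np.abs(pairs.thetas.mean(axis=0)) < bound).all()
        assert (pairs.round_index == 1).all()

    def test_unsampleable_proposal_rejected(self):
        cfg = SimulatorConfig(n_vertices=5, aux_iterations=10)
        with pytest.raises(SimulatorError):
            simulate_training_pairs(object(), 5, cfg)
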