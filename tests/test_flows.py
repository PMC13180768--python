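"""Conditional MAF: construction, gradients, training, atomic loss, persistence."""

import numpy as np
import pytest

from ergmflow.flows import (
    ConditionalMAF,
    FlowConfig,
    FlowError,
    atomic_loss,
    build_flow,
    fit_ml,
    load_flow,
    save_flow,
)
from ergmflow.priors import PriorSpec
from ergmflow.simulator import TrainingPairs
from tests.conftest import LG_SIGMA, lg_posterior_mean


def _pairs(thetas, xs):
    n = len(thetas)
    return TrainingPairs(thetas, xs, np.ones(n, dtype=int), np.arange(n, dtype=np.int64))


class TestConstruction:
    def test_untrained_flow_samples_and_scores_finite(self):
        flow = build_flow(FlowConfig(hidden_units=8, n_transforms=2, seed=0))
        x = np.array([1.0, 2.0, 3.0])
        s = flow.sample(50, x, seed=1)
        assert np.isfinite(s).all()
        assert np.isfinite(flow.log_prob(s, x)).all()

    def test_identical_seed_identical_parameters(self):
        cfg = FlowConfig(hidden_units=8, n_transforms=2, seed=42)
        f1, f2 = build_flow(cfg), build_flow(cfg)
        for p1, p2 in zip(f1._all_params(), f2._all_params()):
            np.testing.assert_array_equal(p1, p2)

    def test_minimal_flow_works(self):
        flow = build_flow(FlowConfig(hidden_units=2, n_transforms=1, seed=0))
        assert np.isfinite(flow.log_prob(np.zeros(3), np.zeros(3))).all()

    def test_invalid_sizes_rejected(self):
        with pytest.raises(FlowError):
            FlowConfig(hidden_units=0)
        with pytest.raises(FlowError):
            FlowConfig(validation_fraction=1.5)

    def test_sampling_deterministic_under_seed(self):
        flow = build_flow(FlowConfig(hidden_units=8, n_transforms=2, seed=3))
        x = np.ones(3)
        np.testing.assert_array_equal(flow.sample(20, x, seed=9), flow.sample(20, x, seed=9))


class TestGradients:
    def test_backward_matches_finite_differences(self):
        flow = build_flow(FlowConfig(hidden_units=6, n_transforms=2, seed=3))
        rng = np.random.default_rng(0)
        for lay in flow.layers:  # randomise away the identity init
            lay.set_params([p + 0.3 * rng.standard_normal(p.shape) for p in lay.params()])
        th = rng.standard_normal((5, 3))
        x = rng.standard_normal((5, 3))
        g = rng.standard_normal(5)
        _, u, caches = flow._forward(th, x)
        grads = flow._backward(caches, u, g)
        params = flow._all_params()
        eps = 1e-6
        checked = 0
        for pi, p in enumerate(params):
            flat = p.reshape(-1)
            for k in range(0, flat.size, max(1, flat.size // 3)):
                old = flat[k]
                flat[k] = old + eps
                lp = float((g * flow._forward(th, x)[0]).sum())
                flat[k] = old - eps
                lm = float((g * flow._forward(th, x)[0]).sum())
                flat[k] = old
                num = (lp - lm) / (2 * eps)
                ana = grads[pi].reshape(-1)[k]
                assert num == pytest.approx(ana, abs=1e-6, rel=1e-4)
                checked += 1
        assert checked > 20


class TestTraining:
    def test_conjugate_posterior_mean_recovered(self, lg_npe_flow):
        x_obs = np.array([1.0, 1.0, 1.0])
        s = lg_npe_flow.sample(20_000, x_obs, seed=4)
        np.testing.assert_allclose(s.mean(axis=0), lg_posterior_mean(x_obs), atol=0.05)

    def test_validation_loss_improves_over_first_epoch(self, lg_npe_flow):
        hist = lg_npe_flow.history["val_loss"]
        assert min(hist) <= hist[0]

    def test_uninformative_conditioning_recovers_marginal(self):
        # constant x carries no information; the fit returns the theta marginal
        rng = np.random.default_rng(1)
        thetas = 0.5 + 1.5 * rng.standard_normal((4_000, 3))
        xs = np.zeros((4_000, 3))
        cfg = FlowConfig(hidden_units=20, n_transforms=3, max_epochs=30, standardise=False, seed=2)
        flow = build_flow(cfg)
        fit_ml(flow, thetas, xs, cfg)
        s = flow.sample(10_000, np.zeros(3), seed=0)
        np.testing.assert_allclose(s.mean(axis=0), np.full(3, 0.5), atol=0.15)
        np.testing.assert_allclose(s.std(axis=0), np.full(3, 1.5), atol=0.25)

    def test_zero_variance_column_raises_with_hint(self):
        thetas = np.random.default_rng(0).standard_normal((100, 3))
        xs = np.zeros((100, 3))
        cfg = FlowConfig(hidden_units=4, n_transforms=1, seed=0)
        flow = build_flow(cfg)
        with pytest.raises(FlowError, match="zero variance"):
            fit_ml(flow, thetas, xs, cfg)

    def test_too_few_pairs_rejected(self):
        cfg = FlowConfig(hidden_units=4, n_transforms=1)
        with pytest.raises(FlowError):
            fit_ml(build_flow(cfg), np.zeros((1, 3)), np.zeros((1, 3)), cfg)

    def test_standardisation_round_trip(self):
        rng = np.random.default_rng(5)
        thetas = 2.0 + 3.0 * rng.standard_normal((4_000, 3))
        xs = thetas + 0.3 * rng.standard_normal((4_000, 3))
        cfg_a = FlowConfig(hidden_units=20, n_transforms=3, max_epochs=25, seed=6)
        fa = fit_ml(build_flow(cfg_a), thetas, xs, cfg_a)
        t_loc, t_sc = thetas.mean(0), thetas.std(0)
        x_loc, x_sc = xs.mean(0), xs.std(0)
        cfg_b = FlowConfig(
            hidden_units=20, n_transforms=3, max_epochs=25, standardise=False, seed=6
        )
        fb = fit_ml(build_flow(cfg_b), (thetas - t_loc) / t_sc, (xs - x_loc) / x_sc, cfg_b)
        x_obs = np.array([2.0, 2.0, 2.0])
        ma = fa.sample(8_000, x_obs, seed=1).mean(axis=0)
        mb = fb.sample(8_000, (x_obs - x_loc) / x_sc, seed=1).mean(axis=0) * t_sc + t_loc
        np.testing.assert_allclose(ma, mb, atol=0.2)


class TestAtomicLoss:
    def _prior_matched_flow(self):
        # identity-initialised flow with unit standardisation equals N(0, I),
        # so with a N(0, I) prior every atomic logit is exactly zero
        return build_flow(FlowConfig(hidden_units=6, n_transforms=2, seed=0))

    def test_single_atom_gives_zero(self, unit_prior):
        flow = self._prior_matched_flow()
        rng = np.random.default_rng(0)
        batch = _pairs(rng.standard_normal((30, 3)), rng.standard_normal((30, 3)))
        assert atomic_loss(flow, batch, unit_prior, 1) == pytest.approx(0.0)

    @pytest.mark.parametrize("n_atoms", [2, 5, 10])
    def test_constant_ratio_gives_log_n_atoms(self, unit_prior, n_atoms):
        flow = self._prior_matched_flow()
        rng = np.random.default_rng(1)
        batch = _pairs(rng.standard_normal((30, 3)), rng.standard_normal((30, 3)))
        assert atomic_loss(flow, batch, unit_prior, n_atoms) == pytest.approx(
            np.log(n_atoms), abs=1e-9
        )

    def test_invariant_to_constant_rescaling_of_q(self, unit_prior):
        rng = np.random.default_rng(2)
        batch = _pairs(rng.standard_normal((25, 3)), rng.standard_normal((25, 3)))
        flow = build_flow(FlowConfig(hidden_units=6, n_transforms=2, seed=5))

        class Scaled(type(flow)):
            def _forward(self, t, x):
                logq, u, c = super()._forward(t, x)
                return logq + 123.4, u, c  # unnormalised constant multiple

        scaled = Scaled(flow.cfg, 3, 3)
        scaled._set_all_params(flow.snapshot())
        base = atomic_loss(flow, batch, unit_prior, 5, seed=3)
        same = atomic_loss(scaled, batch, unit_prior, 5, seed=3)
        assert same == pytest.approx(base, abs=1e-9)

    def test_atoms_exceeding_batch_rejected(self, unit_prior):
        flow = self._prior_matched_flow()
        batch = _pairs(np.zeros((3, 3)), np.zeros((3, 3)))
        with pytest.raises(FlowError):
            atomic_loss(flow, batch, unit_prior, 10)


class TestNormalisation:
    def test_trained_conditional_density_integrates_to_one(self, lg_npe_flow):
        # importance-sampling estimate of the integral of q(theta | x_obs)
        x_obs = np.array([0.5, -0.5, 1.0])
        rng = np.random.default_rng(8)
        ref_mean = lg_posterior_mean(x_obs)
        draws = ref_mean + 1.0 * rng.standard_normal((40_000, 3))
        log_ref = (
            -0.5 * ((draws - ref_mean) ** 2).sum(axis=1) - 1.5 * np.log(2 * np.pi)
        )
        logq = lg_npe_flow.log_prob(draws, x_obs)
        est = np.exp(logq - log_ref).mean()
        assert est == pytest.approx(1.0, abs=0.05)


class TestPersistence:
    def test_checkpoint_round_trip(self, tmp_path, lg_npe_flow):
        path = tmp_path / "flow.npz"
        save_flow(lg_npe_flow, path)
        loaded = load_flow(path)
        x = np.array([1.0, 0.0, -1.0])
        th = np.random.default_rng(0).standard_normal((10, 3))
        np.testing.assert_allclose(loaded.log_prob(th, x), lg_npe_flow.log_prob(th, x))
        np.testing.assert_allclose(loaded.sample(20, x, seed=2), lg_npe_flow.sample(20, x, seed=2))
        assert loaded.trained
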