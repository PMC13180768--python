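"""Neural likelihood (NLE) and neural ratio (NRE) estimation comparators.

Both learn from the same simulated ``(theta, x)`` pairs as posterior
estimation but target different objects:

* NLE fits the same masked autoregressive flow with the roles swapped — a
  density over the statistics ``x`` conditioned on ``theta`` — giving a
  fast surrogate for the intractable ERGM likelihood ``p(x | theta)``.
* NRE trains a binary classifier ``D(theta, x)`` separating joint pairs
  from shuffled (product-of-marginals) pairs; the ratio
  ``r(theta, x) = D / (1 - D)`` estimates ``p(x | theta) / p(x)``.

Neither is amortised at the posterior level: inference still runs MCMC on
``log pi(theta) + log q(x_obs | theta)`` (NLE) or
``log pi(theta) + log r(theta, x_obs)`` (NRE).  The sampler is an adaptive
random-walk Metropolis updating several chains in one batched operation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.neural_network import MLPClassifier

from .exchange import PosteriorSamples
from .flows import ConditionalMAF, FlowConfig, fit_ml
from .priors import PriorSpec
from .simulator import TrainingPairs


class SurrogateError(ValueError):
    pass


@dataclass(frozen=True)
class RatioClassifierConfig:
    """MLP classifier settings for ratio estimation."""

    hidden_units: int = 50
    layers: int = 2
    batch_size: int = 200
    learning_rate: float = 1e-3
    patience_epochs: int = 20
    max_epochs: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hidden_units < 1 or self.layers < 1:
            raise SurrogateError("hidden_units and layers must be positive")


@dataclass(frozen=True)
class SurrogateMCMCConfig:
    """Batched random-walk Metropolis settings."""

    n_chains: int = 8
    n_steps: int = 2_000
    burn_in: int = 500
    initial_step: float = 0.3
    adapt_window: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chains < 1 or self.n_steps < 1:
            raise SurrogateError("n_chains and n_steps must be >= 1")


def train_nle(pairs: TrainingPairs, flow_cfg: FlowConfig) -> ConditionalMAF:
    """Likelihood surrogate: MAF over statistics x conditioned on theta."""
    if len(pairs) < 2:
        raise SurrogateError("need at least 2 pairs to train NLE")
    flow = ConditionalMAF(
        flow_cfg, dim_theta=pairs.stats.shape[1], dim_x=pairs.thetas.shape[1]
    )
    fit_ml(flow, pairs.stats, pairs.thetas, flow_cfg)
    return flow


class RatioEstimator:
    """Classifier-based estimate of ``p(x | theta) / p(x)``."""

    def __init__(self, clf: MLPClassifier, loc: np.ndarray, scale: np.ndarray):
        self.clf = clf
        self.loc = loc
        self.scale = scale

    def _features(self, thetas: np.ndarray, xs: np.ndarray) -> np.ndarray:
        f = np.hstack([np.atleast_2d(thetas), np.atleast_2d(xs)])
        return (f - self.loc) / self.scale

    def log_ratio(self, thetas: np.ndarray, xs: np.ndarray) -> np.ndarray:
        """``log r = logit D(theta, x)`` from the classifier probabilities."""
        logp = self.clf.predict_log_proba(self._features(thetas, xs))
        return logp[:, 1] - logp[:, 0]

    def predict_proba(self, thetas: np.ndarray, xs: np.ndarray) -> np.ndarray:
        return self.clf.predict_proba(self._features(thetas, xs))[:, 1]


def train_nre(
    pairs: TrainingPairs,
    prior: PriorSpec,
    cfg: RatioClassifierConfig,
) -> RatioEstimator:
    """Ratio surrogate from joint-vs-shuffled classification.

    Negatives are formed by permuting theta against x within the training
    set (the standard product-of-marginals construction); label 1 = joint.
    """
    n = len(pairs)
    if n < 2:
        raise SurrogateError("need at least 2 pairs to train NRE")
    rng = np.random.default_rng(cfg.seed)
    perm = rng.permutation(n)
    # derangement-ish: avoid fixed points so negatives are genuine shuffles
    fixed = np.flatnonzero(perm == np.arange(n))
    if fixed.size:
        perm[fixed] = np.roll(perm[fixed], 1)
    feats = np.vstack(
        [
            np.hstack([pairs.thetas, pairs.stats]),
            np.hstack([pairs.thetas[perm], pairs.stats]),
        ]
    )
    labels = np.concatenate([np.ones(n), np.zeros(n)])
    loc = feats.mean(axis=0)
    scale = feats.std(axis=0)
    scale[scale == 0] = 1.0
    clf = MLPClassifier(
        hidden_layer_sizes=tuple([cfg.hidden_units] * cfg.layers),
        batch_size=min(cfg.batch_size, 2 * n),
        learning_rate_init=cfg.learning_rate,
        max_iter=cfg.max_epochs,
        early_stopping=True,
        n_iter_no_change=cfg.patience_epochs,
        validation_fraction=0.1,
        random_state=cfg.seed,
    )
    clf.fit((feats - loc) / scale, labels)
    return RatioEstimator(clf, loc, scale)


class OracleRatio:
    """Analytically supplied log-ratio, used to isolate MCMC correctness."""

    def __init__(self, log_ratio_fn):
        self._fn = log_ratio_fn

    def log_ratio(self, thetas: np.ndarray, xs: np.ndarray) -> np.ndarray:
        return np.asarray(self._fn(np.atleast_2d(thetas), np.atleast_2d(xs)), dtype=float)


def _surrogate_log_target(surrogate, prior: PriorSpec, x_obs: np.ndarray):
    x_obs = np.asarray(x_obs, dtype=float).reshape(1, -1)

    if isinstance(surrogate, ConditionalMAF):

        def log_target(thetas: np.ndarray) -> np.ndarray:
            xs = np.broadcast_to(x_obs, (len(thetas), x_obs.size))
            return np.asarray(prior.log_pdf(thetas)) + surrogate.log_prob(xs, thetas)

    elif hasattr(surrogate, "log_ratio"):

        def log_target(thetas: np.ndarray) -> np.ndarray:
            xs = np.broadcast_to(x_obs, (len(thetas), x_obs.size))
            return np.asarray(prior.log_pdf(thetas)) + surrogate.log_ratio(thetas, xs)

    else:
        raise SurrogateError(f"unsupported surrogate type {type(surrogate)!r}")
    return log_target


def mcmc_sample_surrogate(
    surrogate,
    prior: PriorSpec,
    x_obs: np.ndarray,
    cfg: SurrogateMCMCConfig,
) -> PosteriorSamples:
    """Adaptive random-walk Metropolis on the surrogate posterior.

    All chains advance in one vectorised proposal/evaluation per step;
    during burn-in the step size adapts towards a 20-40% acceptance rate.
    Pooled post-burn-in draws are returned with the split-chain spread
    recorded via the acceptance-rate metadata.
    """
    log_target = _surrogate_log_target(surrogate, prior, x_obs)
    rng = np.random.default_rng(cfg.seed)
    dim = prior.dim
    theta = prior.sample(cfg.n_chains, rng)
    lt = log_target(theta)
    if not np.any(np.isfinite(lt)):
        raise SurrogateError("all chains started at non-finite surrogate target")
    step = cfg.initial_step
    kept = []
    acc_window: list[float] = []
    n_acc = 0
    n_tot = 0
    for t in range(cfg.n_steps):
        prop = theta + step * rng.standard_normal((cfg.n_chains, dim))
        lt_prop = log_target(prop)
        logu = np.log(rng.random(cfg.n_chains))
        accept = (lt_prop - lt) > logu
        theta = np.where(accept[:, None], prop, theta)
        lt = np.where(accept, lt_prop, lt)
        if t < cfg.burn_in:
            acc_window.append(accept.mean())
            if len(acc_window) == cfg.adapt_window:
                rate = float(np.mean(acc_window))
                if rate < 0.20:
                    step *= 0.7
                elif rate > 0.40:
                    step *= 1.4
                acc_window.clear()
        else:
            kept.append(theta.copy())
            n_acc += int(accept.sum())
            n_tot += cfg.n_chains
    draws = np.concatenate(kept, axis=0)
    if not np.all(np.isfinite(draws)):
        raise SurrogateError("non-finite draws from surrogate MCMC")
    method = "nle" if isinstance(surrogate, ConditionalMAF) else "nre"
    return PosteriorSamples(
        draws=draws,
        method=method,
        x_obs=np.asarray(x_obs, dtype=float).reshape(-1),
        acceptance_rate=n_acc / max(n_tot, 1),
        seed=int(cfg.seed),
    )
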