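"""Approximate exchange algorithm: reference Bayesian ERGM posterior sampler.

The ERGM posterior is doubly intractable — the likelihood's normalising
constant ``c(theta)`` cannot be evaluated.  The exchange algorithm targets
an augmented posterior with an auxiliary network ``y' ~ ERGM(theta')``
simulated at every proposed ``theta' ~ N(theta, Sigma)``, so the constants
cancel and the log acceptance ratio reduces to

    log pi(theta') - log pi(theta)
        + (theta' - theta) . h(y_obs) + (theta - theta') . h(y')

which never touches ``c(theta)``.  The marginal of the augmented chain in
``theta`` is the original posterior.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .graph import Graph, StatisticConfig, compute_stats
from .priors import PriorSpec
from .simulator import SimulatorConfig, simulate_network


class ExchangeError(ValueError):
    pass


def _default_proposal_cov() -> np.ndarray:
    return 0.1 * np.eye(3)


@dataclass(frozen=True)
class ExchangeConfig:
    """Settings for one exchange-algorithm run.

    ``proposal_cov`` is the random-walk covariance ``Sigma``; with
    ``adapt_proposal`` the scale is tuned during burn-in towards a 20-40%
    acceptance rate (the shape is kept).
    """

    proposal_cov: np.ndarray = field(default_factory=_default_proposal_cov)
    burn_in: int = 1_000
    n_samples: int = 6_000
    adapt_proposal: bool = False
    sim: SimulatorConfig = field(default_factory=SimulatorConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        c = np.atleast_2d(np.asarray(self.proposal_cov, dtype=float))
        try:
            np.linalg.cholesky(c)
        except np.linalg.LinAlgError as exc:
            raise ExchangeError("proposal covariance is not SPD") from exc
        object.__setattr__(self, "proposal_cov", c)
        if self.n_samples < 1:
            raise ExchangeError("n_samples must be >= 1")
        if self.burn_in < 0:
            raise ExchangeError("burn_in must be >= 0")


@dataclass
class PosteriorSamples:
    """Posterior draws with provenance: method tag, conditioning data, seed."""

    draws: np.ndarray  # (S, 3)
    method: str
    x_obs: np.ndarray | None
    acceptance_rate: float
    seed: int

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.draws)):
            raise ExchangeError("posterior draws contain non-finite values")
        if not 0.0 <= self.acceptance_rate <= 1.0:
            raise ExchangeError("acceptance rate outside [0, 1]")

    def __len__(self) -> int:
        return len(self.draws)

    def mean(self) -> np.ndarray:
        return self.draws.mean(axis=0)

    def std(self) -> np.ndarray:
        return self.draws.std(axis=0, ddof=1)

    def quantiles(self, qs=(0.025, 0.5, 0.975)) -> np.ndarray:
        return np.quantile(self.draws, qs, axis=0)


def log_acceptance_ratio(
    theta: np.ndarray,
    theta_prime: np.ndarray,
    h_obs: np.ndarray,
    h_aux: np.ndarray,
    prior: PriorSpec,
) -> float:
    """Log exchange acceptance ratio; normalising constants never appear."""
    theta = np.asarray(theta, dtype=float)
    theta_prime = np.asarray(theta_prime, dtype=float)
    h_obs = np.asarray(h_obs, dtype=float)
    h_aux = np.asarray(h_aux, dtype=float)
    d_prior = float(prior.log_pdf(theta_prime)[0] - prior.log_pdf(theta)[0])
    return d_prior + float((theta_prime - theta) @ h_obs + (theta - theta_prime) @ h_aux)


def run_exchange(
    y_obs: Graph,
    prior: PriorSpec,
    cfg: ExchangeConfig,
    stat_cfg: StatisticConfig | None = None,
) -> PosteriorSamples:
    """Sample the ERGM posterior for one observed network.

    Each MCMC step simulates one fresh auxiliary network at the proposed
    parameter (re-initialised from ``cfg.sim.init_mode``), so a run costs
    ``(burn_in + n_samples)`` network simulations.
    """
    stat_cfg = stat_cfg or StatisticConfig()
    h_obs = compute_stats(y_obs, stat_cfg)
    sim = cfg.sim
    if sim.n_vertices != y_obs.n_vertices:
        sim = replace(sim, n_vertices=y_obs.n_vertices)
    if sim.init_mode == "observed" and sim.init_graph is None:
        sim = replace(sim, init_graph=y_obs)
    rng = np.random.default_rng(int(cfg.seed))
    chol = np.linalg.cholesky(cfg.proposal_cov)
    scale = 1.0
    theta = prior.mean.astype(float).copy()
    total = cfg.burn_in + cfg.n_samples
    draws = np.empty((cfg.n_samples, 3))
    accepted_post = 0
    window_acc: list[bool] = []
    for t in range(total):
        theta_prime = theta + scale * (chol @ rng.standard_normal(3))
        aux_seed = int(rng.integers(0, 2**31 - 1))
        _, h_aux = simulate_network(theta_prime, replace(sim, seed=aux_seed), stat_cfg)
        log_ar = log_acceptance_ratio(theta, theta_prime, h_obs, h_aux, prior)
        accept = log_ar >= 0 or rng.random() < np.exp(log_ar)
        if accept:
            theta = theta_prime
        if t < cfg.burn_in:
            if cfg.adapt_proposal:
                window_acc.append(accept)
                if len(window_acc) == 50:
                    rate = np.mean(window_acc)
                    if rate < 0.20:
                        scale *= 0.8
                    elif rate > 0.40:
                        scale *= 1.25
                    window_acc.clear()
        else:
            draws[t - cfg.burn_in] = theta
            accepted_post += accept
    return PosteriorSamples(
        draws=draws,
        method="exchange",
        x_obs=h_obs,
        acceptance_rate=accepted_post / cfg.n_samples,
        seed=int(cfg.seed),
    )


def grid_posterior_mean(
    exact_model,
    x_obs: np.ndarray,
    prior: PriorSpec,
    grid_half_width: float = 3.0,
    grid_points: int = 25,
) -> tuple[np.ndarray, np.ndarray]:
    """Posterior mean/sd on a 3-D grid using exact ``c(theta)`` (toy oracle).

    ``pi(theta | x) ∝ pi(theta) exp(theta . x) / c(theta)`` evaluated on a
    regular grid centred at the prior mean; only valid for the enumeration
    sizes where ``c(theta)`` is exact.  Independent of any MCMC machinery,
    so it serves as the oracle the exchange chain is checked against.
    """
    x_obs = np.asarray(x_obs, dtype=float)
    axes = [
        np.linspace(m - grid_half_width, m + grid_half_width, grid_points)
        for m in prior.mean
    ]
    tt = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    log_c = np.array([exact_model.log_normaliser_at(t) for t in tt])
    log_post = prior.log_pdf(tt) + tt @ x_obs - log_c
    log_post -= log_post.max()
    wgt = np.exp(log_post)
    wgt /= wgt.sum()
    mean = wgt @ tt
    var = wgt @ (tt - mean) ** 2
    return mean, np.sqrt(var)
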