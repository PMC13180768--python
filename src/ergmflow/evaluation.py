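"""Bias-evaluation design, error metrics, and graph-space magnitude mapping.

The bias study draws K "true" parameters from the prior, stratified by the
mean edge count of pilot simulations into sparse-graph strata (the default
design uses 10 truths in each of [0,275), [275,550), [550,825), [825,1100)
for 90-vertex networks, rejecting anything at or above 1,100 edges where
the geometrically weighted statistics become collinear).  For each truth,
M replicate observations are simulated, a posterior mean is computed for
each, and averaging over replicates gives the point estimate entering
componentwise ME / MAE / RMSE.

Because raw parameter-space errors are hard to interpret, the magnitude
assessment maps everything back to the statistic space: bias at a truth is
"small" for a component when the mean of the posterior-predictive sample
lies within the 5th-95th percentile band of a large reference sample
simulated at the truth, and an empirical coverage rate (fraction of
reference draws inside the predictive sample's range) is reported for
large-bias cases.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .exchange import PosteriorSamples
from .graph import StatisticConfig
from .priors import PriorSpec
from .simulator import SimulatorConfig, simulate_network


class EvaluationError(ValueError):
    pass


def _default_strata() -> tuple[float, ...]:
    return (0.0, 275.0, 550.0, 825.0, 1100.0)


@dataclass(frozen=True)
class BiasDesign:
    """Stratified study design for bias evaluation."""

    K: int = 40
    M: int = 1_000
    strata: tuple[float, ...] = field(default_factory=_default_strata)
    per_stratum: int = 10
    edge_cap: float = 1_100.0
    posterior_draws: int = 100_000
    pilot_sims: int = 25
    max_attempts_per_stratum: int = 2_000
    seed: int = 0

    def __post_init__(self) -> None:
        s = tuple(float(v) for v in self.strata)
        if any(b <= a for a, b in zip(s, s[1:])):
            raise EvaluationError("strata boundaries must be strictly increasing")
        if self.per_stratum * (len(s) - 1) != self.K:
            raise EvaluationError(
                f"per_stratum * n_strata = {self.per_stratum * (len(s) - 1)} != K = {self.K}"
            )
        object.__setattr__(self, "strata", s)


@dataclass
class BiasReport:
    """Componentwise error summaries over the K truths."""

    truths: np.ndarray  # (K, 3)
    estimates: np.ndarray  # (K, 3)
    me: np.ndarray
    mae: np.ndarray
    rmse: np.ndarray


@dataclass
class MagnitudeReport:
    """Graph-space (statistic-space) bias magnitude for one truth."""

    small_bias: np.ndarray  # (3,) bool, percentile criterion
    coverage_percent: np.ndarray  # (3,) in [0, 100]
    reference_mean: np.ndarray
    predictive_mean: np.ndarray


def stratified_truths(
    prior: PriorSpec,
    design: BiasDesign,
    sim: SimulatorConfig,
    stat_cfg: StatisticConfig | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Rejection-sample truths from the prior into edge-count strata.

    Candidates are pilot-simulated (``design.pilot_sims`` networks each) and
    assigned to a stratum by mean edge count; sampling continues until each
    stratum holds ``per_stratum`` accepted parameters.  Returns the (K, 3)
    truth matrix and the (K,) stratum labels.
    """
    stat_cfg = stat_cfg or StatisticConfig()
    n_strata = len(design.strata) - 1
    buckets: list[list[np.ndarray]] = [[] for _ in range(n_strata)]
    rng = np.random.default_rng(design.seed)
    attempts = 0
    budget = design.max_attempts_per_stratum * n_strata
    while any(len(b) < design.per_stratum for b in buckets):
        if attempts >= budget:
            lacking = [
                f"[{design.strata[i]:g}, {design.strata[i + 1]:g})"
                for i, b in enumerate(buckets)
                if len(b) < design.per_stratum
            ]
            raise EvaluationError(
                f"could not fill stratum {', '.join(lacking)} within "
                f"{budget} candidate draws"
            )
        attempts += 1
        theta = prior.sample(1, rng)[0]
        edges = np.empty(design.pilot_sims)
        for p in range(design.pilot_sims):
            sub = replace(sim, seed=int(rng.integers(0, 2**31 - 1)))
            _, st = simulate_network(theta, sub, stat_cfg)
            edges[p] = st[0]
        mean_edges = edges.mean()
        if mean_edges >= design.edge_cap:
            continue
        s = int(np.searchsorted(design.strata, mean_edges, side="right") - 1)
        if s < 0 or s >= n_strata or len(buckets[s]) >= design.per_stratum:
            continue
        buckets[s].append(theta)
    truths = np.vstack([t for b in buckets for t in b])
    labels = np.repeat(np.arange(n_strata), design.per_stratum)
    return truths, labels


def bias_metrics(truths: np.ndarray, estimates: np.ndarray) -> BiasReport:
    """ME / MAE / RMSE of point estimates against the truths, componentwise."""
    truths = np.atleast_2d(np.asarray(truths, dtype=float))
    estimates = np.atleast_2d(np.asarray(estimates, dtype=float))
    if truths.shape != estimates.shape:
        raise EvaluationError(
            f"shape mismatch: truths {truths.shape} vs estimates {estimates.shape}"
        )
    err = estimates - truths
    return BiasReport(
        truths=truths,
        estimates=estimates,
        me=err.mean(axis=0),
        mae=np.abs(err).mean(axis=0),
        rmse=np.sqrt((err * err).mean(axis=0)),
    )


def magnitude_assessment(
    theta_true: np.ndarray,
    posterior_means: np.ndarray,
    sim: SimulatorConfig,
    stat_cfg: StatisticConfig | None = None,
    n_reference: int = 100_000,
    per_mean_sims: int = 100,
    seed: int = 0,
) -> MagnitudeReport:
    """Map bias at one truth back to the statistic space.

    Simulates ``n_reference`` networks at the truth and ``per_mean_sims``
    networks at each posterior mean; flags a component as small-bias when
    the predictive mean falls inside the reference 5th-95th percentile
    band, and reports coverage as the percentage of reference draws inside
    the predictive sample's min-max range.
    """
    stat_cfg = stat_cfg or StatisticConfig()
    posterior_means = np.atleast_2d(np.asarray(posterior_means, dtype=float))
    if posterior_means.size == 0:
        raise EvaluationError("posterior_means must be non-empty")
    if n_reference < 1 or per_mean_sims < 1:
        raise EvaluationError("simulation budgets must be positive")
    rng = np.random.default_rng(seed)
    theta_true = np.asarray(theta_true, dtype=float)
    ref = np.empty((n_reference, 3))
    for i in range(n_reference):
        sub = replace(sim, seed=int(rng.integers(0, 2**31 - 1)))
        _, ref[i] = simulate_network(theta_true, sub, stat_cfg)
    pred = np.empty((len(posterior_means) * per_mean_sims, 3))
    k = 0
    for pm in posterior_means:
        for _ in range(per_mean_sims):
            sub = replace(sim, seed=int(rng.integers(0, 2**31 - 1)))
            _, pred[k] = simulate_network(pm, sub, stat_cfg)
            k += 1
    lo, hi = np.percentile(ref, [5, 95], axis=0)
    pred_mean = pred.mean(axis=0)
    small = (pred_mean >= lo) & (pred_mean <= hi)
    pmin, pmax = pred.min(axis=0), pred.max(axis=0)
    coverage = 100.0 * ((ref >= pmin) & (ref <= pmax)).mean(axis=0)
    return MagnitudeReport(
        small_bias=small,
        coverage_percent=coverage,
        reference_mean=ref.mean(axis=0),
        predictive_mean=pred_mean,
    )


def posterior_predictive(
    samples: PosteriorSamples,
    sim: SimulatorConfig,
    stat_cfg: StatisticConfig | None = None,
    n_draws: int = 1_000,
    seed: int = 0,
) -> np.ndarray:
    """Statistics of networks simulated at resampled posterior draws."""
    stat_cfg = stat_cfg or StatisticConfig()
    if len(samples) == 0:
        raise EvaluationError("empty posterior sample")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(samples.draws), size=int(n_draws))
    out = np.empty((int(n_draws), 3))
    for i, k in enumerate(idx):
        sub = replace(sim, seed=int(rng.integers(0, 2**31 - 1)))
        _, out[i] = simulate_network(samples.draws[k], sub, stat_cfg)
    return out
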