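"""Network simulation from ERGM(theta) and exact small-graph enumeration.

An ERGM places probability ``p(y | theta) = exp(theta . h(y)) / c(theta)``
on every simple graph ``y``; the normalising constant ``c(theta)`` sums over
the full graph space and is intractable beyond toy sizes. Simulation is by
single-dyad Metropolis--Hastings: propose toggling one uniformly chosen dyad
and accept with probability ``min(1, exp(theta . delta_h))`` where
``delta_h`` is the change statistic of the toggle. The chain length per
simulated network (``aux_iterations``) follows the auxiliary-MCMC
convention of exchange-algorithm samplers.

A tie/no-tie (TNT) proposal — half the proposals drawn uniformly from the
current edges — is available behind a flag for very sparse regimes; the
plain uniform-dyad kernel is the default.

The inner loop is JIT-compiled with numba; for ``n <= 7`` vertices an exact
enumeration over all ``2^(n(n-1)/2)`` graphs provides an oracle for the
statistic distribution, moments and ``log c(theta)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

from .graph import Graph, GraphError, StatisticConfig, compute_stats, gw_weights

ENUM_MAX_VERTICES = 7


class SimulatorError(ValueError):
    pass


@dataclass(frozen=True)
class SimulatorConfig:
    """Auxiliary-chain settings for one ERGM network simulation.

    ``init_mode`` selects the starting graph: ``empty`` / ``full`` /
    ``observed`` or ``provided`` (both of which require ``init_graph``).
    Initialisation genuinely matters in multi-modal regimes, so it is always
    explicit and user-controllable.
    """

    n_vertices: int = 90
    aux_iterations: int = 10_000
    init_mode: str = "empty"
    init_graph: Graph | None = None
    kernel: str = "plain"  # "plain" | "tnt"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_vertices < 1:
            raise SimulatorError(f"n_vertices must be >= 1, got {self.n_vertices}")
        if self.aux_iterations < 0:
            raise SimulatorError("aux_iterations must be >= 0")
        if self.init_mode not in ("empty", "full", "observed", "provided"):
            raise SimulatorError(f"unknown init_mode {self.init_mode!r}")
        # "observed" may be filled in later (e.g. by the exchange runner);
        # "provided" must carry its graph from the start
        if self.init_mode == "provided" and self.init_graph is None:
            raise SimulatorError("init_mode='provided' requires init_graph")
        if self.kernel not in ("plain", "tnt"):
            raise SimulatorError(f"unknown kernel {self.kernel!r}")


@dataclass
class TrainingPairs:
    """B simulated (theta_b, x_b) pairs with round provenance and seeds."""

    thetas: np.ndarray  # (B, 3)
    stats: np.ndarray  # (B, 3)
    round_index: np.ndarray  # (B,), >= 1
    seeds: np.ndarray  # (B,) per-pair simulation seed

    def __post_init__(self) -> None:
        if not (len(self.thetas) == len(self.stats) == len(self.round_index) == len(self.seeds)):
            raise SimulatorError("TrainingPairs row counts differ")

    def __len__(self) -> int:
        return len(self.thetas)

    @staticmethod
    def concatenate(parts: list["TrainingPairs"]) -> "TrainingPairs":
        return TrainingPairs(
            np.concatenate([p.thetas for p in parts]),
            np.concatenate([p.stats for p in parts]),
            np.concatenate([p.round_index for p in parts]),
            np.concatenate([p.seeds for p in parts]),
        )


# ---------------------------------------------------------------------------
# numba kernels
# ---------------------------------------------------------------------------


@njit(cache=True)
def _delta_add(adj, i, j, w):
    """(d_gwesp, d_gwnsp) for adding edge (i, j); requires adj[i, j] == 0."""
    n = adj.shape[0]
    c = 0
    for k in range(n):
        if adj[i, k] == 1 and adj[j, k] == 1:
            c += 1
    d_esp = w[c]
    d_nsp = -w[c]
    for k in range(n):
        if k == i or k == j:
            continue
        if adj[j, k] == 1:  # pair (i, k) gains shared partner j
            s = 0
            for m in range(n):
                if adj[i, m] == 1 and adj[k, m] == 1:
                    s += 1
            dw = w[s + 1] - w[s]
            if adj[i, k] == 1:
                d_esp += dw
            else:
                d_nsp += dw
        if adj[i, k] == 1:  # pair (j, k) gains shared partner i
            s = 0
            for m in range(n):
                if adj[j, m] == 1 and adj[k, m] == 1:
                    s += 1
            dw = w[s + 1] - w[s]
            if adj[j, k] == 1:
                d_esp += dw
            else:
                d_nsp += dw
    return d_esp, d_nsp


@njit(cache=True)
def _run_chain_plain(adj, theta, w, n_iters, seed):
    np.random.seed(seed)
    n = adj.shape[0]
    for _ in range(n_iters):
        i = np.random.randint(0, n)
        j = np.random.randint(0, n - 1)
        if j >= i:
            j += 1
        removing = adj[i, j] == 1
        if removing:
            adj[i, j] = 0
            adj[j, i] = 0
        de, dn = _delta_add(adj, i, j, w)
        logr = theta[0] + theta[1] * de + theta[2] * dn
        if removing:
            logr = -logr
        accept = logr >= 0.0 or np.random.random() < np.exp(logr)
        if accept != removing:
            adj[i, j] = 1
            adj[j, i] = 1
    return adj


@njit(cache=True)
def _run_chain_tnt(adj, theta, w, n_iters, seed):
    """Tie/no-tie kernel: half the proposals pick a uniform existing edge.

    Proposal probabilities are asymmetric in the edge count, so the
    Metropolis--Hastings ratio carries the q-correction.
    """
    np.random.seed(seed)
    n = adj.shape[0]
    ndyads = n * (n - 1) // 2
    # maintain an edge list for uniform edge picks
    max_e = ndyads
    ei = np.empty(max_e, dtype=np.int64)
    ej = np.empty(max_e, dtype=np.int64)
    pos = -np.ones((n, n), dtype=np.int64)
    ne = 0
    for a in range(n):
        for b in range(a + 1, n):
            if adj[a, b] == 1:
                ei[ne] = a
                ej[ne] = b
                pos[a, b] = ne
                ne += 1
    for _ in range(n_iters):
        if ne > 0 and np.random.random() < 0.5:
            k = np.random.randint(0, ne)
            i, j = ei[k], ej[k]
        else:
            i = np.random.randint(0, n)
            j = np.random.randint(0, n - 1)
            if j >= i:
                j += 1
        if i > j:
            i, j = j, i
        removing = adj[i, j] == 1
        if removing:
            adj[i, j] = 0
            adj[j, i] = 0
        de, dn = _delta_add(adj, i, j, w)
        logr = theta[0] + theta[1] * de + theta[2] * dn
        # forward/backward proposal probabilities of picking this dyad
        if removing:
            qf = 0.5 / ne + 0.5 / ndyads
            qb = 0.5 / ndyads if ne - 1 > 0 else 1.0 / ndyads
            logr = -logr + np.log(qb) - np.log(qf)
        else:
            qf = 0.5 / ndyads if ne > 0 else 1.0 / ndyads
            qb = 0.5 / (ne + 1) + 0.5 / ndyads
            logr = logr + np.log(qb) - np.log(qf)
        accept = logr >= 0.0 or np.random.random() < np.exp(logr)
        if removing:
            if accept:  # drop from edge list
                k = pos[i, j]
                ne -= 1
                if k != ne:
                    ei[k], ej[k] = ei[ne], ej[ne]
                    pos[ei[k], ej[k]] = k
                pos[i, j] = -1
            else:
                adj[i, j] = 1
                adj[j, i] = 1
        else:
            if accept:
                adj[i, j] = 1
                adj[j, i] = 1
                ei[ne] = i
                ej[ne] = j
                pos[i, j] = ne
                ne += 1
    return adj


@njit(cache=True)
def _enumerate_stats(n, w):
    """Statistic vector of every labelled simple graph on n vertices."""
    ndyads = n * (n - 1) // 2
    total = 1 << ndyads
    out = np.empty((total, 3), dtype=np.float64)
    iu = np.empty(ndyads, dtype=np.int64)
    ju = np.empty(ndyads, dtype=np.int64)
    t = 0
    for a in range(n):
        for b in range(a + 1, n):
            iu[t] = a
            ju[t] = b
            t += 1
    adj = np.zeros((n, n), dtype=np.uint8)
    for code in range(total):
        for t in range(ndyads):
            bit = (code >> t) & 1
            adj[iu[t], ju[t]] = bit
            adj[ju[t], iu[t]] = bit
        edges = 0.0
        gwesp = 0.0
        gwnsp = 0.0
        for a in range(n):
            for b in range(a + 1, n):
                s = 0
                for m in range(n):
                    if adj[a, m] == 1 and adj[b, m] == 1:
                        s += 1
                if adj[a, b] == 1:
                    edges += 1.0
                    gwesp += w[s]
                else:
                    gwnsp += w[s]
        out[code, 0] = edges
        out[code, 1] = gwesp
        out[code, 2] = gwnsp
    return out


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------


def _initial_graph(cfg: SimulatorConfig) -> Graph:
    if cfg.init_mode == "empty":
        return Graph.empty(cfg.n_vertices)
    if cfg.init_mode == "full":
        return Graph.complete(cfg.n_vertices)
    g = cfg.init_graph
    if g is None:
        raise SimulatorError("init_mode='observed' needs an observed graph attached")
    if g.n_vertices != cfg.n_vertices:
        raise SimulatorError(
            f"init_graph has {g.n_vertices} vertices, config says {cfg.n_vertices}"
        )
    return g.copy()


def simulate_network(
    theta: np.ndarray,
    cfg: SimulatorConfig,
    stat_cfg: StatisticConfig | None = None,
) -> tuple[Graph, np.ndarray]:
    """Draw one network from ERGM(theta) by an auxiliary Metropolis chain."""
    theta = np.asarray(theta, dtype=float).reshape(-1)
    if theta.size != 3 or not np.all(np.isfinite(theta)):
        raise SimulatorError(f"theta must be a finite 3-vector, got {theta!r}")
    stat_cfg = stat_cfg or StatisticConfig()
    g = _initial_graph(cfg)
    w = gw_weights(stat_cfg.decay, cfg.n_vertices)
    if cfg.n_vertices >= 2 and cfg.aux_iterations > 0:
        runner = _run_chain_tnt if cfg.kernel == "tnt" else _run_chain_plain
        runner(g.adj, theta, w, int(cfg.aux_iterations), int(cfg.seed) & 0x7FFFFFFF)
    return g, compute_stats(g, stat_cfg)


def simulate_training_pairs(
    proposal,
    B: int,
    cfg: SimulatorConfig,
    stat_cfg: StatisticConfig | None = None,
    round_index: int = 1,
) -> TrainingPairs:
    """Simulate B pairs ``theta_b ~ proposal, x_b ~ p(x | theta_b)``.

    ``proposal`` must expose ``sample(n, rng) -> (n, 3)`` (a ``PriorSpec``
    or a conditioned flow posterior).  Each pair gets a fresh sub-seed
    derived from ``cfg.seed`` so runs are reproducible bit-for-bit.
    """
    B = int(B)
    if B < 0:
        raise SimulatorError("B must be >= 0")
    stat_cfg = stat_cfg or StatisticConfig()
    if B == 0:
        z = np.zeros((0, 3))
        return TrainingPairs(z, z.copy(), np.zeros(0, dtype=int), np.zeros(0, dtype=int))
    rng = np.random.default_rng(int(cfg.seed))
    try:
        thetas = np.asarray(proposal.sample(B, rng), dtype=float)
    except AttributeError as exc:
        raise SimulatorError("proposal must expose sample(n, rng)") from exc
    if thetas.shape != (B, 3) or not np.all(np.isfinite(thetas)):
        raise SimulatorError(f"proposal returned invalid samples of shape {thetas.shape}")
    sub_seeds = rng.integers(0, 2**31 - 1, size=B)
    stats_out = np.empty((B, 3))
    for b in range(B):
        sub = replace(cfg, seed=int(sub_seeds[b]))
        _, stats_out[b] = simulate_network(thetas[b], sub, stat_cfg)
    return TrainingPairs(
        thetas, stats_out, np.full(B, int(round_index)), sub_seeds.astype(np.int64)
    )


@dataclass
class ExactModel:
    """Exact ERGM outcome distribution on all graphs with n <= 7 vertices.

    The graph space is aggregated by statistic value: ``stats_table`` holds
    the distinct statistic vectors, ``counts`` their multiplicities, and
    ``probabilities`` the ERGM(theta) mass of each row.
    """

    n_vertices: int
    theta: np.ndarray
    stats_table: np.ndarray  # (U, 3)
    counts: np.ndarray  # (U,)
    log_normaliser: float
    probabilities: np.ndarray  # (U,)

    def log_normaliser_at(self, theta: np.ndarray) -> float:
        theta = np.asarray(theta, dtype=float)
        a = self.stats_table @ theta + np.log(self.counts)
        amax = a.max()
        return float(amax + np.log(np.exp(a - amax).sum()))

    def probabilities_at(self, theta: np.ndarray) -> np.ndarray:
        theta = np.asarray(theta, dtype=float)
        a = self.stats_table @ theta + np.log(self.counts)
        a -= a.max()
        p = np.exp(a)
        return p / p.sum()

    def expected_stats(self, theta: np.ndarray | None = None) -> np.ndarray:
        p = self.probabilities if theta is None else self.probabilities_at(theta)
        return p @ self.stats_table

    def stats_cov(self, theta: np.ndarray | None = None) -> np.ndarray:
        p = self.probabilities if theta is None else self.probabilities_at(theta)
        mu = p @ self.stats_table
        d = self.stats_table - mu
        return (d * p[:, None]).T @ d


def enumerate_exact(
    n: int,
    theta: np.ndarray,
    stat_cfg: StatisticConfig | None = None,
) -> ExactModel:
    """Brute-force ERGM oracle: exact distribution over all graphs, n <= 7."""
    n = int(n)
    if n < 1 or n > ENUM_MAX_VERTICES:
        raise SimulatorError(f"exact enumeration capped at n <= {ENUM_MAX_VERTICES}, got {n}")
    theta = np.asarray(theta, dtype=float).reshape(-1)
    if theta.size != 3 or not np.all(np.isfinite(theta)):
        raise SimulatorError("theta must be a finite 3-vector")
    stat_cfg = stat_cfg or StatisticConfig()
    w = gw_weights(stat_cfg.decay, n)
    if n == 1:
        all_stats = np.zeros((1, 3))
    else:
        all_stats = _enumerate_stats(n, w)
    table, counts = np.unique(np.round(all_stats, 9), axis=0, return_counts=True)
    a = table @ theta + np.log(counts)
    amax = a.max()
    log_c = float(amax + np.log(np.exp(a - amax).sum()))
    probs = np.exp(a - log_c)
    return ExactModel(n, theta, table, counts.astype(float), log_c, probs)
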