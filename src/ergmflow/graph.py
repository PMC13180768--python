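"""Undirected simple graphs and their ERGM summary statistics.

The model works with three summary statistics of an undirected simple graph
``y`` on ``n`` vertices, always in the fixed order

    (edges, GWESP, GWNSP)

where GWESP / GWNSP are the geometrically weighted counts of connected /
non-connected vertex pairs by their number of shared partners::

    GWESP(y) = exp(tau) * sum_{i=1}^{n-2} (1 - (1 - exp(-tau))**i) * p_i
    GWNSP(y) = exp(tau) * sum_{i=1}^{n-2} (1 - (1 - exp(-tau))**i) * np_i

``p_i`` (resp. ``np_i``) is the number of connected (non-connected) vertex
pairs sharing exactly ``i`` neighbours, and ``tau > 0`` is the decay
parameter down-weighting high shared-partner counts (default 0.75).

Adjacency is stored as a dense symmetric uint8 matrix: the networks of
interest have n around 90 (at most a few thousand dyads), where dense
storage makes single-dyad change statistics an O(n) common-neighbour scan.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Fixed cross-module ordering of the summary-statistic vector.
STAT_ORDER: tuple[str, str, str] = ("edges", "gwesp", "gwnsp")

STAT_DIM = 3


class GraphError(ValueError):
    """Invalid graph construction or dyad operation."""


@dataclass(frozen=True)
class StatisticConfig:
    """Decay parameter and statistic ordering for (edges, GWESP, GWNSP).

    Parameters
    ----------
    decay
        Geometric decay ``tau``; must be finite and > 0 for the canonical
        model (``tau = 0`` is accepted as the unweighted limit used in
        property checks).
    """

    decay: float = 0.75
    statistic_order: tuple[str, str, str] = field(default=STAT_ORDER)

    def __post_init__(self) -> None:
        if not np.isfinite(self.decay):
            raise GraphError(f"decay must be finite, got {self.decay!r}")
        if self.decay < 0:
            raise GraphError(f"decay must be >= 0, got {self.decay!r}")
        if tuple(self.statistic_order) != STAT_ORDER:
            raise GraphError(
                f"statistic order is a fixed contract {STAT_ORDER}, "
                f"got {self.statistic_order!r}"
            )


class Graph:
    """Undirected simple labelled graph on vertices ``0..n-1``.

    No self-loops, no parallel edges. Construct via :meth:`from_edges` or
    :meth:`from_adjacency`; the adjacency matrix is the authoritative state.
    """

    __slots__ = ("n_vertices", "adj")

    def __init__(self, n_vertices: int, adj: np.ndarray):
        self.n_vertices = int(n_vertices)
        self.adj = adj

    @classmethod
    def empty(cls, n_vertices: int) -> "Graph":
        n = int(n_vertices)
        if n < 1:
            raise GraphError(f"need at least one vertex, got {n}")
        return cls(n, np.zeros((n, n), dtype=np.uint8))

    @classmethod
    def complete(cls, n_vertices: int) -> "Graph":
        g = cls.empty(n_vertices)
        g.adj[:] = 1
        np.fill_diagonal(g.adj, 0)
        return g

    @classmethod
    def from_edges(cls, n_vertices: int, edges) -> "Graph":
        g = cls.empty(n_vertices)
        n = g.n_vertices
        for i, j in edges:
            i, j = int(i), int(j)
            if i == j:
                raise GraphError(f"self-loop at vertex {i}")
            if not (0 <= i < n and 0 <= j < n):
                raise GraphError(f"vertex pair ({i}, {j}) out of range 0..{n - 1}")
            g.adj[i, j] = 1
            g.adj[j, i] = 1
        return g

    @classmethod
    def from_adjacency(cls, adj: np.ndarray) -> "Graph":
        a = np.asarray(adj)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise GraphError(f"adjacency must be square, got shape {a.shape}")
        if not np.array_equal(a, a.T):
            bad = np.argwhere(a != a.T)[0]
            raise GraphError(f"adjacency not symmetric at cell ({bad[0]}, {bad[1]})")
        if np.any(np.diag(a) != 0):
            k = int(np.flatnonzero(np.diag(a))[0])
            raise GraphError(f"self-loop on diagonal at vertex {k}")
        if not np.isin(a, (0, 1)).all():
            raise GraphError("adjacency entries must be 0/1")
        return cls(a.shape[0], a.astype(np.uint8))

    # -- basic queries ----------------------------------------------------

    @property
    def n_edges(self) -> int:
        return int(self.adj.sum()) // 2

    @property
    def n_dyads(self) -> int:
        n = self.n_vertices
        return n * (n - 1) // 2

    def edge_set(self) -> set[tuple[int, int]]:
        iu, ju = np.nonzero(np.triu(self.adj, k=1))
        return {(int(i), int(j)) for i, j in zip(iu, ju)}

    def has_edge(self, i: int, j: int) -> bool:
        return bool(self.adj[i, j])

    def copy(self) -> "Graph":
        return Graph(self.n_vertices, self.adj.copy())

    def relabel(self, perm) -> "Graph":
        """Graph with vertex ``k`` renamed to ``perm[k]``."""
        p = np.asarray(perm, dtype=np.intp)
        inv = np.empty_like(p)
        inv[p] = np.arange(self.n_vertices)
        return Graph(self.n_vertices, self.adj[np.ix_(inv, inv)].copy())

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Graph)
            and self.n_vertices == other.n_vertices
            and np.array_equal(self.adj, other.adj)
        )

    def __repr__(self) -> str:
        return f"Graph(n_vertices={self.n_vertices}, n_edges={self.n_edges})"


@dataclass(frozen=True)
class SharedPartnerCounts:
    """Histograms p_i (connected) and np_i (non-connected pairs), i = 0..n-2."""

    esp: np.ndarray
    nsp: np.ndarray


def gw_weights(decay: float, n_vertices: int) -> np.ndarray:
    """Geometric weights ``w_i = exp(tau) * (1 - (1 - exp(-tau))**i)``.

    Returns an array indexed ``i = 0..n-2`` with ``w_0 = 0``: a pair with no
    shared partner contributes nothing.  Closed forms used in the tests:
    ``w_1 = 1`` for every ``tau`` and ``w_i -> 1`` for all i at ``tau = 0``.
    """
    m = max(n_vertices - 1, 0)
    i = np.arange(m, dtype=float)
    w = np.exp(decay) * (1.0 - (1.0 - np.exp(-decay)) ** i)
    if m:
        w[0] = 0.0
    return w


def shared_partner_counts(g: Graph) -> SharedPartnerCounts:
    """Shared-partner histograms over connected and non-connected pairs.

    Satisfies ``sum(esp) = |E|`` and ``sum(nsp) = n(n-1)/2 - |E|``.
    """
    n = g.n_vertices
    m = max(n - 1, 0)
    esp = np.zeros(m, dtype=np.int64)
    nsp = np.zeros(m, dtype=np.int64)
    if n < 2:
        return SharedPartnerCounts(esp, nsp)
    a = g.adj.astype(np.int64)
    common = a @ a  # common[i, j] = #shared partners of i and j
    iu, ju = np.triu_indices(n, k=1)
    cn = common[iu, ju]
    is_edge = g.adj[iu, ju].astype(bool)
    np.add.at(esp, cn[is_edge], 1)
    np.add.at(nsp, cn[~is_edge], 1)
    return SharedPartnerCounts(esp, nsp)


def compute_stats(g: Graph, cfg: StatisticConfig | None = None) -> np.ndarray:
    """Summary-statistic vector ``h(y) = (edges, GWESP, GWNSP)``."""
    cfg = cfg or StatisticConfig()
    sp = shared_partner_counts(g)
    w = gw_weights(cfg.decay, g.n_vertices)
    return np.array([float(g.n_edges), float(w @ sp.esp), float(w @ sp.nsp)])


def toggle_delta(g: Graph, i: int, j: int, cfg: StatisticConfig | None = None) -> np.ndarray:
    """Change statistic for toggling dyad ``(i, j)`` on ``g`` (g unchanged).

    Toggling an edge (i, j) moves the pair itself between the esp/nsp
    histograms at its current shared-partner count, and shifts by one the
    shared-partner count of every pair (i, k) with k ~ j and (j, k) with
    k ~ i — an O(n) update via common-neighbour scans.
    """
    cfg = cfg or StatisticConfig()
    n = g.n_vertices
    i, j = int(i), int(j)
    if i == j:
        raise GraphError(f"self-loop dyad ({i}, {j})")
    if not (0 <= i < n and 0 <= j < n):
        raise GraphError(f"dyad ({i}, {j}) out of range 0..{n - 1}")
    removing = bool(g.adj[i, j])
    a = g.adj
    if removing:
        # delta(remove) = -delta(add computed on the graph without the edge)
        a = a.copy()
        a[i, j] = 0
        a[j, i] = 0
    w = gw_weights(cfg.decay, n)
    ai = a[i].astype(bool)
    aj = a[j].astype(bool)
    cn_ij = int(np.count_nonzero(ai & aj))
    d_gwesp = w[cn_ij]
    d_gwnsp = -w[cn_ij]
    # pairs (i, k) for k ~ j gain shared partner j; pairs (j, k) for k ~ i gain i
    for u, v, av in ((i, j, aj), (j, i, ai)):
        ks = np.flatnonzero(av)
        ks = ks[(ks != u) & (ks != v)]
        if ks.size == 0:
            continue
        sp = (a[ks].astype(bool) & a[u].astype(bool)).sum(axis=1)
        dws = w[sp + 1] - w[sp]
        edge_uk = a[u, ks].astype(bool)
        d_gwesp += dws[edge_uk].sum()
        d_gwnsp += dws[~edge_uk].sum()
    delta = np.array([1.0, d_gwesp, d_gwnsp])
    return -delta if removing else delta


def apply_toggle_with_delta(
    g: Graph, dyad: tuple[int, int], cfg: StatisticConfig | None = None
) -> tuple[Graph, np.ndarray]:
    """Toggle one dyad, returning the new graph and the statistic change."""
    i, j = dyad
    delta = toggle_delta(g, i, j, cfg)
    g2 = g.copy()
    val = 1 - g2.adj[i, j]
    g2.adj[i, j] = val
    g2.adj[j, i] = val
    return g2, delta
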