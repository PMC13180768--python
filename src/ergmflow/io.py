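"""Network readers/writers, symmetrisation, fixtures, configs and seeding.

Formats are deliberately minimal and diffable:

* edge list — two whitespace-separated integer columns, ``#`` comments,
  0-based vertex ids by default (``one_based=True`` shifts on read);
* adjacency — square CSV of 0/1 entries, validated symmetric;
* posterior CSV — one column per parameter in the fixed statistic order,
  with a ``#`` metadata comment block (method, x_obs, seed).

``symmetrise_directed`` turns a directed nomination list into an
undirected graph: rule "either" places an edge when at least one direction
is reported (the construction used for friendship-nomination networks),
rule "mutual" requires both.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml

from .graph import Graph, GraphError, StatisticConfig
from .priors import PriorSpec

STAT_NAMES = ("edges", "gwesp", "gwnsp")


class IOError_(ValueError):
    pass


# ---------------------------------------------------------------------------
# networks
# ---------------------------------------------------------------------------


def _parse_edge_lines(path: Path):
    for ln, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 2:
            raise IOError_(f"{path}:{ln}: expected two integer columns, got {raw!r}")
        try:
            yield ln, int(parts[0]), int(parts[1])
        except ValueError as exc:
            raise IOError_(f"{path}:{ln}: non-integer vertex id in {raw!r}") from exc


def read_network(
    path,
    format: str = "edgelist",
    n_vertices: int | None = None,
    one_based: bool = False,
) -> Graph:
    """Read an undirected simple graph from an edge list or adjacency CSV."""
    path = Path(path)
    if format == "adjacency":
        rows = [r for r in path.read_text().splitlines() if r.strip()]
        cells = [r.split(",") for r in rows]
        widths = {len(c) for c in cells}
        if len(widths) != 1:
            raise IOError_(f"{path}: ragged adjacency rows (widths {sorted(widths)})")
        try:
            a = np.array([[int(v) for v in row] for row in cells])
        except ValueError as exc:
            raise IOError_(f"{path}: non-integer adjacency cell") from exc
        try:
            return Graph.from_adjacency(a)
        except GraphError as exc:
            raise IOError_(f"{path}: {exc}") from exc
    if format != "edgelist":
        raise IOError_(f"unknown network format {format!r}")
    shift = 1 if one_based else 0
    edges = []
    seen = set()
    max_id = -1
    for ln, i, j in _parse_edge_lines(path):
        i, j = i - shift, j - shift
        if i == j:
            raise IOError_(f"{path}:{ln}: self-loop row ({i}, {j})")
        if i < 0 or j < 0:
            raise IOError_(f"{path}:{ln}: negative vertex id after indexing shift")
        key = (min(i, j), max(i, j))
        if key in seen:
            raise IOError_(f"{path}:{ln}: duplicate edge {key}")
        seen.add(key)
        edges.append(key)
        max_id = max(max_id, i, j)
    n = n_vertices if n_vertices is not None else max_id + 1
    if n < 1:
        raise IOError_(f"{path}: empty edge list and no n_vertices given")
    try:
        return Graph.from_edges(n, edges)
    except GraphError as exc:
        raise IOError_(f"{path}: {exc}") from exc


def write_network(g: Graph, path, format: str = "edgelist") -> None:
    path = Path(path)
    if format == "edgelist":
        lines = [f"# n_vertices={g.n_vertices}"]
        lines += [f"{i}\t{j}" for i, j in sorted(g.edge_set())]
        path.write_text("\n".join(lines) + "\n")
    elif format == "adjacency":
        path.write_text(
            "\n".join(",".join(str(int(v)) for v in row) for row in g.adj) + "\n"
        )
    else:
        raise IOError_(f"unknown network format {format!r}")


def symmetrise_directed(
    directed_edges,
    n_vertices: int,
    rule: str = "either",
) -> Graph:
    """Undirected graph from directed nominations.

    rule "either": edge iff at least one direction is present;
    rule "mutual": edge iff both directions are present.
    """
    if rule not in ("either", "mutual"):
        raise IOError_(f"unknown symmetrisation rule {rule!r}")
    n = int(n_vertices)
    fwd = set()
    for i, j in directed_edges:
        i, j = int(i), int(j)
        if i == j:
            continue
        if not (0 <= i < n and 0 <= j < n):
            raise IOError_(f"directed pair ({i}, {j}) out of range 0..{n - 1}")
        fwd.add((i, j))
    edges = set()
    for i, j in fwd:
        key = (min(i, j), max(i, j))
        if rule == "either" or (j, i) in fwd:
            edges.add(key)
    return Graph.from_edges(n, edges)


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------


def fixture_graph(name: str, seed: int = 0, **kwargs) -> Graph:
    """Deterministic toy graphs and seeded random graphs for the test suite.

    Names: ``K3`` (triangle), ``P3`` (path on 3), ``C4`` (4-cycle),
    ``ER`` (Erdos-Renyi; needs n, p), ``lazega_like`` (seeded random graph
    at a nomination-network-like size/density; synthetic stand-in, not the
    real data; needs n, density).
    """
    if name == "K3":
        return Graph.from_edges(3, [(0, 1), (1, 2), (0, 2)])
    if name == "P3":
        return Graph.from_edges(3, [(0, 1), (1, 2)])
    if name == "C4":
        return Graph.from_edges(4, [(0, 1), (1, 2), (2, 3), (3, 0)])
    if name == "ER":
        n = int(kwargs["n"])
        p = float(kwargs["p"])
        rng = np.random.default_rng(seed)
        iu, ju = np.triu_indices(n, k=1)
        mask = rng.random(len(iu)) < p
        return Graph.from_edges(n, list(zip(iu[mask], ju[mask])))
    if name == "lazega_like":
        n = int(kwargs.get("n", 71))
        density = float(kwargs.get("density", 0.16))
        return fixture_graph("ER", seed=seed, n=n, p=density)
    raise IOError_(f"unknown fixture name {name!r}")


# ---------------------------------------------------------------------------
# posterior / statistics tables
# ---------------------------------------------------------------------------


def write_posterior_csv(samples, path) -> None:
    """Posterior draws with a metadata comment block and fixed header."""
    path = Path(path)
    x = "" if samples.x_obs is None else ",".join(f"{v:.6f}" for v in samples.x_obs)
    header = (
        f"# method={samples.method}\n"
        f"# x_obs={x}\n"
        f"# seed={samples.seed}\n"
        f"# acceptance_rate={samples.acceptance_rate:.6f}\n"
        + ",".join(f"theta_{n}" for n in STAT_NAMES)
    )
    np.savetxt(path, samples.draws, delimiter=",", header=header, comments="")


def read_stats_csv(path) -> np.ndarray:
    """Statistic vectors, one row per network, columns in the fixed order.

    Skips ``#`` comments and a single textual header line if present.
    """
    rows = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split(",")
        try:
            rows.append([float(v) for v in parts])
        except ValueError:
            if rows:
                raise IOError_(f"{path}: non-numeric row {line!r}")
            continue  # header line
    if not rows:
        raise IOError_(f"{path}: no data rows")
    arr = np.asarray(rows)
    if arr.shape[1] != 3:
        raise IOError_(f"{path}: expected 3 statistic columns, got {arr.shape[1]}")
    return arr


def write_stats_csv(stats: np.ndarray, path) -> None:
    np.savetxt(
        Path(path),
        np.atleast_2d(stats),
        delimiter=",",
        header=",".join(STAT_NAMES),
        comments="",
    )


# ---------------------------------------------------------------------------
# run configuration and seeding
# ---------------------------------------------------------------------------


def derive_seeds(master_seed: int, names: list[str]) -> dict[str, int]:
    """Deterministic per-component seeds from one master seed (all < 2^31)."""
    ss = np.random.SeedSequence(int(master_seed))
    children = ss.spawn(len(names))
    return {
        name: int(child.generate_state(1)[0] % (2**31 - 1))
        for name, child in zip(names, children)
    }


def load_prior_yaml(path) -> PriorSpec:
    """Prior from a YAML mapping with ``mean`` and ``covariance`` keys.

    ``covariance`` may be a full matrix, a diagonal vector, or a scalar
    multiple of the identity.
    """
    spec = yaml.safe_load(Path(path).read_text())
    if not isinstance(spec, dict) or "mean" not in spec:
        raise IOError_(f"{path}: prior YAML must contain 'mean'")
    mean = np.asarray(spec["mean"], dtype=float)
    cov = spec.get("covariance", 10.0)
    cov = np.asarray(cov, dtype=float)
    if cov.ndim == 0:
        cov = float(cov) * np.eye(mean.size)
    elif cov.ndim == 1:
        cov = np.diag(cov)
    return PriorSpec(mean=mean, covariance=cov)


def default_stat_config(decay: float = 0.75) -> StatisticConfig:
    return StatisticConfig(decay=decay)
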