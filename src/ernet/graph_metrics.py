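"""Binary undirected graph metrics and small-world indices.

Conventions for disconnected graphs follow the standard ones in the
brain-connectivity literature: the characteristic path length L averages
shortest paths over *reachable* unordered pairs only, and global efficiency
E_glob averages inverse shortest paths over *all* unordered pairs with
unreachable pairs contributing 0 (so E_glob is the Latora-Marchiori "average
inverse shortest path length"; the alternative reading "inverse of the
average shortest path length", which coincides on graphs where all pairs are
reachable at distance ~L, is available as ``definition="inverse-mean"`` for
sensitivity checks).

Small-world-ness is assessed against degree-preserving random null graphs
obtained by double-edge-swap (Maslov-Sneppen) rewiring:
gamma = C_net / C_ran, lambda = L_net / L_ran, sigma = gamma / lambda, with
sigma > 1 read as small-world topology.  The indices are only computed when
the mean degree k exceeds log(n) (natural log by default), the usual
estimability criterion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path as _csgraph_shortest_path

from .connectivity import BinaryGraph
from .errors import DegenerateInputError, UndefinedIndexError, UndefinedMetricError


@dataclass(frozen=True)
class GraphMetrics:
    """Summary metrics of one binary graph."""

    n: int
    k_mean: float
    C: float
    L: float | None
    E_glob: float
    density_pct: float


@dataclass(frozen=True)
class SmallWorldIndices:
    gamma: float | None
    lambda_: float | None
    sigma: float | None
    n_random: int
    estimable: bool


def shortest_path_lengths(g: BinaryGraph) -> np.ndarray:
    """All-pairs hop counts (float matrix; unreachable pairs are np.inf)."""
    a = csr_matrix(g.adjacency)
    d = _csgraph_shortest_path(a, method="D", unweighted=True, directed=False)
    return d


def mean_degree(g: BinaryGraph) -> float:
    """2E / N."""
    return 2.0 * g.n_edges / g.n_nodes


def is_estimable(g: BinaryGraph, log_base: float = math.e) -> bool:
    """Estimability gate for small-world indices: k_mean > log(n).

    The log base defaults to the natural log, the convention of the
    small-world literature the criterion comes from.
    """
    if g.n_nodes < 2:
        raise DegenerateInputError("estimability needs at least 2 nodes")
    return mean_degree(g) > math.log(g.n_nodes, log_base)


def characteristic_path_length(g: BinaryGraph, distances: np.ndarray | None = None) -> float:
    """Mean shortest path over reachable unordered pairs; error if edgeless."""
    if g.n_edges == 0:
        raise UndefinedMetricError("characteristic path length undefined on an edgeless graph")
    d = shortest_path_lengths(g) if distances is None else distances
    iu = np.triu_indices(g.n_nodes, k=1)
    vals = d[iu]
    finite = vals[np.isfinite(vals)]
    return float(finite.mean())


def clustering_coefficient(g: BinaryGraph) -> float:
    """Unweighted mean over all nodes of 2*t_i / (k_i (k_i - 1)); 0 if k_i < 2."""
    a = g.adjacency.astype(np.float64)
    k = a.sum(axis=1)
    triangles = ((a @ a) * a).sum(axis=1) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(k >= 2, 2.0 * triangles / (k * (k - 1)), 0.0)
    return float(c.mean())


def global_efficiency(
    g: BinaryGraph,
    distances: np.ndarray | None = None,
    definition: str = "mean-inverse",
) -> float:
    """Global efficiency of a binary graph.

    ``definition="mean-inverse"`` (default): mean over unordered pairs of
    1/d(i, j), unreachable pairs contributing 0.  ``"inverse-mean"``: 1/L
    with L over reachable pairs (0 for edgeless graphs).
    """
    if g.n_nodes < 2:
        raise DegenerateInputError("global efficiency needs at least 2 nodes")
    if definition not in ("mean-inverse", "inverse-mean"):
        raise ValueError(f"unknown efficiency definition {definition!r}")
    if g.n_edges == 0:
        return 0.0
    d = shortest_path_lengths(g) if distances is None else distances
    iu = np.triu_indices(g.n_nodes, k=1)
    vals = d[iu]
    if definition == "inverse-mean":
        finite = vals[np.isfinite(vals)]
        return float(1.0 / finite.mean())
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(vals), 1.0 / vals, 0.0)
    return float(inv.mean())


def graph_metrics(g: BinaryGraph, efficiency_definition: str = "mean-inverse") -> GraphMetrics:
    """All summary metrics at once (single distance computation)."""
    d = shortest_path_lengths(g)
    L = characteristic_path_length(g, d) if g.n_edges else None
    return GraphMetrics(
        n=g.n_nodes,
        k_mean=mean_degree(g),
        C=clustering_coefficient(g),
        L=L,
        E_glob=global_efficiency(g, d, efficiency_definition),
        density_pct=100.0 * g.n_edges / (g.n_nodes * (g.n_nodes - 1) / 2) if g.n_nodes > 1 else 0.0,
    )


@njit(cache=True)
def _swap_loop(a, edges, pick_i, pick_j, orient):  # pragma: no cover - jitted
    for t in range(pick_i.shape[0]):
        i = pick_i[t]
        j = pick_j[t]
        if i == j:
            continue
        u, v = edges[i, 0], edges[i, 1]
        x, y = edges[j, 0], edges[j, 1]
        if orient[t]:
            x, y = y, x
        # proposed new edges: (u, y) and (x, v)
        if u == y or x == v:
            continue
        if a[u, y] or a[x, v]:
            continue
        a[u, v] = a[v, u] = 0
        a[x, y] = a[y, x] = 0
        a[u, y] = a[y, u] = 1
        a[x, v] = a[v, x] = 1
        edges[i, 0], edges[i, 1] = u, y
        edges[j, 0], edges[j, 1] = x, v


def rewire_preserving_degree(
    g: BinaryGraph, swaps_per_edge: int = 10, seed: int = 0
) -> BinaryGraph:
    """Degree-preserving randomization by double-edge swaps.

    Performs ``swaps_per_edge * E`` swap *attempts*; an attempt picks two
    distinct edges (a, b), (c, d), orients one at random, and replaces them by
    (a, d), (c, b) unless that would create a self-loop or duplicate edge.
    The degree sequence is conserved exactly.  Graphs with fewer than 2 edges
    are returned as copies.  Deterministic for a given seed.
    """
    e = g.n_edges
    if e < 2:
        return BinaryGraph(g.adjacency.copy(), g.node_ids, g.threshold)
    rng = np.random.default_rng(seed)
    a = g.adjacency.copy()
    edges = np.ascontiguousarray(np.array(np.triu(a, k=1).nonzero()).T)  # E x 2
    n_attempts = int(swaps_per_edge) * e
    pick = rng.integers(0, e, size=(n_attempts, 2))
    orient = rng.integers(0, 2, size=n_attempts)
    _swap_loop(a, edges, pick[:, 0], pick[:, 1], orient)
    return BinaryGraph(a, g.node_ids, g.threshold)


def small_world_indices(
    g: BinaryGraph,
    n_random: int = 100,
    swaps_per_edge: int = 10,
    seed: int = 0,
    log_base: float = math.e,
) -> SmallWorldIndices:
    """gamma, lambda and sigma against an ensemble of rewired null graphs.

    Returns ``estimable=False`` with undefined indices when k_mean <= log(n).
    Null-graph seeds are derived deterministically as ``seed + index``.
    Raises :class:`UndefinedIndexError` if the null ensemble has zero mean
    clustering or no finite path (sigma would be undefined).
    """
    if not is_estimable(g, log_base=log_base):
        return SmallWorldIndices(None, None, None, n_random, estimable=False)
    d = shortest_path_lengths(g)
    c_net = clustering_coefficient(g)
    l_net = characteristic_path_length(g, d)
    c_ran = np.empty(n_random)
    l_ran = np.empty(n_random)
    for i in range(n_random):
        null = rewire_preserving_degree(g, swaps_per_edge=swaps_per_edge, seed=seed + i)
        dn = shortest_path_lengths(null)
        c_ran[i] = clustering_coefficient(null)
        finite = dn[np.triu_indices(null.n_nodes, k=1)]
        finite = finite[np.isfinite(finite)]
        if finite.size == 0:
            raise UndefinedIndexError(
                f"null graph {i} has no finite path (n={g.n_nodes}, E={g.n_edges})"
            )
        l_ran[i] = finite.mean()
    c_ran_mean = float(c_ran.mean())
    l_ran_mean = float(l_ran.mean())
    if c_ran_mean <= 0 or l_ran_mean <= 0:
        raise UndefinedIndexError(
            f"null ensemble degenerate: C_ran={c_ran_mean:.4g}, L_ran={l_ran_mean:.4g} "
            f"(n={g.n_nodes}, E={g.n_edges})"
        )
    gamma = c_net / c_ran_mean
    lambda_ = l_net / l_ran_mean
    return SmallWorldIndices(
        gamma=gamma, lambda_=lambda_, sigma=gamma / lambda_,
        n_random=n_random, estimable=True,
    )
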