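"""Graph metrics against independent oracles (brute force and networkx)."""

import itertools
import math

import networkx as nx
import numpy as np
import pytest

from ernet.connectivity import BinaryGraph
from ernet.errors import UndefinedMetricError
from ernet.graph_metrics import (
    characteristic_path_length,
    clustering_coefficient,
    global_efficiency,
    graph_metrics,
    is_estimable,
    mean_degree,
    rewire_preserving_degree,
    shortest_path_lengths,
    small_world_indices,
)


def graph_from_edges(n, edges):
    a = np.zeros((n, n), dtype=np.int8)
    for i, j in edges:
        a[i, j] = a[j, i] = 1
    return BinaryGraph(a, tuple(range(n)))


def random_graph(n, p, seed):
    rng = np.random.default_rng(seed)
    a = (rng.random((n, n)) < p).astype(np.int8)
    a = np.triu(a, 1)
    return BinaryGraph(a + a.T, tuple(range(n)))


# --- independent oracles ---------------------------------------------------

def floyd_warshall(adj):
    """All-pairs relaxation, independent of the BFS route."""
    n = adj.shape[0]
    d = np.where(adj > 0, 1.0, np.inf)
    np.fill_diagonal(d, 0.0)
    for k in range(n):
        d = np.minimum(d, d[:, k, None] + d[None, k, :])
    return d


def brute_clustering(adj):
    n = adj.shape[0]
    cs = []
    for i in range(n):
        nbrs = [j for j in range(n) if adj[i, j]]
        k = len(nbrs)
        if k < 2:
            cs.append(0.0)
            continue
        links = sum(adj[a, b] for a, b in itertools.combinations(nbrs, 2))
        cs.append(2.0 * links / (k * (k - 1)))
    return float(np.mean(cs))


# --- analytic examples -----------------------------------------------------

PATH3 = graph_from_edges(3, [(0, 1), (1, 2)])
CYCLE4 = graph_from_edges(4, [(0, 1), (1, 2), (2, 3), (3, 0)])
K5 = graph_from_edges(5, list(itertools.combinations(range(5), 2)))
K3 = graph_from_edges(3, [(0, 1), (1, 2), (0, 2)])
STAR5 = graph_from_edges(5, [(0, i) for i in range(1, 5)])
EMPTY5 = graph_from_edges(5, [])
TWO_DYADS = graph_from_edges(4, [(0, 1), (2, 3)])


class TestShortestPaths:
    def test_path_graph_distances(self):
        d = shortest_path_lengths(PATH3)
        assert d[0, 2] == 2 and d[0, 1] == 1 and d[1, 2] == 1

    def test_disconnected_dyads_infinite(self):
        d = shortest_path_lengths(TWO_DYADS)
        assert np.isinf(d[0, 2]) and np.isinf(d[1, 3])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_floyd_warshall(self, seed):
        g = random_graph(20, 0.15, seed)
        np.testing.assert_array_equal(shortest_path_lengths(g), floyd_warshall(g.adjacency))


class TestCharacteristicPathLength:
    @pytest.mark.parametrize("g,expected", [
        (K5, 1.0),
        (CYCLE4, 8 / 6),   # four pairs at distance 1, two at distance 2
        (PATH3, 4 / 3),    # (1 + 1 + 2) / 3
    ])
    def test_examples(self, g, expected):
        assert characteristic_path_length(g) == pytest.approx(expected)

    def test_edgeless_undefined(self):
        with pytest.raises(UndefinedMetricError):
            characteristic_path_length(EMPTY5)

    def test_disconnected_averages_reachable_pairs(self):
        assert characteristic_path_length(TWO_DYADS) == 1.0


class TestClustering:
    @pytest.mark.parametrize("g,expected", [(K3, 1.0), (STAR5, 0.0)])
    def test_examples(self, g, expected):
        assert clustering_coefficient(g) == expected

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force(self, seed):
        g = random_graph(20, 0.25, seed)
        assert clustering_coefficient(g) == pytest.approx(brute_clustering(g.adjacency))


class TestGlobalEfficiency:
    @pytest.mark.parametrize("g,expected", [
        (K5, 1.0), (EMPTY5, 0.0), (PATH3, (1 + 1 + 0.5) / 3),
    ])
    def test_examples(self, g, expected):
        assert global_efficiency(g) == pytest.approx(expected)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_networkx(self, seed):
        g = random_graph(18, 0.2, seed)
        assert global_efficiency(g) == pytest.approx(
            nx.global_efficiency(nx.from_numpy_array(g.adjacency)))

    def test_edge_addition_monotone(self):
        rng = np.random.default_rng(3)
        g = random_graph(15, 0.2, 11)
        base = global_efficiency(g)
        zeros = np.argwhere(np.triu(g.adjacency == 0, 1))
        i, j = zeros[rng.integers(len(zeros))]
        a = g.adjacency.copy()
        a[i, j] = a[j, i] = 1
        assert global_efficiency(BinaryGraph(a, g.node_ids)) >= base

    def test_inverse_mean_definition(self):
        # 1 / L over reachable pairs, the alternative reading
        assert global_efficiency(PATH3, definition="inverse-mean") == pytest.approx(3 / 4)


class TestDegreeAndEstimability:
    def test_mean_degree_examples(self):
        ring = graph_from_edges(6, [(i, (i + d) % 6) for i in range(6) for d in (1, 2)])
        assert mean_degree(ring) == 4.0
        assert mean_degree(EMPTY5) == 0.0
        assert mean_degree(graph_from_edges(5, [(0, 1), (1, 2), (2, 3), (3, 4)])) == 1.6

    def test_estimability_natural_log(self):
        # ln(264) ~ 5.576 separates k = 6 from k = 5
        a = np.zeros((264, 264), dtype=np.int8)
        g264 = BinaryGraph(a, tuple(range(264)))
        assert math.log(264) == pytest.approx(5.576, abs=1e-3)
        # construct via a ring with degree 6 vs a sparser one
        ring6 = graph_from_edges(264, [(i, (i + d) % 264) for i in range(264) for d in (1, 2, 3)])
        assert mean_degree(ring6) == 6.0 and is_estimable(ring6)
        ring5 = graph_from_edges(264, [(i, (i + d) % 264) for i in range(264) for d in (1, 2)])
        # add one extra neighbour to half the nodes: k = 5
        extra = [(i, (i + 4) % 264) for i in range(0, 264, 2)]
        g5 = graph_from_edges(264, [(i, (i + d) % 264) for i in range(264) for d in (1, 2)] + extra)
        assert mean_degree(g5) == 5.0 and not is_estimable(g5)

    def test_dyad_estimable(self):
        g = graph_from_edges(2, [(0, 1)])
        assert is_estimable(g)  # k = 1 > ln 2


class TestRewiring:
    def test_degree_sequence_conserved(self):
        g = random_graph(30, 0.2, 5)
        null = rewire_preserving_degree(g, swaps_per_edge=10, seed=9)
        np.testing.assert_array_equal(null.adjacency.sum(1), g.adjacency.sum(1))
        assert np.diag(null.adjacency).sum() == 0

    def test_triangle_has_no_alternative(self):
        null = rewire_preserving_degree(K3, swaps_per_edge=10, seed=0)
        np.testing.assert_array_equal(null.adjacency, K3.adjacency)

    def test_seed_determinism(self):
        g = random_graph(50, 0.1, 2)
        a = rewire_preserving_degree(g, 10, seed=7)
        b = rewire_preserving_degree(g, 10, seed=7)
        c = rewire_preserving_degree(g, 10, seed=8)
        np.testing.assert_array_equal(a.adjacency, b.adjacency)
        assert (a.adjacency != c.adjacency).any()


class TestSmallWorld:
    def test_self_null_sigma_is_one(self):
        g = random_graph(30, 0.2, 1)
        sw = small_world_indices(g, n_random=1, swaps_per_edge=0, seed=0)
        assert sw.sigma == pytest.approx(1.0)

    def test_estimability_gate(self):
        sparse = graph_from_edges(20, [(0, 1), (2, 3)])
        sw = small_world_indices(sparse, n_random=5, seed=0)
        assert not sw.estimable and sw.sigma is None

    def test_lattice_with_shortcuts_is_small_world(self):
        ws = nx.watts_strogatz_graph(60, 6, 0.05, seed=4)
        g = BinaryGraph(nx.to_numpy_array(ws), tuple(range(60)))
        sw = small_world_indices(g, n_random=20, seed=3)
        assert sw.estimable and sw.sigma > 1
        assert sw.sigma == pytest.approx(sw.gamma / sw.lambda_)

    def test_graph_metrics_bundle_consistent(self):
        g = random_graph(25, 0.2, 3)
        m = graph_metrics(g)
        assert m.E_glob == pytest.approx(global_efficiency(g))
        assert m.C == pytest.approx(clustering_coefficient(g))
        assert m.L == pytest.approx(characteristic_path_length(g))
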