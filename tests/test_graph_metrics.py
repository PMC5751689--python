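"""Nodal metric correctness against closed-form cases and brute-force oracles."""

import itertools

import networkx as nx
import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import nirsnet as nn
from conftest import random_adjacency


def adjacency_from_edges(n, edge_list):
    a = np.zeros((n, n), dtype=np.uint8)
    for i, j in edge_list:
        a[i, j] = a[j, i] = 1
    return nn.AdjacencyMatrix(edges=a, threshold=0.0)


# ---------------------------------------------------------------- oracles


def floyd_warshall_oracle(edges):
    """Brute-force all-pairs hop distances, independent of the BFS route."""
    n = edges.shape[0]
    d = np.where(edges > 0, 1.0, np.inf)
    np.fill_diagonal(d, 0.0)
    for k in range(n):
        for i in range(n):
            for j in range(n):
                d[i, j] = min(d[i, j], d[i, k] + d[k, j])
    return d


def clustering_oracle(edges):
    """Exhaustive triangle enumeration per node."""
    n = edges.shape[0]
    out = np.zeros(n)
    for i in range(n):
        nb = np.flatnonzero(edges[i])
        k = nb.size
        if k < 2:
            continue
        t = sum(edges[a, b] for a, b in itertools.combinations(nb, 2))
        out[i] = 2 * t / (k * (k - 1))
    return out


def global_efficiency_oracle(edges):
    n = edges.shape[0]
    d = floyd_warshall_oracle(edges)
    out = np.zeros(n)
    for i in range(n):
        out[i] = sum(1.0 / d[i, j] for j in range(n) if j != i and np.isfinite(d[i, j]))
        out[i] /= n - 1
    return out


def local_efficiency_oracle(edges):
    n = edges.shape[0]
    out = np.zeros(n)
    for i in range(n):
        nb = np.flatnonzero(edges[i])
        k = nb.size
        if k < 2:
            continue
        sub = edges[np.ix_(nb, nb)]
        d = floyd_warshall_oracle(sub)
        total = sum(
            1.0 / d[a, b]
            for a in range(k)
            for b in range(k)
            if a != b and np.isfinite(d[a, b])
        )
        out[i] = total / (k * (k - 1))
    return out


# ---------------------------------------------------------------- hand cases


class TestClosedFormCases:
    def test_complete_graph_all_metrics_maximal(self):
        adj = adjacency_from_edges(5, itertools.combinations(range(5), 2))
        ms = nn.metric_profile(adj)
        np.testing.assert_array_equal(ms.degree, 4)
        np.testing.assert_allclose(ms.clustering, 1.0)
        np.testing.assert_allclose(ms.local_efficiency, 1.0)
        np.testing.assert_allclose(ms.global_efficiency, 1.0)

    def test_complete_graph_52_degree(self, rng):
        adj = random_adjacency(52, 1.1, rng)  # p>1: complete
        assert np.all(nn.nodal_degree(adj) == 51)

    def test_star_graph(self):
        adj = adjacency_from_edges(5, [(0, i) for i in range(1, 5)])
        ms = nn.metric_profile(adj)
        assert ms.degree[0] == 4 and np.all(ms.degree[1:] == 1)
        np.testing.assert_array_equal(ms.clustering, 0.0)
        np.testing.assert_array_equal(ms.local_efficiency, 0.0)

    def test_path_graph_global_efficiency(self):
        """Path a-b-c: d(a,c)=2 so E_glob(a) = (1 + 1/2)/2 = 0.75; E_glob(b)=1."""
        adj = adjacency_from_edges(3, [(0, 1), (1, 2)])
        d = nn.shortest_paths(adj)
        assert d[0, 2] == 2
        eg = nn.nodal_global_efficiency(adj)
        np.testing.assert_allclose(eg, [0.75, 1.0, 0.75])

    def test_disconnected_pairs_infinite_distance_zero_efficiency(self):
        adj = adjacency_from_edges(4, [(0, 1), (2, 3)])
        d = nn.shortest_paths(adj)
        assert np.isinf(d[0, 2]) and np.isinf(d[1, 3])
        eg = nn.nodal_global_efficiency(adj)
        np.testing.assert_allclose(eg, [1 / 3] * 4)

    def test_isolated_node_zero_everywhere(self):
        adj = adjacency_from_edges(3, [(0, 1)])
        ms = nn.metric_profile(adj)
        assert ms.degree[2] == 0
        assert ms.global_efficiency[2] == 0.0
        assert ms.local_efficiency[2] == 0.0

    def test_triangle_with_pendant_clustering(self):
        """Triangle {a,b,c} plus pendant d-a: C_a=1/3, C_b=C_c=1, C_d=0."""
        adj = adjacency_from_edges(4, [(0, 1), (0, 2), (1, 2), (0, 3)])
        np.testing.assert_allclose(
            nn.clustering_coefficient(adj), [1 / 3, 1.0, 1.0, 0.0]
        )

    def test_chorded_square_local_efficiency(self):
        """4-cycle 0-1-2-3-0 with chord 0-2: node 0's neighbours {1,2,3}
        induce edges 1-2 and 2-3, so E_loc(0) = 2*(1+1+1/2)/6 = 5/6."""
        adj = adjacency_from_edges(4, [(0, 1), (1, 2), (2, 3), (3, 0), (0, 2)])
        assert nn.nodal_local_efficiency(adj)[0] == pytest.approx(5 / 6)

    def test_degree_of_thresholded_four_node_network(self, four_node_corr):
        adj = nn.binarize(four_node_corr, 0.7)  # edges (0,1),(0,2),(0,3)
        np.testing.assert_array_equal(nn.nodal_degree(adj), [3, 1, 1, 1])

    def test_empty_graph_profile_all_zero(self):
        adj = adjacency_from_edges(4, [])
        ms = nn.metric_profile(adj)
        for vec in (ms.degree, ms.clustering, ms.local_efficiency, ms.global_efficiency):
            np.testing.assert_array_equal(vec, 0)


# ---------------------------------------------------------------- oracle sweep


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(8))
    def test_all_metrics_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(8):
            n = int(rng.integers(2, 13))
            adj = random_adjacency(n, float(rng.uniform(0.1, 0.9)), rng)
            np.testing.assert_array_equal(
                nn.shortest_paths(adj), floyd_warshall_oracle(adj.edges)
            )
            np.testing.assert_allclose(
                nn.clustering_coefficient(adj), clustering_oracle(adj.edges), atol=1e-12
            )
            np.testing.assert_allclose(
                nn.nodal_global_efficiency(adj),
                global_efficiency_oracle(adj.edges),
                atol=1e-12,
            )
            np.testing.assert_allclose(
                nn.nodal_local_efficiency(adj),
                local_efficiency_oracle(adj.edges),
                atol=1e-12,
            )

    def test_against_networkx(self, rng):
        """Independent library cross-check on clustering and efficiencies."""
        for _ in range(10):
            n = int(rng.integers(3, 12))
            adj = random_adjacency(n, 0.4, rng)
            g = nx.from_numpy_array(adj.edges)
            np.testing.assert_allclose(
                nn.clustering_coefficient(adj),
                [nx.clustering(g, i) for i in range(n)],
                atol=1e-12,
            )
            # networkx global_efficiency is the mean over nodes of our nodal form
            assert nn.global_efficiency_scalar(adj) == pytest.approx(
                nx.global_efficiency(g), abs=1e-12
            )
            # networkx local_efficiency is the mean of the nodal values
            assert np.mean(nn.nodal_local_efficiency(adj)) == pytest.approx(
                nx.local_efficiency(g), abs=1e-12
            )


# ---------------------------------------------------------------- properties


class TestProperties:
    @given(seed=st.integers(0, 10_000))
    def test_handshake_lemma(self, seed):
        rng = np.random.default_rng(seed)
        adj = random_adjacency(int(rng.integers(2, 15)), 0.4, rng)
        assert nn.nodal_degree(adj).sum() == 2 * adj.edge_count

    @given(seed=st.integers(0, 10_000))
    def test_metrics_bounded(self, seed):
        rng = np.random.default_rng(seed)
        adj = random_adjacency(int(rng.integers(2, 15)), float(rng.uniform(0, 1)), rng)
        ms = nn.metric_profile(adj)
        for vec in (ms.clustering, ms.local_efficiency, ms.global_efficiency):
            assert np.all(vec >= 0) and np.all(vec <= 1 + 1e-12)

    @given(seed=st.integers(0, 10_000))
    def test_degree_and_global_efficiency_monotone_under_edge_addition(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 12))
        adj = random_adjacency(n, 0.3, rng)
        absent = [
            (i, j)
            for i in range(n)
            for j in range(i + 1, n)
            if adj.edges[i, j] == 0
        ]
        if not absent:
            return
        i, j = absent[int(rng.integers(len(absent)))]
        grown = adj.edges.copy()
        grown[i, j] = grown[j, i] = 1
        bigger = nn.AdjacencyMatrix(edges=grown, threshold=0.0)
        assert np.all(nn.nodal_degree(bigger) >= nn.nodal_degree(adj))
        assert np.all(
            nn.nodal_global_efficiency(bigger) >= nn.nodal_global_efficiency(adj) - 1e-12
        )

    def test_profile_matches_individual_operations(self, rng):
        adj = random_adjacency(10, 0.4, rng)
        ms = nn.metric_profile(adj)
        np.testing.assert_array_equal(ms.degree, nn.nodal_degree(adj))
        np.testing.assert_array_equal(ms.clustering, nn.clustering_coefficient(adj))
        np.testing.assert_array_equal(ms.local_efficiency, nn.nodal_local_efficiency(adj))
        np.testing.assert_array_equal(ms.global_efficiency, nn.nodal_global_efficiency(adj))
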