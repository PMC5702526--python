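"""Graph metrics against independent oracles."""

import networkx as nx
import numpy as np
import pytest
from scipy.sparse.csgraph import floyd_warshall

from ctrlnet.connectivity import BinaryGraph
from ctrlnet.metrics import (MetricsError, detect_modules, global_efficiency,
                             global_metrics, local_efficiency,
                             modularity_of_partition, nodal_metrics,
                             normalize_globals, rewire_null, shortest_paths)

from conftest import random_adjacency


def graph_of(a):
    return BinaryGraph(np.asarray(a, dtype=np.int8))


def path_graph(n):
    a = np.zeros((n, n), dtype=np.int8)
    for i in range(n - 1):
        a[i, i + 1] = a[i + 1, i] = 1
    return graph_of(a)


def star_graph(leaves):
    a = np.zeros((leaves + 1, leaves + 1), dtype=np.int8)
    a[0, 1:] = a[1:, 0] = 1
    return graph_of(a)


def complete_graph(n):
    return graph_of(1 - np.eye(n, dtype=np.int8))


class TestShortestPaths:
    def test_complete_k4(self):
        sp = shortest_paths(complete_graph(4))
        off = ~np.eye(4, dtype=bool)
        assert np.all(sp.dist[off] == 1)

    def test_path_graph_counts(self):
        sp = shortest_paths(path_graph(3))
        assert sp.dist[0, 2] == 2
        assert sp.sigma[0, 2] == 1

    def test_disconnected_pairs_infinite(self):
        a = np.zeros((4, 4), dtype=np.int8)
        a[0, 1] = a[1, 0] = 1
        sp = shortest_paths(graph_of(a))
        assert np.isinf(sp.dist[0, 2])

    def test_matches_floyd_warshall_oracle(self, small_graphs):
        for a in small_graphs:
            sp = shortest_paths(graph_of(a))
            oracle = floyd_warshall(a.astype(float), directed=False,
                                    unweighted=True)
            assert np.array_equal(sp.dist, oracle)


class TestEfficiencies:
    def test_complete_graph_unity(self):
        assert global_efficiency(complete_graph(5)) == 1.0
        assert local_efficiency(complete_graph(4)) == 1.0

    def test_empty_graph_zero(self):
        assert global_efficiency(graph_of(np.zeros((4, 4)))) == 0.0

    def test_star_global_efficiency_hand_computed(self):
        # star with 4 leaves: 8 ordered hub pairs at d=1, 12 at d=2
        assert global_efficiency(star_graph(4)) == pytest.approx(0.7)

    def test_star_local_efficiency_zero(self):
        assert local_efficiency(star_graph(4)) == 0.0

    def test_match_networkx_oracle(self, small_graphs):
        for a in small_graphs[:60]:
            g = nx.from_numpy_array(a)
            bg = graph_of(a)
            assert global_efficiency(bg) == pytest.approx(
                nx.global_efficiency(g), abs=1e-12)
            assert local_efficiency(bg) == pytest.approx(
                nx.local_efficiency(g), abs=1e-12)

    def test_adding_edge_never_decreases_global_efficiency(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            a = random_adjacency(rng, 10)
            base = global_efficiency(graph_of(a))
            zeros = np.argwhere(np.triu(a == 0, k=1))
            if len(zeros) == 0:
                continue
            i, j = zeros[rng.integers(len(zeros))]
            a2 = a.copy()
            a2[i, j] = a2[j, i] = 1
            assert global_efficiency(graph_of(a2)) >= base - 1e-12


class TestModularity:
    def test_single_module_is_zero(self):
        rng = np.random.default_rng(2)
        a = random_adjacency(rng, 8, p=0.5)
        q = modularity_of_partition(graph_of(a), np.zeros(8, dtype=int))
        assert q == pytest.approx(0.0, abs=1e-12)

    def test_two_triangles_with_bridge_hand_value(self):
        a = np.zeros((6, 6), dtype=np.int8)
        for i, j in [(0, 1), (0, 2), (1, 2), (3, 4), (3, 5), (4, 5), (2, 3)]:
            a[i, j] = a[j, i] = 1
        part = np.array([0, 0, 0, 1, 1, 1])
        q = modularity_of_partition(graph_of(a), part)
        assert q == pytest.approx(2 * (3 / 7 - (7 / 14) ** 2), abs=1e-12)

    def test_matches_networkx_oracle_on_random_partitions(self, small_graphs):
        rng = np.random.default_rng(9)
        for a in small_graphs[:50]:
            if a.sum() == 0:
                continue
            n = a.shape[0]
            part = rng.integers(0, 3, size=n)
            # relabel so every module is nonempty
            _, part = np.unique(part, return_inverse=True)
            g = nx.from_numpy_array(a)
            comms = [set(np.flatnonzero(part == k))
                     for k in np.unique(part)]
            expected = nx.community.modularity(g, comms)
            got = modularity_of_partition(graph_of(a), part)
            assert got == pytest.approx(expected, abs=1e-12)

    def test_empty_module_rejected(self):
        a = 1 - np.eye(4, dtype=np.int8)
        with pytest.raises(MetricsError):
            modularity_of_partition(graph_of(a), np.array([0, 0, 2, 2]))


class TestDetectModules:
    def test_two_disjoint_cliques_recovered(self):
        a = np.zeros((8, 8), dtype=np.int8)
        a[:4, :4] = 1 - np.eye(4)
        a[4:, 4:] = 1 - np.eye(4)
        res = detect_modules(graph_of(a))
        assert res.n_modules == 2
        p = res.partition
        assert len(set(p[:4])) == 1 and len(set(p[4:])) == 1
        assert p[0] != p[4]

    def test_deterministic(self):
        rng = np.random.default_rng(4)
        a = random_adjacency(rng, 20, p=0.2)
        if a.sum() == 0:
            a[0, 1] = a[1, 0] = 1
        r1 = detect_modules(graph_of(a), seed=1)
        r2 = detect_modules(graph_of(a), seed=1)
        assert np.array_equal(r1.partition, r2.partition)
        assert r1.q == r2.q

    def test_edgeless_graph_rejected(self):
        with pytest.raises(MetricsError):
            detect_modules(graph_of(np.zeros((5, 5))))

    def test_beats_greedy_baseline(self, small_graphs):
        # spectral + fine-tuning should not fall below the networkx
        # greedy optimizer on small graphs
        for a in small_graphs[:30]:
            if a.sum() < 4:
                continue
            got = detect_modules(graph_of(a)).q
            g = nx.from_numpy_array(a)
            comms = nx.community.greedy_modularity_communities(g)
            ref = nx.community.modularity(g, comms)
            assert got >= ref - 0.05


class TestNodalMetrics:
    def test_star_hub(self):
        nm = nodal_metrics(star_graph(4))
        assert nm.degree[0] == 4
        assert nm.betweenness[0] == pytest.approx(6.0)  # C(4,2) pairs
        assert np.all(nm.betweenness[1:] == 0)

    def test_complete_graph(self):
        nm = nodal_metrics(complete_graph(6))
        assert np.all(nm.betweenness == 0)
        assert np.all(nm.efficiency == 1.0)

    def test_betweenness_matches_brute_force_enumeration(self, small_graphs):
        def oracle_betweenness(a):
            n = a.shape[0]
            dist = floyd_warshall(a.astype(float), directed=False,
                                  unweighted=True)
            btw = np.zeros(n)

            def count_paths(m, nn):
                # enumerate all shortest m->nn paths by DFS over the
                # predecessor structure
                if m == nn:
                    return 1, {}
                total = 0
                through: dict[int, int] = {}
                stack = [(nn, [nn])]
                paths = []
                # recursive enumeration
                def rec(v, acc):
                    nonlocal total
                    if v == m:
                        paths.append(list(acc))
                        return
                    for u in np.flatnonzero(a[v]):
                        if dist[m, u] == dist[m, v] - 1:
                            rec(u, acc + [u])
                rec(nn, [nn])
                total = len(paths)
                for p in paths:
                    for v in p[1:-1]:
                        through[v] = through.get(v, 0) + 1
                return total, through

            for m in range(n):
                for nn in range(m + 1, n):
                    if not np.isfinite(dist[m, nn]):
                        continue
                    total, through = count_paths(m, nn)
                    for v, c in through.items():
                        btw[v] += c / total
            return btw

        for a in small_graphs[:40]:
            nm = nodal_metrics(graph_of(a))
            assert np.allclose(nm.betweenness, oracle_betweenness(a),
                               atol=1e-10)

    def test_betweenness_matches_networkx(self, small_graphs):
        for a in small_graphs[40:120]:
            nm = nodal_metrics(graph_of(a))
            ref = nx.betweenness_centrality(nx.from_numpy_array(a),
                                            normalized=False)
            assert np.allclose(nm.betweenness,
                               [ref[i] for i in range(a.shape[0])],
                               atol=1e-10)


class TestRewireNull:
    def test_degree_sequence_preserved(self):
        rng = np.random.default_rng(6)
        a = random_adjacency(rng, 15, p=0.3)
        g = graph_of(a)
        for null in rewire_null(g, n_nulls=20, seed=0):
            assert np.array_equal(null.degrees, g.degrees)
            assert null.n_edges == g.n_edges

    def test_cycle_stays_two_regular(self):
        n = 6
        a = np.zeros((n, n), dtype=np.int8)
        for i in range(n):
            a[i, (i + 1) % n] = a[(i + 1) % n, i] = 1
        for null in rewire_null(graph_of(a), n_nulls=10, seed=1):
            assert np.all(null.degrees == 2)

    def test_rewiring_randomizes_modular_structure(self):
        # two cliques + bridge: mean null modularity < observed
        a = np.zeros((12, 12), dtype=np.int8)
        a[:6, :6] = 1 - np.eye(6)
        a[6:, 6:] = 1 - np.eye(6)
        a[5, 6] = a[6, 5] = 1
        g = graph_of(a)
        q_obs = detect_modules(g).q
        q_null = np.mean([detect_modules(x).q
                          for x in rewire_null(g, n_nulls=20, seed=3)])
        assert q_null < q_obs

    def test_too_constrained_graph_warns(self):
        with pytest.warns(UserWarning, match="constrained"):
            rewire_null(complete_graph(4), n_nulls=2, seed=0)


class TestNormalizeGlobals:
    def test_self_normalization_is_unity(self):
        a = np.zeros((8, 8), dtype=np.int8)
        a[:4, :4] = 1 - np.eye(4)
        a[4:, 4:] = 1 - np.eye(4)
        a[3, 4] = a[4, 3] = 1
        g = graph_of(a)
        gm = global_metrics(g)
        out = normalize_globals(gm, [gm])
        assert out.normalized_e_glob == 1.0
        assert out.normalized_e_loc == 1.0
        assert out.normalized_q == 1.0

    def test_zero_null_mean_rejected(self):
        gm = global_metrics(complete_graph(5))
        null = global_metrics(star_graph(4))  # e_loc = 0
        with pytest.raises(MetricsError, match="zero"):
            normalize_globals(gm, [null])
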