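import numpy as np
import networkx as nx
import pytest

import eegnets as e
from eegnets.netmetrics import metrics_bundle
from conftest import random_adjacency
from _oracles import brute_force_metrics


def adj_from_edges(n, edges):
    a = np.zeros((n, n), dtype=np.int8)
    for i, j in edges:
        a[i, j] = a[j, i] = 1
    return a


PATH4 = adj_from_edges(4, [(0, 1), (1, 2), (2, 3)])
CYCLE4 = adj_from_edges(4, [(0, 1), (1, 2), (2, 3), (3, 0)])


class TestShortestPaths:
    def test_complete_graph_all_distance_one(self):
        a = 1 - np.eye(20, dtype=np.int8)
        dist, counts = e.shortest_paths(a)
        off = ~np.eye(20, dtype=bool)
        assert (dist[off] == 1).all() and (counts[off] == 1).all()

    def test_path_graph(self):
        dist, counts = e.shortest_paths(PATH4)
        assert dist[0, 3] == 3 and counts[0, 3] == 1

    def test_cycle_two_geodesics(self):
        dist, counts = e.shortest_paths(CYCLE4)
        assert dist[0, 2] == 2 and counts[0, 2] == 2

    def test_disconnected_infinite(self):
        a = adj_from_edges(4, [(0, 1)])
        dist, counts = e.shortest_paths(a)
        assert np.isinf(dist[0, 2]) and counts[0, 2] == 0


class TestPathLength:
    def test_complete(self):
        l, cpf = e.avg_path_length(1 - np.eye(20, dtype=np.int8))
        assert l == 1.0 and cpf == 1.0

    def test_path4_enumeration(self):
        # pairwise geodesics 1+2+3+1+2+1 over 6 pairs
        l, cpf = e.avg_path_length(PATH4)
        assert l == pytest.approx(10 / 6)
        assert cpf == 1.0

    def test_two_disjoint_triangles(self):
        a = adj_from_edges(6, [(0, 1), (1, 2), (2, 0), (3, 4), (4, 5), (5, 3)])
        l, cpf = e.avg_path_length(a)
        assert l == 1.0 and cpf == pytest.approx(6 / 15)

    def test_empty_graph_undefined(self):
        with pytest.raises(ValueError, match="undefined"):
            e.avg_path_length(np.zeros((4, 4), dtype=np.int8))


class TestClustering:
    def test_triangle(self):
        a = adj_from_edges(3, [(0, 1), (1, 2), (2, 0)])
        assert e.clustering(a, 0) == 1.0

    def test_star_center_zero(self):
        a = adj_from_edges(6, [(0, i) for i in range(1, 6)])
        assert e.clustering(a, 0) == 0.0

    def test_one_of_three_neighbor_links(self):
        a = adj_from_edges(4, [(3, 0), (3, 1), (3, 2), (0, 1)])
        assert e.clustering(a, 3) == pytest.approx(1 / 3)


class TestBetweenness:
    def test_complete_zero(self):
        assert np.allclose(e.betweenness(1 - np.eye(20, dtype=np.int8)), 0.0)

    def test_middle_of_path3(self):
        a = adj_from_edges(3, [(0, 1), (1, 2)])
        assert e.betweenness(a, 1) == 1.0

    def test_cycle_half(self):
        assert e.betweenness(CYCLE4, 1) == pytest.approx(0.5)

    def test_star_center(self):
        n = 8
        a = adj_from_edges(n, [(0, i) for i in range(1, n)])
        assert e.betweenness(a, 0) == pytest.approx((n - 1) * (n - 2) / 2)

    def test_conservation_law(self, rng):
        """Σ_i B_i = Σ_pairs (d − 1): geodesics of length d have d−1 interiors."""
        for _ in range(20):
            a = random_adjacency(rng, n=15, p=rng.uniform(0.1, 0.5))
            dist, _ = e.shortest_paths(a)
            iu, ju = np.triu_indices(15, k=1)
            d = dist[iu, ju]
            finite = np.isfinite(d)
            assert e.betweenness(a).sum() == pytest.approx(
                (d[finite] - 1).sum(), abs=1e-9
            )


class TestGlobalMetrics:
    def test_complete(self):
        gm = e.global_metrics(1 - np.eye(20, dtype=np.int8))
        assert (gm.l_avg, gm.c_avg, gm.b_avg) == (1.0, 1.0, 0.0)

    def test_b_avg_is_mean_of_nodes(self, rng):
        a = random_adjacency(rng, n=12, p=0.3)
        gm = e.global_metrics(a)
        assert gm.b_avg == pytest.approx(e.betweenness(a).mean())


class TestInvariants:
    def test_handshake(self, rng):
        for k in (5, 30, 100):
            m = rng.uniform(-1, 1, size=(20, 20))
            m = (m + m.T) / 2
            np.fill_diagonal(m, 1.0)
            net = e.build_fixed_links(m, k)
            assert e.degree(net).sum() == 2 * k

    def test_degenerate_bounds(self, rng):
        a = random_adjacency(rng, n=15, p=0.12)
        deg = e.degree(a)
        clu = e.clustering(a)
        bet = e.betweenness(a)
        assert np.all(clu[deg < 2] == 0.0)
        assert np.all(bet[deg <= 1] == 0.0)

    def test_bundle_matches_individual(self, rng):
        a = random_adjacency(rng, n=12, p=0.3)
        deg, clu, bet, l, cpf = metrics_bundle(a)
        np.testing.assert_array_equal(deg, e.degree(a))
        np.testing.assert_allclose(clu, e.clustering(a))
        np.testing.assert_allclose(bet, e.betweenness(a))
        assert (l, cpf) == e.avg_path_length(a)


class TestOracleEquivalence:
    def test_small_graph_brute_force(self, rng):
        """Exact match vs all-simple-path enumeration on random ≤5-node graphs."""
        for _ in range(40):
            n = int(rng.integers(2, 6))
            a = random_adjacency(rng, n=n, p=rng.uniform(0.1, 0.9))
            deg_o, clu_o, bet_o, l_o, cpf_o, dist_o, counts_o = brute_force_metrics(a)
            dist, counts = e.shortest_paths(a)
            np.testing.assert_array_equal(dist, dist_o)
            np.testing.assert_array_equal(counts, counts_o)
            np.testing.assert_array_equal(e.degree(a), deg_o)
            np.testing.assert_allclose(e.clustering(a), clu_o, atol=1e-12)
            np.testing.assert_allclose(e.betweenness(a), bet_o, atol=1e-9)
            if np.isfinite(l_o):
                l, cpf = e.avg_path_length(a)
                assert l == pytest.approx(l_o) and cpf == pytest.approx(cpf_o)

    def test_networkx_cross_check_20_nodes(self, rng):
        """Independent Brandes implementation agrees on 20-node graphs."""
        for _ in range(25):
            a = random_adjacency(rng, n=20, p=rng.uniform(0.1, 0.5))
            g = nx.from_numpy_array(a)
            bc = nx.betweenness_centrality(g, normalized=False)
            np.testing.assert_allclose(
                e.betweenness(a), [bc[i] for i in range(20)], atol=1e-8
            )
            np.testing.assert_allclose(
                e.clustering(a), [nx.clustering(g, i) for i in range(20)],
                atol=1e-12,
            )


class TestErBaseline:
    def test_full_density_is_complete_graph(self):
        df = e.er_baseline(10, 45, reps=5, seed=1)
        assert (df.l_avg == 1.0).all() and (df.c_avg == 1.0).all()

    def test_expected_clustering_equals_density(self):
        """ER clustering concentrates at the edge density K / (N choose 2)."""
        df = e.er_baseline(20, 50, reps=300, seed=2)
        density = 50 / 190
        mean = df.c_avg.mean()
        sd = df.c_avg.std(ddof=1)
        assert abs(mean - density) < 3 * sd / np.sqrt(len(df)) + 0.01

    def test_k_out_of_range(self):
        with pytest.raises(ValueError):
            e.er_baseline(5, 11, reps=2)
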