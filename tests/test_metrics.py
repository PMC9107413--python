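import numpy as np
import networkx as nx
import pytest

from covnet import (
    auc_over_densities,
    build_network,
    characteristic_path_length,
    clustering_coefficient,
    density_grid,
    local_efficiency,
    metric_profiles,
    nodal_degree,
    normalized_global_metrics,
    random_reference,
)
from covnet.metrics import global_efficiency

from oracles import (
    brute_clustering,
    brute_global_efficiency,
    brute_local_efficiency,
    brute_path_length,
    random_graph,
)


def _adj(edges, n):
    A = np.zeros((n, n), dtype=np.uint8)
    for i, j in edges:
        A[i, j] = A[j, i] = 1
    return A


class TestClustering:
    def test_triangle(self):
        c, mean = clustering_coefficient(_adj([(0, 1), (1, 2), (0, 2)], 3))
        assert np.allclose(c, 1.0) and mean == 1.0

    def test_path_center_zero(self):
        c, _ = clustering_coefficient(_adj([(0, 1), (1, 2)], 3))
        assert c[1] == 0.0

    def test_k4_minus_edge(self):
        A = _adj([(0, 1), (0, 2), (0, 3), (1, 2), (1, 3)], 4)  # K4 minus (2,3)
        c, _ = clustering_coefficient(A)
        assert np.allclose(c, brute_clustering(A))
        assert c[2] == pytest.approx(1.0)  # degree-2 node in one triangle
        assert c[0] == pytest.approx(2 / 3)  # degree-3 node, 2 of 3 pairs linked


class TestPathLength:
    def test_complete_graph(self):
        A = np.ones((82, 82), dtype=np.uint8) - np.eye(82, dtype=np.uint8)
        assert characteristic_path_length(A) == pytest.approx(1.0)

    def test_four_cycle(self):
        A = _adj([(0, 1), (1, 2), (2, 3), (3, 0)], 4)
        assert characteristic_path_length(A) == pytest.approx(4 / 3)

    def test_disjoint_triangles_reachable_pairs_only(self):
        A = _adj([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)], 6)
        assert characteristic_path_length(A) == pytest.approx(1.0)

    def test_harmonic_policy_penalizes_disconnection(self):
        two_triangles = _adj([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)], 6)
        one_component = _adj([(0, 1), (1, 2), (0, 2), (2, 3), (3, 4), (4, 5)], 6)
        l_frag = characteristic_path_length(two_triangles, policy="harmonic")
        assert l_frag == pytest.approx(30 / 12)  # 12 unit-distance ordered pairs
        assert l_frag > characteristic_path_length(two_triangles, policy="reachable")
        assert characteristic_path_length(one_component, policy="harmonic") > 0

    def test_largest_component_policy(self):
        A = _adj([(0, 1), (1, 2), (2, 3), (3, 0), (4, 5)], 6)
        assert characteristic_path_length(A, policy="largest_component") == pytest.approx(4 / 3)

    def test_edgeless_graph_raises(self):
        with pytest.raises(ValueError):
            characteristic_path_length(np.zeros((5, 5), dtype=np.uint8))


class TestLocalEfficiency:
    def test_triangle_node(self):
        A = _adj([(0, 1), (1, 2), (0, 2)], 3)
        assert local_efficiency(A, 0) == pytest.approx(1.0)

    def test_star_center_zero(self):
        A = _adj([(0, 1), (0, 2), (0, 3), (0, 4)], 5)
        assert local_efficiency(A, 0) == 0.0

    def test_five_node_toy_matches_oracle(self, rng):
        A = _adj([(0, 1), (0, 2), (0, 3), (1, 2), (2, 3), (3, 4)], 5)
        assert np.allclose(local_efficiency(A), brute_local_efficiency(A))


def test_degree_examples(rng):
    K = np.ones((82, 82), dtype=np.uint8) - np.eye(82, dtype=np.uint8)
    assert np.all(nodal_degree(K) == 81)
    assert np.all(nodal_degree(np.zeros((82, 82), dtype=np.uint8)) == 0)
    A = _adj([(0, 1), (0, 2), (0, 3), (1, 2)], 5)
    assert list(nodal_degree(A)) == [3, 2, 2, 1, 0]


class TestMetricsAgainstBruteForce:
    def test_random_small_graphs_match_oracle(self):
        """Clustering, path length, local efficiency and degree agree with
        exhaustive enumeration on 200 random graphs of <= 8 nodes."""
        rng = np.random.default_rng(77)
        checked_paths = 0
        for _ in range(200):
            n = int(rng.integers(2, 9))
            p = float(rng.uniform(0.1, 0.9))
            A = random_graph(n, p, rng)
            c, mean = clustering_coefficient(A)
            assert np.allclose(c, brute_clustering(A), atol=1e-12)
            assert mean == pytest.approx(brute_clustering(A).mean())
            assert np.array_equal(nodal_degree(A), A.sum(1))
            assert np.allclose(local_efficiency(A), brute_local_efficiency(A), atol=1e-12)
            assert global_efficiency(A) == pytest.approx(brute_global_efficiency(A), abs=1e-12)
            if A.sum() > 0:
                assert characteristic_path_length(A) == pytest.approx(brute_path_length(A))
                checked_paths += 1
        assert checked_paths > 150


class TestRandomReference:
    def test_degree_sequence_preserved(self, rng):
        A = random_graph(40, 0.2, rng)
        R = random_reference(A, seed=0)
        assert np.array_equal(np.sort(R.sum(1)), np.sort(A.sum(1)))
        assert np.array_equal(R.sum(1), A.sum(1))

    def test_output_is_simple_graph(self, rng):
        A = random_graph(30, 0.3, rng)
        R = random_reference(A, seed=1)
        assert np.all(np.diag(R) == 0)
        assert np.array_equal(R, R.T)
        assert set(np.unique(R)) <= {0, 1}

    def test_pure_function_of_seed(self, rng):
        A = random_graph(30, 0.3, rng)
        assert np.array_equal(random_reference(A, seed=5), random_reference(A, seed=5))

    def test_four_cycle_stays_simple(self):
        A = _adj([(0, 1), (1, 2), (2, 3), (3, 0)], 4)
        R = random_reference(A, seed=3)
        assert np.all(np.diag(R) == 0) and R.sum() == A.sum()

    def test_no_swap_possible_warns(self):
        A = _adj([(0, 1)], 3)
        with pytest.warns(UserWarning):
            R = random_reference(A, seed=0)
        assert np.array_equal(R, A)

    def test_lattice_declusters(self):
        """Rewiring destroys lattice clustering in >= 95% of seeds."""
        G = nx.watts_strogatz_graph(60, 8, 0.0, seed=1)  # pure ring lattice
        A = nx.to_numpy_array(G, dtype=np.uint8)
        c0 = clustering_coefficient(A)[1]
        wins = sum(
            clustering_coefficient(random_reference(A, seed=s))[1] < c0
            for s in range(100)
        )
        assert wins >= 95


class TestNormalizedGlobalMetrics:
    def test_self_null_gives_unity(self, rng):
        A = random_graph(40, 0.2, rng)
        res = normalized_global_metrics(A, null_graphs=[A])
        assert res.gamma == pytest.approx(1.0)
        assert res.lam == pytest.approx(1.0)
        assert res.sigma == pytest.approx(1.0)

    def test_small_world_ring_lattice(self):
        """A rewired ring lattice is small-world: sigma > 1.1."""
        G = nx.watts_strogatz_graph(82, 8, 0.1, seed=42)
        A = nx.to_numpy_array(G, dtype=np.uint8)
        res = normalized_global_metrics(A, n_null=50, seed=0)
        assert res.sigma > 1.1

    def test_random_graph_sigma_near_one(self, rng):
        A = random_graph(82, 0.2, rng)
        res = normalized_global_metrics(A, n_null=100, seed=0)
        assert res.gamma == pytest.approx(1.0, abs=0.1)
        assert res.lam == pytest.approx(1.0, abs=0.1)

    def test_sigma_is_gamma_over_lambda(self, rng):
        A = random_graph(50, 0.15, rng)
        res = normalized_global_metrics(A, n_null=5, seed=2)
        assert res.sigma == res.gamma / res.lam


class TestAUC:
    def test_constant_profile(self):
        grid = density_grid(0.10, 0.40, 0.01)
        assert auc_over_densities(np.ones_like(grid), grid) == pytest.approx(0.30)

    def test_linear_ramp(self):
        grid = density_grid(0.10, 0.40, 0.01)
        ramp = np.linspace(0, 1, len(grid))
        assert auc_over_densities(ramp, grid) == pytest.approx(0.15)

    def test_two_point_trapezoid(self):
        assert auc_over_densities([2.0, 4.0], [0.1, 0.4]) == pytest.approx(0.9)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            auc_over_densities([1.0, 2.0], [0.1, 0.2, 0.3])
        with pytest.raises(ValueError):
            auc_over_densities([1.0], [0.1])


class TestMetricProfiles:
    def test_flat_profiles_for_equal_weights(self):
        W = 0.5 * (np.ones((20, 20)) - np.eye(20))
        grid = density_grid(0.2, 0.4, 0.1)
        gp, lp = metric_profiles(W, grid, n_null=3, seed=0)
        # ties resolved identically at each density; profile driven solely
        # by density, and sigma = gamma/lambda exactly
        assert np.all(gp.sigma == gp.gamma / gp.lam)
        assert lp.degree.shape == (20, 3)

    def test_determinism(self, rng):
        W = build_network(rng.normal(size=30))
        grid = density_grid(0.2, 0.4, 0.1)
        g1, l1 = metric_profiles(W, grid, n_null=4, seed=11)
        g2, l2 = metric_profiles(W, grid, n_null=4, seed=11)
        assert np.array_equal(g1.gamma, g2.gamma)
        assert np.array_equal(g1.lam, g2.lam)
        assert np.array_equal(l1.local_efficiency, l2.local_efficiency)

    def test_toy_profile_matches_manual_evaluation(self):
        rng = np.random.default_rng(4)
        W = build_network(rng.normal(size=10))
        grid = np.array([0.3, 0.6])
        gp, lp = metric_profiles(W, grid, n_null=2, seed=9)
        from covnet import threshold_at_density

        for t, d in enumerate(grid):
            A = threshold_at_density(W, d)
            c, mean_c = clustering_coefficient(A)
            assert gp.clustering[t] == pytest.approx(mean_c)
            assert gp.path_length[t] == pytest.approx(characteristic_path_length(A))
            assert np.allclose(lp.clustering[:, t], c)
            assert np.allclose(lp.degree[:, t], nodal_degree(A))
        aucs = gp.auc
        assert aucs["sigma"] == pytest.approx(
            auc_over_densities(gp.sigma, grid), rel=1e-12
        )
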