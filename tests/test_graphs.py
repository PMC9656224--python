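import numpy as np
import pytest

from emograph.connectivity import AdjacencyMatrix
from emograph.graphs import (
    betweenness_centrality,
    characteristic_path_length,
    clustering_coefficients,
    degree_centrality,
    density,
    global_efficiency,
    graph_feature_block,
    local_efficiency,
    modularity,
    partition_modularity,
    shortest_path_matrix,
    transitivity,
)

from .oracles import (
    betweenness_oracle,
    binary_clustering_oracle,
    binary_transitivity_oracle,
    clustering_oracle,
    floyd_warshall,
    local_efficiency_oracle,
    modularity_oracle,
    transitivity_oracle,
)


def random_weighted(rng, n, sparsity=0.0):
    w = rng.uniform(0.1, 1.0, (n, n))
    w = (w + w.T) / 2
    np.fill_diagonal(w, 0)
    if sparsity:
        drop = rng.uniform(size=(n, n)) < sparsity
        drop = np.triu(drop, 1)
        w[drop | drop.T] = 0
    return w


def path_graph(n):
    w = np.zeros((n, n))
    for i in range(n - 1):
        w[i, i + 1] = w[i + 1, i] = 1.0
    return w


def star_graph(n):
    w = np.zeros((n, n))
    w[0, 1:] = w[1:, 0] = 1.0
    return w


def triangle():
    return np.ones((3, 3)) - np.eye(3)


def complete(n):
    return np.ones((n, n)) - np.eye(n)


class TestShortestPaths:
    def test_two_unit_hops(self):
        d = shortest_path_matrix(path_graph(3))
        assert d[0, 2] == 2.0

    def test_detour_beats_weak_direct_edge(self):
        w = np.array([[0, 1, 0.25], [1, 0, 1], [0.25, 1, 0]])
        d = shortest_path_matrix(w)
        assert d[0, 2] == 2.0  # via the middle node, not 1/0.25 = 4

    def test_floyd_warshall_equivalence(self, rng):
        for _ in range(20):
            w = random_weighted(rng, 8, sparsity=0.4)
            np.testing.assert_allclose(
                shortest_path_matrix(w), floyd_warshall(w), atol=1e-12
            )

    def test_disconnected_inf(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 1.0
        d = shortest_path_matrix(w)
        assert np.isinf(d[0, 2])


class TestCharacteristicPathLength:
    def test_complete_unit_graph(self):
        for n in (3, 5, 8):
            assert characteristic_path_length(complete(n)) == pytest.approx(1.0)

    def test_path_graph_enumeration(self):
        assert characteristic_path_length(path_graph(3)) == pytest.approx(4 / 3)

    def test_weight_scaling(self, rng):
        w = random_weighted(rng, 6)
        c = 2.5
        assert characteristic_path_length(c * w) == pytest.approx(
            characteristic_path_length(w) / c
        )

    def test_disconnected_raises(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 1.0
        with pytest.raises(ValueError, match="disconnected"):
            characteristic_path_length(w)


class TestEfficiencies:
    def test_complete_graph(self):
        assert global_efficiency(complete(4)) == pytest.approx(1.0)

    def test_path_graph(self):
        assert global_efficiency(path_graph(3)) == pytest.approx(5 / 6)

    def test_empty_graph(self):
        assert global_efficiency(np.zeros((4, 4))) == 0.0

    def test_triangle_local(self):
        np.testing.assert_allclose(local_efficiency(triangle()), 1.0)

    def test_star_leaves_zero(self):
        le = local_efficiency(star_graph(5))
        np.testing.assert_array_equal(le[1:], 0.0)

    def test_local_efficiency_oracle(self, rng):
        for _ in range(15):
            w = random_weighted(rng, 7, sparsity=0.4)
            np.testing.assert_allclose(
                local_efficiency(w), local_efficiency_oracle(w), atol=1e-12
            )

    def test_harmonic_arithmetic_inequality(self, rng):
        for _ in range(10):
            w = random_weighted(rng, 7)
            assert 1.0 / characteristic_path_length(w) <= global_efficiency(w) + 1e-12


class TestClusteringTransitivity:
    def test_triangle(self):
        np.testing.assert_allclose(clustering_coefficients(triangle()), 1.0)
        assert transitivity(triangle()) == pytest.approx(1.0)

    def test_star(self):
        np.testing.assert_array_equal(clustering_coefficients(star_graph(5)), 0.0)
        assert transitivity(star_graph(5)) == 0.0

    def test_binary_reduces_to_classic(self, rng):
        for _ in range(15):
            w = (random_weighted(rng, 8, sparsity=0.5) > 0).astype(float)
            np.testing.assert_allclose(
                clustering_coefficients(w), binary_clustering_oracle(w), atol=1e-12
            )
            assert transitivity(w) == pytest.approx(
                binary_transitivity_oracle(w), abs=1e-12
            )

    def test_weighted_oracles(self, rng):
        for _ in range(10):
            w = random_weighted(rng, 7, sparsity=0.3)
            np.testing.assert_allclose(
                clustering_coefficients(w), clustering_oracle(w), atol=1e-12
            )
            assert transitivity(w) == pytest.approx(
                transitivity_oracle(w), abs=1e-12
            )


class TestBetweenness:
    def test_star_centre(self):
        bc = betweenness_centrality(star_graph(4))
        assert bc[0] == pytest.approx(1.0)
        np.testing.assert_array_equal(bc[1:], 0.0)

    def test_complete_graph_zero(self):
        np.testing.assert_allclose(betweenness_centrality(complete(5)), 0.0)

    def test_enumeration_oracle(self, rng):
        for _ in range(10):
            w = random_weighted(rng, 7, sparsity=0.3)
            np.testing.assert_allclose(
                betweenness_centrality(w), betweenness_oracle(w), atol=1e-9
            )


class TestDegreeDensity:
    def test_triangle_strength(self):
        np.testing.assert_allclose(degree_centrality(triangle()), 2.0)

    def test_star_strengths(self):
        s = degree_centrality(star_graph(5))
        assert s[0] == 4.0
        np.testing.assert_array_equal(s[1:], 1.0)

    def test_density_examples(self):
        assert density(triangle()) == 3.0
        assert density(np.zeros((4, 4))) == 0.0

    def test_density_linearity(self, rng):
        w = random_weighted(rng, 6)
        assert density(2 * w) == pytest.approx(2 * density(w))

    def test_handshake_identity(self, rng):
        w = random_weighted(rng, 6)
        assert degree_centrality(w).sum() == pytest.approx(2 * density(w))


class TestModularity:
    def test_single_community_q_zero(self, rng):
        w = random_weighted(rng, 6)
        assert partition_modularity(w, np.zeros(6, dtype=int)) == pytest.approx(0.0)

    def test_two_disjoint_triangles(self):
        w = np.zeros((6, 6))
        for a, b in [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)]:
            w[a, b] = w[b, a] = 1.0
        assert modularity(w) == pytest.approx(0.5)
        assert modularity_oracle(w) == pytest.approx(0.5)

    def test_all_zero_graph(self):
        assert modularity(np.zeros((4, 4))) == 0.0

    def test_within_tolerance_of_exhaustive(self, rng):
        for _ in range(15):
            n = int(rng.integers(4, 7))
            w = random_weighted(rng, n, sparsity=0.4)
            assert modularity(w) >= modularity_oracle(w) - 0.05

    def test_never_negative(self, rng):
        for _ in range(10):
            w = random_weighted(rng, 6)
            assert modularity(w) >= 0.0


class TestFeatureBlock:
    def _adj(self, rng, n):
        w = random_weighted(rng, n)
        return AdjacencyMatrix(w, tuple(f"c{i}" for i in range(n)))

    def test_length_14_nodes(self, rng):
        block = graph_feature_block(self._adj(rng, 14))
        assert len(block.values) == 61  # 5 + 4 x 14

    def test_length_32_nodes(self, rng):
        block = graph_feature_block(self._adj(rng, 32))
        assert len(block.values) == 133  # 5 + 4 x 32

    def test_names_stable_and_unique(self, rng):
        adj = self._adj(rng, 5)
        a = graph_feature_block(adj)
        b = graph_feature_block(adj)
        assert a.names == b.names
        assert len(set(a.names)) == len(a.names)
        assert a.names[:5] == [
            "characteristic_path_length", "global_efficiency", "transitivity",
            "modularity", "density",
        ]

    def test_node_permutation_equivariance(self, rng):
        n = 7
        w = random_weighted(rng, n)
        labels = tuple(f"c{i}" for i in range(n))
        perm = rng.permutation(n)
        block = graph_feature_block(AdjacencyMatrix(w, labels))
        permuted = graph_feature_block(
            AdjacencyMatrix(w[np.ix_(perm, perm)], tuple(labels[i] for i in perm))
        )
        # globals unchanged (modularity detector is partition-dependent but
        # the partition search is label-agnostic up to ties)
        np.testing.assert_allclose(permuted.values[:3], block.values[:3], atol=1e-9)
        assert permuted.values[4] == pytest.approx(block.values[4])
        ref = dict(zip(block.names, block.values))
        for name, value in zip(permuted.names, permuted.values):
            if "__" in name:
                assert value == pytest.approx(ref[name], abs=1e-9)
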