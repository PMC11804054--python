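"""RB quality, the multiplex optimizer vs exhaustive enumeration, and the
resolution search."""

import numpy as np
import pytest
from scipy.sparse.csgraph import connected_components

from spatialmux import (
    LayerSpec,
    Partition,
    ValidationError,
    WeightedGraph,
    leiden,
    leiden_multiplex,
    multiplex_quality,
    rb_quality,
    search_resolution,
    spatial_leiden,
)


def graph_from_edges(n, edges, weights=None):
    u, v = zip(*edges)
    w = np.ones(len(edges)) if weights is None else np.asarray(weights, float)
    return WeightedGraph(n, np.array(u), np.array(v), w)


def two_triangles():
    return graph_from_edges(6, [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)])


def bridged_cliques():
    return graph_from_edges(6, [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5), (2, 3)])


def set_partitions(n):
    """All partitions of {0..n-1} as membership tuples (Bell enumeration)."""
    if n == 1:
        yield (0,)
        return
    for rest in set_partitions(n - 1):
        k = max(rest) + 1
        for c in range(k + 1):
            yield rest + (c,)


def exhaustive_optimum(layers):
    """Best multiplex quality over every partition (dense double-sum oracle)."""
    n = layers[0].graph.n_nodes
    mats = []
    for spec in layers:
        if spec.layer_weight == 0:
            continue
        A = spec.graph.to_csr().toarray()
        k = A.sum(axis=1)
        mats.append((spec.layer_weight, spec.resolution, A, k, k.sum()))
    best = -np.inf
    for mem in set_partitions(n):
        m = np.asarray(mem)
        same = m[:, None] == m[None, :]
        q = sum(w * ((A * same).sum() - gamma * (k @ (same @ k)) / tm)
                for w, gamma, A, k, tm in mats)
        best = max(best, q)
    return best


def random_instance(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, 9))
    layers = []
    for _ in range(2):
        edges = [(i, j) for i in range(n) for j in range(i + 1, n) if rng.random() < 0.5]
        if not edges:
            edges = [(0, 1)]
        u, v = zip(*edges)
        g = WeightedGraph(n, np.array(u), np.array(v), rng.uniform(0.1, 2.0, len(edges)))
        layers.append(LayerSpec(g, float(rng.uniform(0.2, 2.0)), float(rng.uniform(0.5, 1.5))))
    return layers


class TestRbQuality:
    def test_two_triangles_partitioned_by_triangle(self):
        part = Partition(np.array([0, 0, 0, 1, 1, 1]))
        assert rb_quality(two_triangles(), part, gamma=1.0) == pytest.approx(6.0)

    def test_gamma_zero_single_community_gives_total_weight(self, rng):
        g = graph_from_edges(5, [(0, 1), (1, 2), (2, 3), (3, 4)], rng.uniform(0.5, 2, 4))
        part = Partition(np.zeros(5, dtype=int))
        assert rb_quality(g, part, gamma=1e-12) == pytest.approx(2 * g.weight.sum())

    def test_singleton_partition_gamma_zero_is_zero(self):
        g = two_triangles()
        part = Partition(np.arange(6))
        assert rb_quality(g, part, gamma=1e-12) == pytest.approx(0.0, abs=1e-6)

    def test_matches_leidenalg_quality(self):
        """Dual route: our quality function vs the igraph reference on random
        graphs and partitions."""
        import igraph as ig
        import leidenalg as la

        rng = np.random.default_rng(3)
        for _ in range(10):
            n = int(rng.integers(5, 20))
            edges = [(i, j) for i in range(n) for j in range(i + 1, n) if rng.random() < 0.4]
            if not edges:
                continue
            u, v = zip(*edges)
            w = rng.uniform(0.1, 3.0, len(edges))
            g = WeightedGraph(n, np.array(u), np.array(v), w)
            mem = rng.integers(0, 3, n)
            from spatialmux.multiplex_leiden import relabel_by_first_occurrence

            part = Partition(relabel_by_first_occurrence(mem))
            gamma = float(rng.uniform(0.3, 2.0))
            gi = ig.Graph(n=n, edges=list(edges))
            ref = la.RBConfigurationVertexPartition(
                gi, initial_membership=list(part.membership), weights=list(w),
                resolution_parameter=gamma,
            ).quality()
            assert rb_quality(g, part, gamma) == pytest.approx(ref, rel=1e-10)


class TestMultiplexQuality:
    def test_zero_weight_layer_contributes_nothing(self):
        g = two_triangles()
        part = Partition(np.array([0, 0, 0, 1, 1, 1]))
        layers = [LayerSpec(g, 1.0, 1.0), LayerSpec(bridged_cliques(), 0.0, 1.0)]
        assert multiplex_quality(layers, part) == rb_quality(g, part, 1.0)

    def test_duplicated_layer_doubles_quality(self):
        g = two_triangles()
        part = Partition(np.array([0, 0, 0, 1, 1, 1]))
        layers = [LayerSpec(g, 1.0, 1.0), LayerSpec(g, 1.0, 1.0)]
        assert multiplex_quality(layers, part) == pytest.approx(2 * rb_quality(g, part, 1.0))

    def test_weight_scaling_scales_quality(self):
        g, h = two_triangles(), bridged_cliques()
        part = Partition(np.array([0, 0, 0, 1, 1, 1]))
        q1 = multiplex_quality([LayerSpec(g, 1.0, 1.0), LayerSpec(h, 0.5, 1.2)], part)
        q3 = multiplex_quality([LayerSpec(g, 3.0, 1.0), LayerSpec(h, 1.5, 1.2)], part)
        assert q3 == pytest.approx(3 * q1)

    def test_node_count_mismatch_rejected(self):
        g = two_triangles()
        h = graph_from_edges(4, [(0, 1), (2, 3)])
        with pytest.raises(ValidationError):
            multiplex_quality([LayerSpec(g, 1, 1), LayerSpec(h, 1, 1)], Partition(np.zeros(6, int)))


class TestLeidenMultiplex:
    def test_bridged_cliques_recovered_at_global_optimum(self):
        g = bridged_cliques()
        part = leiden(g, 1.0, seed=0)
        assert part.n_clusters == 2
        assert part.membership[0] == part.membership[1] == part.membership[2]
        assert part.quality == pytest.approx(5.0)
        assert exhaustive_optimum([LayerSpec(g, 1.0, 1.0)]) == pytest.approx(5.0)

    def test_zero_weight_layer_leaves_partition_unchanged(self):
        g = bridged_cliques()
        p1 = leiden_multiplex([LayerSpec(g, 1.0, 1.0)], seed=5)
        p2 = leiden_multiplex([LayerSpec(g, 1.0, 1.0), LayerSpec(two_triangles(), 0.0, 1.0)], seed=5)
        np.testing.assert_array_equal(p1.membership, p2.membership)

    def test_conflicting_layers_follow_dominant_weight(self):
        # expression: two 4-cliques {0-3}, {4-7}; spatial: conflicting pairing
        expr_edges = [(i, j) for i in range(4) for j in range(i + 1, 4)]
        expr_edges += [(i, j) for i in range(4, 8) for j in range(i + 1, 8)]
        expr = graph_from_edges(8, expr_edges)
        spat = graph_from_edges(8, [(0, 4), (1, 5), (2, 6), (3, 7), (0, 5), (1, 4), (2, 7), (3, 6)])
        for w, dominant in [(1e-3, expr), (1e3, spat)]:
            layers = [LayerSpec(expr, 1.0, 1.0), LayerSpec(spat, w, 1.0)]
            part = leiden_multiplex(layers, seed=1)
            single = [LayerSpec(dominant, 1.0, 1.0)]
            assert multiplex_quality(single, part) == pytest.approx(exhaustive_optimum(single))

    @pytest.mark.parametrize("seed", range(10))
    def test_never_exceeds_exhaustive_optimum(self, seed):
        layers = random_instance(seed + 1000)
        part = leiden_multiplex(layers, seed=seed)
        opt = exhaustive_optimum(layers)
        assert part.quality <= opt + 1e-9
        assert multiplex_quality(layers, part) == pytest.approx(part.quality, abs=1e-9)

    def test_quality_trace_monotone(self, small_graphs):
        latent_g, spatial_g = small_graphs
        part = leiden_multiplex(
            [LayerSpec(latent_g, 1.0, 1.0), LayerSpec(spatial_g, 2.0, 1.0)], seed=3
        )
        trace = part.meta["quality_trace"]
        assert all(b >= a - 1e-6 for a, b in zip(trace, trace[1:]))

    def test_seed_determinism(self, small_graphs):
        latent_g, _ = small_graphs
        p1 = leiden(latent_g, 1.0, seed=11)
        p2 = leiden(latent_g, 1.0, seed=11)
        np.testing.assert_array_equal(p1.membership, p2.membership)

    def test_weight_ratio_invariance(self, small_graphs):
        latent_g, spatial_g = small_graphs
        base = [LayerSpec(latent_g, 1.0, 0.8), LayerSpec(spatial_g, 2.0, 1.1)]
        scaled = [LayerSpec(latent_g, 4.0, 0.8), LayerSpec(spatial_g, 8.0, 1.1)]
        p1 = leiden_multiplex(base, seed=2)
        p2 = leiden_multiplex(scaled, seed=2)
        np.testing.assert_array_equal(p1.membership, p2.membership)
        assert p2.quality == pytest.approx(4 * p1.quality, rel=1e-9)

    def test_final_clusters_connected_in_union_graph(self, small_graphs):
        latent_g, spatial_g = small_graphs
        part = leiden_multiplex(
            [LayerSpec(latent_g, 1.0, 1.3), LayerSpec(spatial_g, 2.0, 0.7)], seed=9
        )
        union = latent_g.to_csr() + spatial_g.to_csr()
        for c in range(part.n_clusters):
            nodes = np.flatnonzero(part.membership == c)
            ncc, _ = connected_components(union[nodes][:, nodes], directed=False)
            assert ncc == 1


class TestSearchResolution:
    @staticmethod
    def _stub(threshold=0.5):
        def fn(res):
            k = 2 if res < threshold else 3
            return Partition(np.arange(6) % k)

        return fn

    def test_step_function_target_found(self):
        res, part = search_resolution(self._stub(), target_k=3, r_init=0.1, r_step=0.1)
        assert res >= 0.5 and part.n_clusters == 3

    def test_target_at_initial_resolution_returns_immediately(self):
        calls = []

        def fn(res):
            calls.append(res)
            return Partition(np.arange(6) % 3)

        res, part = search_resolution(fn, target_k=3, r_init=1.0)
        assert res == 1.0 and len(calls) == 1

    def test_downward_search_with_step_halving(self):
        res, part = search_resolution(self._stub(0.37), target_k=2, r_init=1.0, r_step=0.2)
        assert res < 0.37 and part.n_clusters == 2

    def test_invalid_target_rejected(self):
        with pytest.raises(ValidationError):
            search_resolution(self._stub(), target_k=0)


class TestSpatialLeiden:
    def test_zero_spatial_weight_reduces_to_nonspatial(self, small_graphs):
        latent_g, spatial_g = small_graphs
        part_s = spatial_leiden(latent_g, spatial_g, 0.0, target_k=4, seed=4)
        r, part_l = search_resolution(lambda r: leiden(latent_g, r, seed=4), 4)
        np.testing.assert_array_equal(part_s.membership, part_l.membership)
        assert part_s.meta["spatial_resolution"] is None

    def test_node_count_mismatch_rejected(self, small_graphs):
        latent_g, _ = small_graphs
        other = graph_from_edges(4, [(0, 1), (1, 2), (2, 3)])
        with pytest.raises(ValidationError):
            spatial_leiden(latent_g, other, 1.0, target_k=3, seed=0)

    def test_reaches_target_cluster_count(self, small_graphs):
        latent_g, spatial_g = small_graphs
        part = spatial_leiden(latent_g, spatial_g, 2.0, target_k=4, seed=0)
        assert part.n_clusters == 4
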