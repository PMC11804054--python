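"""Graph builders against brute-force geometric oracles."""

import numpy as np
import pytest

from spatialmux import (
    GeometryError,
    SpotCoordinates,
    Technology,
    ValidationError,
    WeightedGraph,
    build_delaunay_graph,
    build_grid_graph,
    build_knn_graph,
    build_latent_knn,
    distances_to_connectivities,
)


def knn_union_oracle(points: np.ndarray, k: int) -> set[tuple[int, int]]:
    """O(n^2) nearest-neighbor scan, union-symmetrized."""
    n = len(points)
    d = np.linalg.norm(points[:, None] - points[None, :], axis=2)
    np.fill_diagonal(d, np.inf)
    edges = set()
    for i in range(n):
        for j in np.argsort(d[i])[:k]:
            edges.add((min(i, int(j)), max(i, int(j))))
    return edges


def delaunay_edge_oracle(points: np.ndarray) -> set[tuple[int, int]]:
    """Edges of all triangles with an empty circumcircle (general position)."""
    n = len(points)
    edges = set()
    for i in range(n):
        for j in range(i + 1, n):
            for k in range(j + 1, n):
                a, b, c = points[i], points[j], points[k]
                d = 2 * (a[0] * (b[1] - c[1]) + b[0] * (c[1] - a[1]) + c[0] * (a[1] - b[1]))
                if abs(d) < 1e-12:
                    continue
                ux = ((a @ a) * (b[1] - c[1]) + (b @ b) * (c[1] - a[1]) + (c @ c) * (a[1] - b[1])) / d
                uy = ((a @ a) * (c[0] - b[0]) + (b @ b) * (a[0] - c[0]) + (c @ c) * (b[0] - a[0])) / d
                center = np.array([ux, uy])
                r = np.linalg.norm(a - center)
                dist = np.linalg.norm(points - center, axis=1)
                mask = np.ones(n, bool)
                mask[[i, j, k]] = False
                if (dist[mask] < r * (1 - 1e-9)).sum() == 0:
                    edges.update({(i, j), (j, k), (i, k)})
    return edges


def square_grid_coords(rows, cols, tech=Technology.SQUARE_GRID):
    pts = np.array([(c, r) for r in range(rows) for c in range(cols)], float)
    return SpotCoordinates([f"s{i}" for i in range(len(pts))], pts, tech)


def hex_grid_coords(rows, cols):
    pts = np.array(
        [(c + (0.5 if r % 2 else 0.0), r * np.sqrt(3) / 2) for r in range(rows) for c in range(cols)],
        float,
    )
    return SpotCoordinates([f"s{i}" for i in range(len(pts))], pts, Technology.HEX_GRID)


class TestGridGraph:
    def test_square_lattice_degrees(self):
        g = build_grid_graph(square_grid_coords(5, 5), "square")
        deg = g.degrees()
        center = 2 * 5 + 2  # row 2, col 2
        assert deg[center] == 4
        assert deg[0] == 2  # corner
        assert (g.weight == 1).all()

    def test_hex_lattice_interior_degree_six(self):
        g = build_grid_graph(hex_grid_coords(5, 5), "hex")
        deg = g.degrees()
        interior = 2 * 5 + 2
        assert deg[interior] == 6

    def test_single_spot_graph_is_empty(self):
        c = SpotCoordinates(["a"], np.array([[0.0, 0.0]]), Technology.SQUARE_GRID)
        assert build_grid_graph(c, "square").n_edges == 0

    def test_irregular_points_raise_geometry_error(self, rng):
        pts = rng.uniform(0, 10, size=(30, 2))
        c = SpotCoordinates([f"s{i}" for i in range(30)], pts, Technology.GENERIC)
        with pytest.raises(GeometryError):
            build_grid_graph(c, "square")

    def test_regularity_away_from_boundary(self):
        g = build_grid_graph(square_grid_coords(10, 10), "square")
        deg = g.degrees().reshape(10, 10)
        assert (deg[1:-1, 1:-1] == 4).all()


class TestKnnGraph:
    def test_two_points_single_edge_with_distance(self):
        g = build_knn_graph(np.array([[0.0, 0.0], [3.0, 4.0]]), k=1)
        assert g.n_edges == 1
        assert g.distance[0] == pytest.approx(5.0)

    def test_collinear_union_symmetrization(self):
        pts = np.array([[0.0, 0], [1, 0], [2, 0], [10, 0]])
        g = build_knn_graph(pts, k=1)
        assert g.edge_set() == {(0, 1), (1, 2), (2, 3)}

    def test_k_clipped_to_complete_graph(self):
        g = build_knn_graph(np.arange(10).reshape(5, 2).astype(float), k=10)
        assert g.n_edges == 5 * 4 // 2

    @pytest.mark.parametrize("seed,n,k", [(0, 50, 3), (1, 200, 5), (2, 500, 10)])
    def test_matches_brute_force_oracle(self, seed, n, k):
        pts = np.random.default_rng(seed).uniform(0, 100, size=(n, 2))
        g = build_knn_graph(pts, k=k)
        assert g.edge_set() == knn_union_oracle(pts, k)
        assert (g.degrees() >= min(k, n - 1)).all()


class TestDelaunayGraph:
    def test_triangle(self):
        g = build_delaunay_graph(np.array([[0.0, 0], [1, 0], [0, 1]]))
        assert g.n_edges == 3

    def test_unit_square_has_five_edges(self):
        g = build_delaunay_graph(np.array([[0.0, 0], [1, 0], [1, 1], [0, 1]]))
        assert g.n_edges == 5  # 4 sides + 1 diagonal

    def test_collinear_points_raise(self):
        with pytest.raises(GeometryError):
            build_delaunay_graph(np.array([[0.0, 0], [1, 0], [2, 0], [3, 0]]))

    def test_duplicate_points_named(self):
        with pytest.raises(GeometryError, match="duplicate"):
            build_delaunay_graph(np.array([[0.0, 0], [0, 0], [1, 1]]))

    @pytest.mark.parametrize("seed,n", [(3, 25), (4, 40), (5, 60)])
    def test_matches_empty_circumcircle_oracle(self, seed, n):
        pts = np.random.default_rng(seed).uniform(0, 10, size=(n, 2))
        g = build_delaunay_graph(pts)
        assert g.edge_set() == delaunay_edge_oracle(pts)


class TestDistancesToConnectivities:
    def test_printed_formula_and_zero_edge_removal(self):
        g = WeightedGraph(3, [0, 1], [1, 2], [1.0, 1.0], distance=[2.0, 8.0])
        t = distances_to_connectivities(g)
        assert t.n_edges == 1  # d = d_max edge dropped
        assert t.weight[0] == pytest.approx(1 - 2 / 8)

    def test_half_dmax_gives_half_weight(self):
        g = WeightedGraph(3, [0, 1], [1, 2], [1.0, 1.0], distance=[4.0, 8.0])
        t = distances_to_connectivities(g)
        assert t.weight[t.distance == 4.0][0] == pytest.approx(0.5)

    def test_all_equal_distances_degenerate(self):
        g = WeightedGraph(3, [0, 1], [1, 2], [1.0, 1.0], distance=[5.0, 5.0])
        with pytest.raises(ValidationError, match="degenerate"):
            distances_to_connectivities(g)

    def test_scale_invariance(self, rng):
        pts = rng.uniform(0, 1, size=(40, 2))
        g1 = distances_to_connectivities(build_knn_graph(pts, 4))
        g2 = distances_to_connectivities(build_knn_graph(pts * 37.5, 4))
        assert g1.edge_set() == g2.edge_set()
        np.testing.assert_allclose(np.sort(g1.weight), np.sort(g2.weight), atol=1e-12)


class TestLatentKnn:
    def test_identical_vectors_weight_one(self):
        g = build_latent_knn(np.zeros((6, 3)), k=2)
        assert (g.weight == 1.0).all()

    def test_separated_blobs_have_no_cross_edges(self, rng):
        blob1 = rng.normal(0, 0.1, size=(30, 2))
        blob2 = rng.normal(50, 0.1, size=(30, 2))
        g = build_latent_knn(np.vstack([blob1, blob2]), k=5)
        assert not any(u < 30 <= v for u, v in g.edge_set())

    def test_permutation_equivariance(self, rng):
        latent = rng.normal(size=(40, 5))
        perm = rng.permutation(40)
        g = build_latent_knn(latent, k=4)
        gp = build_latent_knn(latent[perm], k=4)
        inv = np.empty(40, dtype=int)
        inv[perm] = np.arange(40)
        assert gp.edge_set() == {(min(inv[u], inv[v]), max(inv[u], inv[v])) for u, v in g.edge_set()}

    def test_nan_latent_rejected(self):
        with pytest.raises(ValidationError):
            build_latent_knn(np.array([[0.0, np.nan], [1, 1]]), k=1)

    def test_weights_in_unit_interval(self, rng):
        g = build_latent_knn(rng.normal(size=(100, 10)), k=8)
        assert (g.weight > 0).all() and (g.weight <= 1).all()


def test_builders_permutation_equivariant(rng):
    pts = rng.uniform(0, 10, size=(60, 2))
    perm = rng.permutation(60)
    inv = np.empty(60, dtype=int)
    inv[perm] = np.arange(60)
    for builder in (lambda p: build_knn_graph(p, 4), build_delaunay_graph):
        g = builder(pts)
        gp = builder(pts[perm])
        assert gp.edge_set() == {(min(inv[u], inv[v]), max(inv[u], inv[v])) for u, v in g.edge_set()}
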