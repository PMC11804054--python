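"""Neighbor-graph construction over spots.

Two kinds of graphs drive the clustering: a *spatial* graph over physical
coordinates (regular grid adjacency, Delaunay triangulation, or kNN) and a
*latent* kNN graph over the dimensionality-reduced expression space.  Both
are undirected weighted graphs on the same node set.

Distance-carrying graphs (Delaunay/kNN) are converted to connectivities with
``w = 1 - d / d_max`` where ``d_max`` is the largest edge distance in the
graph; grid graphs use unit weights since all neighbors are equidistant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
import numpy as np
from scipy import sparse
from scipy.spatial import Delaunay, QhullError, cKDTree

from .data_model import SpotCoordinates, ValidationError

logger = logging.getLogger(__name__)

#: relative tolerance (of the lattice spacing) for snapping grid coordinates
GRID_TOL = 1e-3


class GeometryError(ValueError):
    """Raised when coordinates are incompatible with the requested geometry."""


@dataclass
class WeightedGraph:
    """Undirected weighted graph over spots.

    Edges are stored once with ``u < v``; ``weight`` is the connectivity used
    by clustering and autocorrelation, ``distance`` (optional) the raw
    Euclidean edge length it was derived from.
    """

    n_nodes: int
    u: np.ndarray
    v: np.ndarray
    weight: np.ndarray
    distance: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=np.int64)
        self.v = np.asarray(self.v, dtype=np.int64)
        self.weight = np.asarray(self.weight, dtype=float)
        if self.distance is not None:
            self.distance = np.asarray(self.distance, dtype=float)
        # canonicalize orientation u < v
        flip = self.u > self.v
        if flip.any():
            self.u[flip], self.v[flip] = self.v[flip].copy(), self.u[flip].copy()
        if (self.u == self.v).any():
            raise ValidationError("self-loops are not allowed")
        if self.weight.size and self.weight.min() <= 0:
            raise ValidationError("edge weights must be > 0")
        if self.u.size and (self.u.min() < 0 or self.v.max() >= self.n_nodes):
            raise ValidationError("edge endpoint out of range")
        if len({(a, b) for a, b in zip(self.u, self.v)}) != self.u.size:
            raise ValidationError("duplicate edges")

    @property
    def n_edges(self) -> int:
        return int(self.u.size)

    def edge_set(self) -> set[tuple[int, int]]:
        return {(int(a), int(b)) for a, b in zip(self.u, self.v)}

    def to_csr(self, attr: str = "weight") -> sparse.csr_matrix:
        """Symmetric CSR adjacency carrying ``weight`` or ``distance``."""
        vals = self.weight if attr == "weight" else self.distance
        if vals is None:
            raise ValidationError(f"graph has no '{attr}' attribute")
        rows = np.concatenate([self.u, self.v])
        cols = np.concatenate([self.v, self.u])
        data = np.concatenate([vals, vals])
        return sparse.csr_matrix((data, (rows, cols)), shape=(self.n_nodes, self.n_nodes))

    def degrees(self) -> np.ndarray:
        """Unweighted degree per node."""
        d = np.zeros(self.n_nodes, dtype=int)
        np.add.at(d, self.u, 1)
        np.add.at(d, self.v, 1)
        return d

    def row_normalized(self) -> sparse.csr_matrix:
        """Row-normalized weight matrix W (rows of isolated nodes stay zero)."""
        A = self.to_csr()
        rs = np.asarray(A.sum(axis=1)).ravel()
        inv = np.divide(1.0, rs, out=np.zeros_like(rs), where=rs > 0)
        return sparse.diags(inv) @ A

    def permuted(self, perm: np.ndarray) -> "WeightedGraph":
        """Relabel node i as perm[i]."""
        perm = np.asarray(perm)
        return WeightedGraph(self.n_nodes, perm[self.u], perm[self.v],
                             self.weight.copy(),
                             None if self.distance is None else self.distance.copy())

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            cols = "u\tv\tweight" + ("\tdistance" if self.distance is not None else "")
            fh.write(cols + "\n")
            for i in range(self.n_edges):
                row = f"{self.u[i]}\t{self.v[i]}\t{self.weight[i]:.10g}"
                if self.distance is not None:
                    row += f"\t{self.distance[i]:.10g}"
                fh.write(row + "\n")

    @classmethod
    def read_tsv(cls, path: str | Path, n_nodes: int | None = None) -> "WeightedGraph":
        import pandas as pd

        df = pd.read_csv(path, sep="\t")
        n = n_nodes if n_nodes is not None else (int(max(df["u"].max(), df["v"].max())) + 1 if len(df) else 0)
        dist = df["distance"].to_numpy() if "distance" in df.columns else None
        return cls(n, df["u"].to_numpy(), df["v"].to_numpy(), df["weight"].to_numpy(), dist)


def _dedupe_edges(n: int, u: np.ndarray, v: np.ndarray, dist: np.ndarray) -> WeightedGraph:
    # duplicate points make a node its own "nearest neighbor"; drop such pairs
    keep = u != v
    u, v, dist = u[keep], v[keep], dist[keep]
    lo, hi = np.minimum(u, v), np.maximum(u, v)
    key = lo * n + hi
    _, idx = np.unique(key, return_index=True)
    return WeightedGraph(n, lo[idx], hi[idx], np.ones(idx.size), dist[idx])


def build_grid_graph(coords: SpotCoordinates, grid_type: str) -> WeightedGraph:
    """Adjacency on a regular lattice: 6 neighbors (hex) or 4 (square).

    Neighbors are pairs at the lattice spacing (the median nearest-neighbor
    distance), within a relative tolerance of ``GRID_TOL``.  All edges get
    unit weight because lattice neighbors are equidistant.
    """
    if grid_type not in ("hex", "square"):
        raise ValidationError(f"grid_type must be 'hex' or 'square', got {grid_type!r}")
    n = coords.n_spots
    if n < 2:
        return WeightedGraph(n, np.empty(0, int), np.empty(0, int), np.empty(0))
    pts = coords.xy
    tree = cKDTree(pts)
    nn_d, _ = tree.query(pts, k=2)
    spacing = float(np.median(nn_d[:, 1]))
    if spacing == 0:
        raise GeometryError("duplicate coordinates; cannot resolve lattice spacing")
    lo, hi = spacing * (1 - GRID_TOL), spacing * (1 + GRID_TOL)
    if (nn_d[:, 1] < lo).any() or (nn_d[:, 1] > hi).any():
        raise GeometryError("coordinates do not lie on a regular lattice within tolerance")
    pairs = tree.query_pairs(r=hi, output_type="ndarray")
    if pairs.size == 0:
        return WeightedGraph(n, np.empty(0, int), np.empty(0, int), np.empty(0))
    d = np.linalg.norm(pts[pairs[:, 0]] - pts[pairs[:, 1]], axis=1)
    keep = d >= lo
    pairs = pairs[keep]
    g = WeightedGraph(n, pairs[:, 0], pairs[:, 1], np.ones(pairs.shape[0]))
    max_deg = 6 if grid_type == "hex" else 4
    deg = g.degrees()
    if deg.max(initial=0) > max_deg:
        raise GeometryError(
            f"node degree {int(deg.max())} exceeds {max_deg}; coordinates are not a {grid_type} lattice"
        )
    return g


def build_knn_graph(points: np.ndarray, k: int) -> WeightedGraph:
    """kNN by Euclidean distance, symmetrized by union; carries distances."""
    points = np.asarray(points, dtype=float)
    n = points.shape[0]
    if n < 2:
        raise ValidationError("need at least 2 points for a kNN graph")
    if k < 1:
        raise ValidationError("k must be >= 1")
    if k >= n:
        logger.warning("k=%d >= n=%d; clipping to %d", k, n, n - 1)
        k = n - 1
    tree = cKDTree(points)
    d, idx = tree.query(points, k=k + 1)
    src = np.repeat(np.arange(n), k)
    dst = idx[:, 1:].ravel()
    dist = d[:, 1:].ravel()
    return _with_distances(_dedupe_edges(n, src, dst, dist), points)


def build_delaunay_graph(points: np.ndarray) -> WeightedGraph:
    """Delaunay triangulation edges with Euclidean distances."""
    points = np.asarray(points, dtype=float)
    n = points.shape[0]
    if n < 3:
        raise GeometryError("Delaunay triangulation needs at least 3 points")
    uniq, counts = np.unique(np.round(points, 12), axis=0, return_counts=True)
    if (counts > 1).any():
        dups = uniq[counts > 1][:5].tolist()
        raise GeometryError(f"duplicate points: {dups}")
    try:
        tri = Delaunay(points)
    except QhullError as e:
        raise GeometryError(f"degenerate point set (collinear?): {e}") from e
    edges = set()
    for simplex in tri.simplices:
        for a in range(3):
            for b in range(a + 1, 3):
                i, j = int(simplex[a]), int(simplex[b])
                edges.add((min(i, j), max(i, j)))
    uu = np.array([e[0] for e in sorted(edges)], dtype=int)
    vv = np.array([e[1] for e in sorted(edges)], dtype=int)
    g = WeightedGraph(n, uu, vv, np.ones(uu.size))
    return _with_distances(g, points)


def _with_distances(g: WeightedGraph, points: np.ndarray) -> WeightedGraph:
    d = np.linalg.norm(points[g.u] - points[g.v], axis=1)
    return WeightedGraph(g.n_nodes, g.u, g.v, g.weight, d)


def distances_to_connectivities(g: WeightedGraph) -> WeightedGraph:
    """Transform edge distances to weights ``1 - d / d_max``.

    ``d_max`` is the global maximum edge distance; edges reaching weight 0
    (``d = d_max``) are removed, so weights lie in (0, 1].
    """
    if g.distance is None:
        raise ValidationError("graph carries no distances")
    if g.n_edges == 0:
        raise ValidationError("graph has no edges")
    d_max = float(g.distance.max())
    if d_max == 0:
        raise ValidationError("degenerate transform: all edge distances are zero")
    w = 1.0 - g.distance / d_max
    keep = w > 0
    if not keep.any():
        raise ValidationError(
            "degenerate transform: all edges at d_max; use unit weights instead"
        )
    return WeightedGraph(g.n_nodes, g.u[keep], g.v[keep], w[keep], g.distance[keep])


def build_spatial_graph(coords: SpotCoordinates, mode: str, k: int = 10) -> WeightedGraph:
    """Dispatch: grid adjacency (unit weights) or Delaunay/kNN with the
    ``1 - d/d_max`` connectivity transform."""
    if mode == "grid":
        grid_type = "hex" if coords.technology.value == "hex_grid" else "square"
        return build_grid_graph(coords, grid_type)
    if mode == "delaunay":
        return distances_to_connectivities(build_delaunay_graph(coords.xy))
    if mode == "knn":
        return distances_to_connectivities(build_knn_graph(coords.xy, k))
    raise ValidationError(f"unknown spatial graph mode {mode!r}")


def build_latent_knn(latent: np.ndarray, k: int = 15, kernel: str = "local_gaussian") -> WeightedGraph:
    """kNN graph in latent expression space with a local-scaling kernel.

    Edge weights are ``exp(-d^2 / (sigma_i * sigma_j))`` where ``sigma_i`` is
    node i's distance to its k-th neighbor (so weights adapt to local
    density); ``kernel='binary'`` uses unit weights instead.
    """
    latent = np.asarray(latent, dtype=float)
    if latent.ndim == 1:
        latent = latent[:, None]
    if not np.all(np.isfinite(latent)):
        raise ValidationError("NaN/inf in latent vectors")
    n = latent.shape[0]
    if n < 2:
        raise ValidationError("need at least 2 spots")
    if k >= n:
        logger.warning("latent k=%d >= n=%d; clipping", k, n)
        k = n - 1
    tree = cKDTree(latent)
    d, idx = tree.query(latent, k=k + 1)
    sigma = d[:, -1].copy()  # distance to the k-th neighbor
    src = np.repeat(np.arange(n), k)
    dst = idx[:, 1:].ravel()
    dist = d[:, 1:].ravel()
    g = _dedupe_edges(n, src, dst, dist)
    gd = np.linalg.norm(latent[g.u] - latent[g.v], axis=1)
    if kernel == "binary":
        w = np.ones(g.n_edges)
    elif kernel == "local_gaussian":
        denom = sigma[g.u] * sigma[g.v]
        w = np.where(gd == 0, 1.0, np.exp(-gd**2 / np.maximum(denom, 1e-300)))
        w = np.maximum(w, 1e-12)  # keep strictly positive weights
    else:
        raise ValidationError(f"unknown latent kernel {kernel!r}")
    return WeightedGraph(n, g.u, g.v, w, gd)
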