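"""Multiplex Leiden community detection with per-layer RB-configuration quality.

One partition of a shared node set is optimized jointly over several graph
layers.  Each layer l carries a weight w_l and a resolution gamma_l and
contributes the (unnormalized) Reichardt-Bornholdt configuration quality

    Q_l(gamma) = sum_ij (A_ij - gamma * k_i k_j / (2m)) * delta(c_i, c_j)

over ordered node pairs, with k the weighted degree and 2m the total degree.
The combined objective is Q_total = sum_l w_l Q_l(gamma_l); only the ratio
of layer weights matters for the argmax.

The optimizer follows the Leiden scheme: seeded queue-based local moving,
refinement restricted to the current communities, and simultaneous
aggregation of all layers, repeated until a pass no longer improves
Q_total.  Quality is non-decreasing across sweeps and passes (asserted).

For spatial omics the two layers are the latent gene-expression kNN graph
(weight fixed at 1) and the physical-space neighbor graph; resolutions are
tuned by a bracketing search to reach a target number of clusters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from numba import njit
from scipy import sparse
from scipy.sparse.csgraph import connected_components

from .data_model import ValidationError
from .neighbor_graphs import WeightedGraph

logger = logging.getLogger(__name__)

_EPS = 1e-12


@dataclass
class LayerSpec:
    """One clustering layer: a graph plus its layer weight and resolution."""

    graph: WeightedGraph
    layer_weight: float = 1.0
    resolution: float = 1.0

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ValidationError("resolution must be positive")


@dataclass
class Partition:
    """Node -> cluster assignment with contiguous 0-based cluster ids."""

    membership: np.ndarray
    quality: float = float("nan")
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.membership = np.asarray(self.membership, dtype=np.int64)
        ids = np.unique(self.membership)
        if ids.size and (ids[0] != 0 or ids[-1] != ids.size - 1):
            raise ValidationError("cluster ids must be contiguous 0-based")

    @property
    def n_clusters(self) -> int:
        return int(self.membership.max()) + 1 if self.membership.size else 0

    @property
    def n_nodes(self) -> int:
        return int(self.membership.size)


def relabel_by_first_occurrence(membership: np.ndarray) -> np.ndarray:
    """Map arbitrary labels to contiguous 0-based ids in order of appearance."""
    out = np.empty(membership.size, dtype=np.int64)
    lut: dict[int, int] = {}
    for i, c in enumerate(membership):
        c = int(c)
        if c not in lut:
            lut[c] = len(lut)
        out[i] = lut[c]
    return out


# ---------------------------------------------------------------------------
# quality
# ---------------------------------------------------------------------------

class _Layer:
    """Internal CSR layer with cached degrees; diagonal entries represent
    collapsed within-cluster weight (ordered-pair convention, so the total
    matrix sum is invariant under aggregation)."""

    __slots__ = ("A", "k", "two_m", "gamma", "w", "indptr", "indices", "data")

    def __init__(self, A: sparse.csr_matrix, gamma: float, w: float):
        self.A = A
        self.k = np.asarray(A.sum(axis=1)).ravel()
        self.two_m = float(self.k.sum())
        self.gamma = gamma
        self.w = w
        self.indptr = A.indptr
        self.indices = A.indices
        self.data = A.data


def _layer_quality(layer: _Layer, membership: np.ndarray) -> float:
    A = layer.A.tocoo()
    same = membership[A.row] == membership[A.col]
    in_sum = float(A.data[same].sum())
    d = np.bincount(membership, weights=layer.k, minlength=int(membership.max()) + 1)
    return in_sum - layer.gamma * float(d @ d) / layer.two_m


def _make_layers(layers: Sequence[LayerSpec]) -> tuple[list[_Layer], int]:
    if not layers:
        raise ValidationError("at least one layer required")
    n = layers[0].graph.n_nodes
    for spec in layers:
        if spec.graph.n_nodes != n:
            raise ValidationError("all layers must share the same node set")
    if all(spec.layer_weight == 0 for spec in layers):
        raise ValidationError("at least one layer must have nonzero weight")
    out = []
    for spec in layers:
        if spec.layer_weight == 0:
            continue  # contributes nothing to Q_total
        if spec.graph.n_edges == 0:
            raise ValidationError("layer graph has no edges")
        out.append(_Layer(spec.graph.to_csr(), spec.resolution, spec.layer_weight))
    return out, n


def rb_quality(g: WeightedGraph, part: Partition, gamma: float) -> float:
    """Unnormalized RB-configuration quality of a partition on one graph.

    With gamma = 1 this is (unnormalized) Newman-Girvan modularity.
    """
    if g.n_edges == 0:
        raise ValidationError("empty graph")
    if part.n_nodes != g.n_nodes:
        raise ValidationError("partition does not cover the graph's nodes")
    return _layer_quality(_Layer(g.to_csr(), gamma, 1.0), part.membership)


def multiplex_quality(layers: Sequence[LayerSpec], part: Partition) -> float:
    """Weighted sum of per-layer RB qualities, sum_l w_l Q_l(gamma_l)."""
    n = layers[0].graph.n_nodes
    for spec in layers:
        if spec.graph.n_nodes != n:
            raise ValidationError("layer node counts differ")
    if part.n_nodes != n:
        raise ValidationError("partition does not cover the layers' nodes")
    total = 0.0
    for spec in layers:
        if spec.layer_weight == 0:
            continue
        total += spec.layer_weight * rb_quality(spec.graph, part, spec.resolution)
    return total


# ---------------------------------------------------------------------------
# optimizer
# ---------------------------------------------------------------------------

def _quality(layers: list[_Layer], membership: np.ndarray) -> float:
    return sum(l.w * _layer_quality(l, membership) for l in layers)


def _pack(layers: list[_Layer]) -> tuple:
    """Concatenate the layers' CSR arrays for the compiled kernels."""
    L = len(layers)
    n = layers[0].A.shape[0]
    indptr = np.empty((L, n + 1), dtype=np.int64)
    chunks_idx, chunks_dat = [], []
    offset = 0
    for li, l in enumerate(layers):
        indptr[li] = l.indptr.astype(np.int64) + offset
        chunks_idx.append(l.indices.astype(np.int64))
        chunks_dat.append(l.data.astype(np.float64))
        offset += l.indices.size
    indices = np.concatenate(chunks_idx) if chunks_idx else np.empty(0, np.int64)
    data = np.concatenate(chunks_dat) if chunks_dat else np.empty(0, np.float64)
    k2d = np.stack([l.k for l in layers]).astype(np.float64)
    wl = np.array([l.w for l in layers], dtype=np.float64)
    gl = np.array([l.gamma for l in layers], dtype=np.float64)
    tml = np.array([l.two_m for l in layers], dtype=np.float64)
    return indptr, indices, data, k2d, wl, gl, tml


@njit(cache=True)
def _local_move_kernel(n, L, indptr, indices, data, k2d, wl, gl, tml,
                       membership, order, D, comm_size, empty_stack, n_empty):
    """Queue-based local moving over all layers; mutates membership/D in place.

    For node i the gain of joining community c is
    sum_l w_l * (2*lw_l(i,c) - 2*gamma_l*k_il*D_l[c]/(2m_l)); ties prefer
    the current community, then the lowest community id; a fresh (empty)
    community is taken when every occupied choice has negative gain.
    """
    EPS = 1e-12
    cap = n + 1
    queue = np.empty(cap, np.int64)
    in_q = np.zeros(n, np.bool_)
    head, tail = 0, 0
    for idx in range(n):
        queue[tail] = order[idx]
        tail = (tail + 1) % cap
        in_q[order[idx]] = True
    S = D.shape[1]
    gains = np.zeros(S, np.float64)
    mark = np.full(S, -1, np.int64)
    touched = np.empty(S, np.int64)
    moved_any = False
    stamp = -1
    while head != tail:
        i = queue[head]
        head = (head + 1) % cap
        in_q[i] = False
        stamp += 1
        a = membership[i]
        for l in range(L):
            D[l, a] -= k2d[l, i]
        comm_size[a] -= 1
        if comm_size[a] == 0:
            empty_stack[n_empty] = a
            n_empty += 1
        ntouch = 0
        for l in range(L):
            coef = 2.0 * wl[l]
            for p in range(indptr[l, i], indptr[l, i + 1]):
                j = indices[p]
                if j == i:
                    continue  # self-loop contributes equally to every choice
                c = membership[j]
                if mark[c] != stamp:
                    mark[c] = stamp
                    gains[c] = 0.0
                    touched[ntouch] = c
                    ntouch += 1
                gains[c] += coef * data[p]
        if mark[a] != stamp:
            mark[a] = stamp
            gains[a] = 0.0
        best_c = a
        best_gain = gains[a]
        for l in range(L):
            best_gain -= 2.0 * wl[l] * gl[l] * k2d[l, i] * D[l, a] / tml[l]
        for c in np.sort(touched[:ntouch]):
            if c == a:
                continue
            g = gains[c]
            for l in range(L):
                g -= 2.0 * wl[l] * gl[l] * k2d[l, i] * D[l, c] / tml[l]
            if g > best_gain + EPS:
                best_c, best_gain = c, g
        if 0.0 > best_gain + EPS and n_empty > 0:
            best_c = empty_stack[n_empty - 1]
        if n_empty > 0 and best_c == empty_stack[n_empty - 1]:
            n_empty -= 1
        membership[i] = best_c
        for l in range(L):
            D[l, best_c] += k2d[l, i]
        comm_size[best_c] += 1
        if best_c != a:
            moved_any = True
            for l in range(L):
                for p in range(indptr[l, i], indptr[l, i + 1]):
                    j = indices[p]
                    if membership[j] != best_c and not in_q[j]:
                        in_q[j] = True
                        queue[tail] = j
                        tail = (tail + 1) % cap
    return moved_any


def _local_move(layers: list[_Layer], membership: np.ndarray, rng: np.random.Generator) -> bool:
    """Seeded queue-based local moving (Leiden's fast local move)."""
    n = membership.size
    S = n + 1  # at most n occupied communities plus one spare
    D = np.zeros((len(layers), S), dtype=np.float64)
    for li, l in enumerate(layers):
        counts = np.bincount(membership, weights=l.k)
        D[li, : counts.size] = counts
    comm_size = np.zeros(S, dtype=np.int64)
    sizes = np.bincount(membership)
    comm_size[: sizes.size] = sizes
    empty_stack = np.empty(S, dtype=np.int64)
    free = np.flatnonzero(comm_size == 0)
    empty_stack[: free.size] = free
    indptr, indices, data, k2d, wl, gl, tml = _pack(layers)
    return bool(
        _local_move_kernel(
            n, len(layers), indptr, indices, data, k2d, wl, gl, tml,
            membership, rng.permutation(n), D, comm_size, empty_stack, free.size,
        )
    )


@njit(cache=True)
def _refine_kernel(n, L, indptr, indices, data, k2d, wl, gl, tml,
                   membership, order, rand_vals, refined, size, D):
    """Randomized refinement: singleton nodes merge into an adjacent refined
    community of the same coarse community, chosen uniformly among the
    strictly improving candidates."""
    EPS = 1e-12
    gains = np.zeros(n, np.float64)
    mark = np.full(n, -1, np.int64)
    touched = np.empty(n, np.int64)
    improving = np.empty(n, np.int64)
    for t in range(n):
        i = order[t]
        r_self = refined[i]
        if size[r_self] > 1:
            continue
        ntouch = 0
        for l in range(L):
            coef = 2.0 * wl[l]
            for p in range(indptr[l, i], indptr[l, i + 1]):
                j = indices[p]
                if j == i or membership[j] != membership[i]:
                    continue
                r = refined[j]
                if r == r_self:
                    continue
                if mark[r] != t:
                    mark[r] = t
                    gains[r] = 0.0
                    touched[ntouch] = r
                    ntouch += 1
                gains[r] += coef * data[p]
        n_improving = 0
        for r in np.sort(touched[:ntouch]):
            g = gains[r]
            for l in range(L):
                g -= 2.0 * wl[l] * gl[l] * k2d[l, i] * D[l, r] / tml[l]
            if g > EPS:
                improving[n_improving] = r
                n_improving += 1
        if n_improving > 0:
            best_r = improving[int(rand_vals[t] * n_improving)]
            for l in range(L):
                D[l, best_r] += k2d[l, i]
                D[l, r_self] -= k2d[l, i]
            size[best_r] += size[r_self]
            size[r_self] = 0
            refined[i] = best_r


def _refine(layers: list[_Layer], membership: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Refinement phase: re-cluster inside each community by randomized merges.

    Starts from singletons; a node still alone in its refined community may
    merge into an adjacent refined community of the *same* coarse community
    when that strictly increases Q_total, choosing uniformly at random among
    the improving candidates (the randomization lets later aggregation
    passes escape greedy local optima).  Every refined community stays
    connected within its coarse community.
    """
    n = membership.size
    refined = np.arange(n, dtype=np.int64)
    size = np.ones(n, dtype=np.int64)
    D = np.stack([l.k.astype(np.float64) for l in layers])
    indptr, indices, data, k2d, wl, gl, tml = _pack(layers)
    _refine_kernel(
        n, len(layers), indptr, indices, data, k2d, wl, gl, tml,
        membership, rng.permutation(n), rng.random(n), refined, size, D,
    )
    return relabel_by_first_occurrence(refined)


def _aggregate(layers: list[_Layer], refined: np.ndarray) -> list[_Layer]:
    n_ref = int(refined.max()) + 1
    S = sparse.csr_matrix(
        (np.ones(refined.size), (np.arange(refined.size), refined)), shape=(refined.size, n_ref)
    )
    return [_Layer(sparse.csr_matrix(S.T @ l.A @ S), l.gamma, l.w) for l in layers]


def _split_disconnected(layers: list[_Layer], membership: np.ndarray) -> np.ndarray:
    """Split communities that are disconnected in the union of the layers.

    Under non-negative layer weights and positive resolutions this never
    decreases Q_total (the in-community term is unchanged and the null term
    shrinks).
    """
    union = layers[0].A.copy()
    for l in layers[1:]:
        union = union + l.A
    union = sparse.csr_matrix(union)
    out = membership.copy()
    next_id = int(membership.max()) + 1
    for c in np.unique(membership):
        nodes = np.flatnonzero(membership == c)
        if nodes.size == 1:
            continue
        sub = union[nodes][:, nodes]
        n_cc, cc = connected_components(sub, directed=False)
        if n_cc > 1:
            for comp in range(1, n_cc):
                out[nodes[cc == comp]] = next_id
                next_id += 1
    return relabel_by_first_occurrence(out)


def _one_pass(flat_layers: list[_Layer], flat_membership: np.ndarray,
              rng: np.random.Generator, tol: float) -> np.ndarray:
    """One full Leiden cycle from the flat graph: local move, refinement and
    aggregation repeated down the hierarchy until aggregation stabilizes."""
    work = flat_layers
    n = flat_membership.size
    node_of = np.arange(n, dtype=np.int64)  # original node -> current super-node
    membership = flat_membership.copy()
    while True:
        _local_move(work, membership, rng)
        membership = relabel_by_first_occurrence(membership)
        refined = _refine(work, membership, rng)
        n_ref = int(refined.max()) + 1
        if n_ref == membership.size:
            break  # no merges: aggregation would be the identity
        # seed the aggregate with the pre-refinement communities
        agg_membership = np.empty(n_ref, dtype=np.int64)
        agg_membership[refined] = membership
        work = _aggregate(work, refined)
        node_of = refined[node_of]
        membership = agg_membership
    return relabel_by_first_occurrence(membership[node_of])


def leiden_multiplex(
    layers: Sequence[LayerSpec],
    seed: int = 0,
    max_passes: int = 100,
    n_restarts: int = 3,
) -> Partition:
    """Optimize one partition over all layers with the Leiden procedure.

    Each pass runs local moving, randomized refinement and simultaneous
    aggregation of all layers down the hierarchy, then restarts from the
    flat graph with the resulting membership; passes repeat until three in
    a row bring no quality increase (fresh refinement randomization can
    escape local optima even when a single pass stalls).  The whole
    procedure is run ``n_restarts`` times with seeds derived from ``seed``
    and the best-quality partition is returned (the heuristic is seed
    sensitive on small or ambiguous graphs); the result is deterministic
    given ``seed``.  ``meta`` records the pass count and the monotone
    quality trace of the winning run, and the final communities are
    connected in the union of the nonzero-weight layers.
    """
    if n_restarts < 1:
        raise ValidationError("n_restarts must be >= 1")
    best: Partition | None = None
    for r in range(n_restarts):
        part = _leiden_multiplex_once(layers, (seed + r * 10007) % (2**31), max_passes)
        if best is None or part.quality > best.quality + _EPS:
            best = part
    assert best is not None
    return best


def _leiden_multiplex_once(
    layers: Sequence[LayerSpec],
    seed: int,
    max_passes: int,
) -> Partition:
    work, n = _make_layers(layers)
    rng = np.random.default_rng(seed)
    membership = np.arange(n, dtype=np.int64)
    scale = max(sum(abs(l.w) * l.two_m for l in work), 1.0)
    tol = 1e-10 * scale
    q_prev = _quality(work, membership)
    trace = [q_prev]
    passes = 0
    stall = 0
    while passes < max_passes and stall < 3:
        passes += 1
        membership = _one_pass(work, membership, rng, tol)
        q_now = _quality(work, membership)
        assert q_now >= q_prev - tol, "quality decreased during a pass"
        trace.append(q_now)
        stall = 0 if q_now > q_prev + tol else stall + 1
        q_prev = q_now
    if passes >= max_passes and stall < 3:
        logger.warning("max_passes=%d reached before convergence", max_passes)

    flat = membership
    if all(l.w >= 0 and l.gamma > 0 for l in work):
        flat2 = _split_disconnected(work, flat)
        q2 = _quality(work, flat2)
        assert q2 >= q_prev - tol, "connectivity split decreased quality"
        flat, q_prev = flat2, q2
    flat = relabel_by_first_occurrence(flat)
    return Partition(flat, q_prev, {"passes": passes, "quality_trace": trace})


def leiden(g: WeightedGraph, resolution: float = 1.0, seed: int = 0) -> Partition:
    """Non-spatial (single-layer) Leiden clustering."""
    return leiden_multiplex([LayerSpec(g, 1.0, resolution)], seed=seed)


# ---------------------------------------------------------------------------
# resolution search
# ---------------------------------------------------------------------------

def search_resolution(
    cluster_fn: Callable[[float], Partition],
    target_k: int,
    r_init: float = 1.0,
    r_step: float = 0.1,
    max_iter: int = 40,
) -> tuple[float, Partition]:
    """Bracketing search for a resolution that yields ``target_k`` clusters.

    Increases the resolution while too few clusters are found, decreases it
    while too many; each direction flip halves the step.  Returns the first
    resolution hitting the target, else the closest one found (with a
    warning).  ``cluster_fn`` must be deterministic in the resolution (fix
    the seed inside).
    """
    if target_k < 1:
        raise ValidationError("target_k must be >= 1")
    res = float(r_init)
    step = float(r_step)
    last_dir = 0
    best: tuple[int, float, Partition] | None = None
    for _ in range(max_iter):
        part = cluster_fn(res)
        k = part.n_clusters
        if best is None or abs(k - target_k) < best[0]:
            best = (abs(k - target_k), res, part)
        if k == target_k:
            return res, part
        direction = 1 if k < target_k else -1
        if last_dir != 0 and direction != last_dir:
            step /= 2.0
        last_dir = direction
        res = res + direction * step
        if res <= 0:
            logger.warning("resolution reached non-positive value; clamped to 1e-4")
            res = 1e-4
    assert best is not None
    logger.warning(
        "resolution search did not reach k=%d in %d iterations; closest k=%d at r=%.4g",
        target_k, max_iter, best[2].n_clusters, best[1],
    )
    return best[1], best[2]


def balanced_spatial_weight(latent_graph: WeightedGraph, spatial_graph: WeightedGraph) -> float:
    """Spatial-layer weight that equalizes the two layers' total edge mass.

    Per-layer quality is unnormalized, so a layer's influence scales with
    its total edge weight; this returns sum(latent weights) / sum(spatial
    weights), the multiplier under which both layers contribute comparable
    quality mass.  A good grid default when no technology-specific weight
    has been tuned.
    """
    denom = float(spatial_graph.weight.sum())
    if denom == 0:
        raise ValidationError("spatial graph has no edge weight")
    return float(latent_graph.weight.sum()) / denom


def spatial_leiden(
    latent_graph: WeightedGraph,
    spatial_graph: WeightedGraph,
    spatial_weight: float = 1.0,
    target_k: int = 4,
    seed: int = 0,
    r_init: float = 1.0,
    r_step: float = 0.1,
    max_iter: int = 40,
) -> Partition:
    """Two-stage spatially aware clustering.

    Stage (a) tunes the latent layer's resolution with non-spatial Leiden to
    reach ``target_k`` clusters; stage (b) freezes that resolution and layer
    weights (1, ``spatial_weight``) and tunes the spatial layer's resolution
    so the multiplex clustering reaches ``target_k``.  ``spatial_weight = 0``
    reduces exactly to the stage-(a) result.
    """
    if latent_graph.n_nodes != spatial_graph.n_nodes:
        raise ValidationError("latent and spatial graphs must share the node set")
    if spatial_weight < 0:
        raise ValidationError("spatial_weight must be >= 0")
    r_latent, part_a = search_resolution(
        lambda r: leiden_multiplex([LayerSpec(latent_graph, 1.0, r)], seed=seed),
        target_k, r_init=r_init, r_step=r_step, max_iter=max_iter,
    )
    if spatial_weight == 0:
        part_a.meta.update({"latent_resolution": r_latent, "spatial_resolution": None})
        return part_a
    r_spatial, part_b = search_resolution(
        lambda r: leiden_multiplex(
            [LayerSpec(latent_graph, 1.0, r_latent), LayerSpec(spatial_graph, spatial_weight, r)],
            seed=seed,
        ),
        target_k, r_init=r_latent, r_step=r_step, max_iter=max_iter,
    )
    part_b.meta.update({"latent_resolution": r_latent, "spatial_resolution": r_spatial})
    return part_b
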