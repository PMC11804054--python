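# Methods

## Problem setting

Spots (capture locations or segmented cells) carry a non-negative
expression vector and a 2-D position. A spatial domain is a group of spots
with a shared expression profile that is also spatially organized. The
package detects domains by optimizing a single partition over two graph
layers on the same node set: a kNN graph in expression latent space and a
neighbor graph in physical space. Domains may be spatially disconnected
(e.g., mirrored structures in the two brain hemispheres); nothing in the
objective enforces contiguity, the spatial layer only rewards it.

## Graphs

**Spatial layer.** For gridded platforms the neighbors are the lattice
adjacency: 6 per interior spot on a hexagonal grid, 4 on a square grid,
detected as point pairs at the lattice spacing (median nearest-neighbor
distance) within a relative tolerance of 1e-3. All grid edges get unit
weight because lattice neighbors are equidistant. For non-gridded
platforms, Delaunay triangulation or kNN (default k = 10, symmetrized by
union) defines the edges, and edge distances d are converted to
connectivities `w = 1 − d/d_max` with `d_max` the largest edge distance in
the graph; edges that reach weight exactly 0 are removed, since a 0-weight
edge is a non-edge for modularity-type objectives. The transform is
scale-invariant in the coordinates.

**Latent layer.** Counts are total-count scaled (default 1e4 per spot) and
log1p-transformed; genes are ranked and the top `n_top_genes` (default
3000) retained, either by variance-stabilized dispersion (HVG: local-linear
fit of log10 variance vs log10 mean across genes, span 0.3; counts
standardized by the fitted standard deviation, clipped at sqrt(n_spots);
score = variance of the clipped values) or by Moran's *I* over the spatial
graph (SVG), with ties broken lexicographically by gene id for
reproducibility. The latent space is the top `n_components` (default 30)
components of PCA or of the spatially weighted decomposition (below); the
latent graph connects each spot to its `latent_k` = 15 nearest neighbors,
union-symmetrized, with a local-scaling Gaussian kernel
`w_ij = exp(−d_ij² / σ_i σ_j)` where σ_i is the distance to the k-th
neighbor. This kernel is a deliberate, fully specified alternative to the
fuzzy-union connectivities of the common single-cell stacks; a `binary`
kernel is available behind config.

## Spatially weighted PCA

With Xc the column-centered (optionally scaled) expression of the selected
genes and W the row-normalized spatial weight matrix, the decomposition
solves the symmetric eigenproblem of

```
H = Xcᵀ (W + Wᵀ) Xc / (2n).
```

Each eigenvalue satisfies λ_j = var(s_j) · I(s_j), the product of the j-th
score's variance and its Moran's *I* under W (exact when W has no zero
rows, i.e., no isolated nodes), so leading components trade variance for
spatial smoothness. The `n_comp` largest eigenvalues are kept; the most
negative components (locally alternating patterns) are excluded by default
and available via `n_neg`. Row normalization before symmetrization follows
the original multivariate spatial-analysis convention; raw weights are a
config option. Components are sign-canonicalized (largest-magnitude loading
positive). For more than 5000 spots the eigenproblem is solved iteratively
on the implicit operator `v ↦ Xcᵀ(W+Wᵀ)(Xc v)/(2n)` without materializing
H.

## Multiplex Leiden

Per layer, the quality is the unnormalized Reichardt–Bornholdt
configuration function over ordered pairs; the combined objective is the
layer-weighted sum. Quality being unnormalized means a layer's influence
scales with its total edge mass — this is documented prominently because it
defines what the spatial weight w means: w multiplies raw quality units of
the spatial graph against raw units of the latent graph.

The optimizer is the Leiden scheme generalized to shared-partition layers:

1. **Local move** — nodes visited in a seeded shuffle with queue-based
   revisiting; a node joins the neighboring community (neighbors pooled
   across layers) with the largest ΔQ_total, computed incrementally from
   per-layer community degree sums; an empty community is taken when every
   occupied option has negative gain. Ties keep the current community, then
   the lowest community id.
2. **Refinement** — within each community, nodes start as singletons and a
   still-singleton node merges into an adjacent refined community of the
   same coarse community chosen uniformly at random among the strictly
   improving options. Refined communities are therefore connected within
   their community.
3. **Aggregation** — the refined partition collapses every layer
   simultaneously (edge weights summed, self-loops kept; the diagonal
   carries the ordered-pair within-cluster weight so the total mass is
   invariant), seeded with the pre-refinement communities.

A pass runs 1–3 down the hierarchy until aggregation stabilizes, then
restarts from the flat graph; passes repeat until three consecutive passes
bring no quality increase (the randomized refinement can escape a local
optimum even when one pass stalls). Q_total never decreases across passes
(asserted at runtime), and disconnected communities are split as a final
step, which cannot decrease the objective for non-negative weights and
positive resolutions. Because the heuristic is seed-sensitive on small or
ambiguous graphs, `leiden_multiplex` runs 3 restarts with derived seeds by
default and returns the best-quality partition; the result is deterministic
given the seed, and multiplying all layer weights by a constant leaves it
unchanged. The hot loops are numba-compiled.

## Resolution search and the two-stage procedure

`search_resolution` brackets a target cluster count: raise the resolution
while too few clusters are found, lower it while too many, halving the step
on every direction flip, up to 40 evaluations with one fixed clustering
seed per search; a non-positive candidate resolution is clamped to 1e-4.
`spatial_leiden` first tunes the latent layer's resolution with non-spatial
Leiden to the target count, then freezes it (and the layer weights 1, w)
and tunes the spatial layer's resolution in the multiplex, starting from
the latent resolution. Stage (a) is never re-tuned after the spatial layer
is added; with w = 0 the procedure reduces exactly to non-spatial Leiden.

The cluster count is not a free dial of the resolution alone: when domains
form well-separated latent blobs, merging two blobs always lowers the
configuration quality at any positive resolution, so counts *below* the
number of natural components are unreachable — a structural property of
the null model, not of the search.

## Choosing the spatial weight

With unnormalized per-layer quality, "weight 1" only means parity when the
two layers carry comparable edge mass. The local-scaling latent kernel
yields roughly 2× the mass of a unit-weight grid, so the package exposes
`balanced_spatial_weight` = Σ(latent weights)/Σ(spatial weights) (~2.2 on
the default synthetic tissue) as the principled default for grids when no
technology-specific weight has been tuned; the recovery experiment and the
acceptance study use it. `sweep-weight` in the CLI runs the diagnostic
weight sweep for tuning on real data, where the best weight is known to be
technology- and neighborhood-definition-dependent.

## Evaluation and testing statistics

ARI and NMI are computed from the contingency table over spots present in
both labelings (excluded spots are counted and logged). NMI uses
arithmetic-mean normalization by default (geometric/min/max behind a flag);
two single-cluster labelings score 1, a one-sided single cluster scores 0.
The paired Wilcoxon signed-rank test drops zero differences, midranks ties,
and uses the exact rank-sum distribution (dynamic program over doubled
midranks) up to 25 informative pairs and a tie- and continuity-corrected
normal approximation beyond; two-sided p = min(1, 2·min(P≤, P≥)).
Benjamini–Hochberg is the standard step-up with q capped at 1, applied
across all comparisons of a run.

## Synthetic tissue

The generator emulates a layered tissue at desk scale: spots on a
hex/square lattice or random points; K domains as horizontal bands of
near-equal size (cortical-layer-like) or Voronoi patches, contiguous by
construction. Expression: per-gene baseline means drawn log-normal(0, 1);
each domain's `n_markers_per_domain` markers multiplied by
exp(`marker_log_fold_change`); profiles normalized and scaled to
`library_size`; counts negative binomial with size `dispersion` (variance
μ + μ²/size; `dispersion = inf` gives the Poisson limit). With probability
`noise_mixing`, a spot's whole profile is swapped for a uniformly chosen
other domain's profile — mimicking ambiguous or mis-assigned spots, the
regime where spatial information resolves what expression cannot. Defaults:
2000 spots, 500 genes, K = 4, 25 markers/domain, LFC = 1.0, size = 2,
library 2000 — typical magnitudes for a filtered Visium-scale experiment
(a few percent of genes informative per domain, ~e-fold markers, strongly
overdispersed counts, ~2k counts/spot).

What the generator does **not** emulate: platform artifacts (spot swapping,
segmentation errors), gene–gene correlation beyond the domain profiles,
continuous gradients within domains, batch effects, or histology. Passing
the recovery study therefore shows the machinery behaves as designed under
its own assumptions, not that any particular weight setting is optimal for
a real platform.

## Study sizes used in tests and the acceptance script

The recovery study runs the full pipeline (normalize → HVG → PCA → graphs →
clustering with resolution search) at the default study conditions, 10
seeds, comparing non-spatial Leiden and the multiplex clustering at the
balanced spatial weight, with and without 30% profile mixing. The
resolution-search study uses a weak-marker tissue (800 spots, 300 genes,
LFC = 0.5, 30% mixing) whose cluster count is resolution-driven, so targets
below and above the generating K are all attainable (see the structural
note above). Optimizer optimality is checked against exhaustive
enumeration of all partitions on random two-layer instances of up to 8
nodes, where enumeration is feasible and exact.

## Numerical choices and degenerate inputs

- Quality tolerances: improvement threshold 1e-12 (absolute per move);
  monotonicity asserted at 1e-10 of the summed layer mass.
- `1 − d/d_max` with all distances equal is degenerate (every weight 0) and
  raises; grids use unit weights instead.
- Zero-variance genes score −inf (SVG) or 0 (HVG) and are never selected.
- Spots with zero total count fail normalization with their ids listed.
- Duplicate points are rejected for Delaunay and grids; in kNN graphs a
  duplicate's zero-distance self-pair is dropped and kernel weights at
  d = 0 are 1.
- k ≥ n in kNN builders clips to n − 1 with a warning.
- Isolated nodes in the spatial graph leave zero rows in W (warned); the
  eigenvalue identity then holds only up to the S0/n factor.

## Known limitations

- The optimizer is a heuristic; optimality is only verified exhaustively at
  tiny sizes, and restarts reduce but do not eliminate seed sensitivity.
- The two-stage resolution search can fail to hit the exact target count
  when the count jumps by more than one between achievable plateaus; the
  closest partition is returned with a warning.
- Directed graphs, CPM quality, contiguity constraints, n-rings > 1 grid
  neighborhoods, and 3-D coordinates are out of scope.
- IO supports MatrixMarket/TSV only; AnnData/HDF5 readers are intentionally
  not a dependency.
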