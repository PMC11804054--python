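# spatialmux

Spatially aware multiplex Leiden clustering for spatially resolved omics.

Spatial transcriptomics platforms (10x Visium, Stereo-seq, MERFISH, osmFISH,
STARmap, ...) measure expression at known tissue positions, and the analysis
goal is usually to partition spots/cells into **spatial domains** — regions
such as cortical layers that share an expression profile. Standard Leiden
clustering uses only a k-nearest-neighbor graph in expression latent space
and ignores where the cells sit. `spatialmux` makes Leiden spatially aware
by adding the physical neighborhood as a **second graph layer** over the
same nodes and optimizing one partition jointly across both layers.

## The model

Each layer *l* (latent-expression kNN graph; spatial grid / Delaunay / kNN
graph) contributes a Reichardt–Bornholdt configuration quality with its own
resolution γ<sub>l</sub>:

```
Q_l(γ) = Σ_ij (A_ij − γ k_i k_j / 2m) δ(c_i, c_j)
```

and the optimizer maximizes `Q_total = Σ_l w_l Q_l(γ_l)` with a multiplex
Leiden procedure (seeded queue-based local moves, randomized refinement,
simultaneous aggregation of all layers). Only the ratio of the layer
weights w<sub>l</sub> matters; the expression layer is fixed at weight 1 and
the spatial weight controls how strongly tissue contiguity shapes the
domains. Resolutions are tuned by a bracketing search to a target cluster
count: first the latent layer alone (plain Leiden), then the spatial layer
with the latent resolution frozen.

The package also provides spatially aware feature selection (Moran's *I*
ranking of spatially variable genes), spatially weighted PCA (eigenvectors
of `Xcᵀ(W+Wᵀ)Xc/(2n)`, whose eigenvalues factor into score variance ×
Moran's *I*), clustering metrics (ARI, NMI), paired significance tests
(exact Wilcoxon signed-rank + Benjamini–Hochberg), and a synthetic-tissue
generator with known domains so the whole workflow is testable offline.

## Worked example

Simulate a 30×30-spot four-layer tissue in which 25% of spots carry the
expression profile of a *different* domain (transcriptionally ambiguous but
spatially embedded), then cluster it with and without the spatial layer:

```sh
spatialmux simulate --n-spots 900 --n-genes 300 --noise-mixing 0.25 --seed 7 --out demo
spatialmux run --matrix demo/matrix.mtx --spots demo/spots.tsv --genes demo/genes.tsv \
    --coords demo/coords.tsv --technology square_grid \
    --target-k 4 --seed 7 --spatial-weight 2.0 --out demo/run
spatialmux evaluate --pred demo/run/clusters.tsv --truth demo/truth.tsv
```

prints

```json
{"ari": 0.679, "nmi": 0.618, "n_used": 900, "n_excluded": 0}
```

whereas the same run with `--spatial-weight 0` (plain, non-spatial Leiden)
gives `{"ari": 0.479, "nmi": 0.433, ...}`: the spatial layer reassigns the
profile-swapped spots to the domain their neighborhood supports, lifting
agreement with the generating labels from 0.48 to 0.68 ARI. `demo/run/`
also contains a `manifest.json` with the config snapshot, derived stage
seeds, the resolutions found by the two-stage search and output hashes.

The same workflow is available as a library:

```python
from spatialmux import TissueSpec, recovery_experiment
table = recovery_experiment(TissueSpec(noise_mixing=0.3, seed=0), n_seeds=10)
print(table.groupby("method")["ari"].median())
```

## Layout

- `spatialmux.data_model` — matrix/coordinate/label types and TSV/MatrixMarket IO
- `spatialmux.neighbor_graphs` — grid/Delaunay/kNN spatial graphs, latent kNN, `1 − d/d_max` connectivities
- `spatialmux.feature_selection` — Moran's *I*, SVG and variance-stabilized HVG ranking
- `spatialmux.spatial_dimred` — PCA and spatially weighted PCA
- `spatialmux.multiplex_leiden` — RB quality, the multiplex Leiden optimizer, resolution search
- `spatialmux.evaluation` — ARI/NMI, Wilcoxon signed-rank, Benjamini–Hochberg
- `spatialmux.synthetic_tissue` — tissue generator and the recovery experiment
- `spatialmux.cli` — `spatialmux` console script (`simulate`, `graph`, `reduce`, `cluster`, `evaluate`, `compare`, `sweep-weight`, `run`)

See `docs/methods.md` for the modeling choices, parameter meanings and
known limitations.
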