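"""Gene selection: highly variable genes (HVG) and spatially variable genes (SVG).

HVGs are ranked by a variance-stabilized dispersion: a local-linear fit of
log10(variance) against log10(mean) across genes predicts each gene's
expected standard deviation, counts are standardized by it (clipped at
sqrt(n_spots)) and the variance of the clipped values is the score.

SVGs are ranked by Moran's I spatial autocorrelation of the log-normalized
expression over the spatial neighbor graph; positive I means spatially
smooth expression, the signature of a domain marker.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse

from .data_model import ExpressionMatrix, LayerTag, ValidationError
from .neighbor_graphs import WeightedGraph

logger = logging.getLogger(__name__)


@dataclass
class GeneScoreTable:
    """Per-gene scores with descending ranks (rank 1 = best) and a selection mask."""

    gene_ids: list[str]
    score: np.ndarray
    rank: np.ndarray
    selected: np.ndarray
    kind: str = "score"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"gene": self.gene_ids, "score": self.score, "rank": self.rank, "selected": self.selected}
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def selected_genes(self) -> list[str]:
        order = np.argsort(self.rank)
        return [self.gene_ids[i] for i in order if self.selected[i]]


def morans_i(values: np.ndarray, g: WeightedGraph, row_normalize: bool = True) -> float:
    """Moran's I of ``values`` over the graph's weights.

    I = (n / S0) * sum_ij w_ij z_i z_j / sum_i z_i^2 with z the centered
    values and S0 the total weight over ordered pairs.  Weights are
    row-normalized by default (the common autocorrelation convention).
    """
    values = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValidationError("non-finite values")
    if g.n_edges == 0:
        raise ValidationError("graph has no edges")
    z = values - values.mean()
    denom = float(z @ z)
    if denom == 0:
        raise ValidationError("Moran's I undefined for constant values")
    W = g.row_normalized() if row_normalize else g.to_csr()
    s0 = float(W.sum())
    num = float(z @ (W @ z))
    return len(values) / s0 * num / denom


def _morans_i_all_genes(Z: np.ndarray, W: sparse.csr_matrix, n: int) -> np.ndarray:
    """Vectorized Moran's I over columns of centered matrix Z."""
    s0 = float(W.sum())
    num = np.einsum("ij,ij->j", Z, W @ Z)
    denom = np.einsum("ij,ij->j", Z, Z)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = n / s0 * num / denom
    out[denom == 0] = -np.inf
    return out


def _rank_and_select(gene_ids: list[str], score: np.ndarray, n_top: int, kind: str) -> GeneScoreTable:
    if n_top < 1:
        raise ValidationError("n_top must be >= 1")
    p = len(gene_ids)
    if n_top > p:
        logger.warning("n_top=%d > n_genes=%d; selecting all genes", n_top, p)
    # descending score, gene-id lexicographic tie-break for reproducibility
    order = sorted(range(p), key=lambda i: (-score[i], gene_ids[i]))
    rank = np.empty(p, dtype=int)
    for r, i in enumerate(order):
        rank[i] = r + 1
    selected = (rank <= n_top) & np.isfinite(score)
    return GeneScoreTable(list(gene_ids), score, rank, selected, kind)


def select_svgs(X: ExpressionMatrix, g: WeightedGraph, n_top: int = 3000,
                row_normalize: bool = True) -> GeneScoreTable:
    """Rank genes by Moran's I over the spatial graph; keep the top ``n_top``.

    Zero-variance genes score ``-inf`` and are never selected.
    """
    if g.n_nodes != X.n_spots:
        raise ValidationError("graph node count does not match matrix")
    dense = X.dense()
    Z = dense - dense.mean(axis=0, keepdims=True)
    W = g.row_normalized() if row_normalize else g.to_csr()
    score = _morans_i_all_genes(Z, W, X.n_spots)
    return _rank_and_select(X.gene_ids, score, n_top, "morans_i")


def _local_linear_fit(x: np.ndarray, y: np.ndarray, span: float = 0.3) -> np.ndarray:
    """Tricube-weighted local linear regression of y on x, predicted at x.

    For each point the nearest ``ceil(span * n)`` neighbors in x define the
    window; weights are tricube in scaled distance.  Mirrors the smoother
    conventionally used for mean-variance trend fitting.
    """
    n = x.size
    k = max(2, int(np.ceil(span * n)))
    order = np.argsort(x)
    xs, ys = x[order], y[order]
    fitted = np.empty(n)
    for pos, xi in enumerate(xs):
        lo = np.searchsorted(xs, xi)
        i0 = max(0, min(lo - k // 2, n - k))
        window = slice(i0, i0 + k)
        xw, yw = xs[window], ys[window]
        h = np.abs(xw - xi).max()
        if h == 0:
            fitted[pos] = yw.mean()
            continue
        w = (1 - np.minimum(np.abs(xw - xi) / h, 1) ** 3) ** 3
        w = np.maximum(w, 1e-9)
        sw = w.sum()
        xm = (w * xw).sum() / sw
        ym = (w * yw).sum() / sw
        sxx = (w * (xw - xm) ** 2).sum()
        slope = (w * (xw - xm) * (yw - ym)).sum() / sxx if sxx > 0 else 0.0
        fitted[pos] = ym + slope * (xi - xm)
    out = np.empty(n)
    out[order] = fitted
    return out


def select_hvgs(X: ExpressionMatrix, n_top: int = 3000, span: float = 0.3) -> GeneScoreTable:
    """Variance-stabilized HVG ranking on raw counts.

    Genes with zero variance score 0 and rank last; requires at least 10
    genes with nonzero variance for a stable mean-variance trend fit.
    """
    if X.layer_tag != LayerTag.RAW:
        raise ValidationError("HVG selection operates on raw counts")
    counts = X.dense()
    n = X.n_spots
    mean = counts.mean(axis=0)
    var = counts.var(axis=0, ddof=1)
    usable = (var > 0) & (mean > 0)
    if usable.sum() < 10:
        raise ValidationError(
            f"only {int(usable.sum())} genes with nonzero variance; trend fit unstable"
        )
    fitted_logvar = _local_linear_fit(np.log10(mean[usable]), np.log10(var[usable]), span)
    sd_fit = np.ones(X.n_genes)
    sd_fit[usable] = np.sqrt(10.0 ** fitted_logvar)
    clip = np.sqrt(n)
    Zc = np.clip((counts - mean) / sd_fit, -clip, clip)
    score = Zc.var(axis=0, ddof=1)
    score[~usable] = 0.0
    return _rank_and_select(X.gene_ids, score, n_top, "standardized_variance")
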