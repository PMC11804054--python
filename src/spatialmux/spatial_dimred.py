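"""PCA and spatially weighted PCA (MULTISPATI-style) for the latent space.

Standard PCA eigendecomposes the gene-gene covariance C = Xc' Xc / n of the
column-centered data.  The spatially weighted variant instead solves the
symmetric eigenproblem of

    H = Xc' (W + W') Xc / (2 n)

where W is the row-normalized spatial weight matrix.  Each eigenvalue
factorizes as lambda_j = var(s_j) * I(s_j): the variance of the component
scores times their Moran's I under W, so the leading components trade
variance for spatial smoothness.  The trailing (most negative) eigenvalues
capture locally alternating patterns and are excluded unless requested via
``n_neg``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import sparse
from scipy.linalg import eigh
from scipy.sparse.linalg import LinearOperator, eigsh

from .data_model import ExpressionMatrix, ValidationError
from .neighbor_graphs import WeightedGraph

logger = logging.getLogger(__name__)

#: above this many spots the eigenproblem is solved iteratively on the
#: implicit operator instead of materializing H
DENSE_SPOT_LIMIT = 5000


@dataclass
class MultispatiModel:
    """Fitted decomposition: eigenvalues (descending), orthonormal gene
    loadings, spot scores, the centering vector and (for the spatial variant)
    the row-normalized weight matrix used at fit time."""

    eigenvalues: np.ndarray           # (n_comp,)
    components: np.ndarray            # (p, n_comp), orthonormal columns
    scores: np.ndarray                # (n, n_comp)
    centering: np.ndarray             # (p,)
    scaling: np.ndarray | None        # (p,) or None
    W: sparse.csr_matrix | None       # None for plain PCA
    gene_ids: list[str]

    @property
    def n_components(self) -> int:
        return int(self.eigenvalues.size)

    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        np.savetxt(outdir / "eigenvalues.tsv", self.eigenvalues, delimiter="\t")
        np.savetxt(outdir / "components.tsv", self.components, delimiter="\t")
        np.savetxt(outdir / "scores.tsv", self.scores, delimiter="\t")
        np.savetxt(outdir / "centering.tsv", self.centering, delimiter="\t")
        meta = {"n_components": self.n_components, "spatial": self.W is not None,
                "scaled": self.scaling is not None, "gene_ids": self.gene_ids}
        (outdir / "model.json").write_text(json.dumps(meta))


def _center_scale(X: ExpressionMatrix, scale: bool) -> tuple[np.ndarray, np.ndarray, np.ndarray | None]:
    dense = X.dense()
    mu = dense.mean(axis=0)
    Xc = dense - mu
    sd = None
    if scale:
        sd = dense.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        Xc = Xc / sd
    return Xc, mu, sd


def _canonicalize_signs(components: np.ndarray, scores: np.ndarray) -> None:
    """Flip each component so its largest-magnitude loading is positive."""
    for j in range(components.shape[1]):
        i = int(np.argmax(np.abs(components[:, j])))
        if components[i, j] < 0:
            components[:, j] *= -1
            scores[:, j] *= -1


def fit_pca(X: ExpressionMatrix, n_comp: int = 30, scale: bool = False) -> MultispatiModel:
    """Plain PCA: eigendecomposition of the covariance Xc' Xc / n.

    Eigenvalues are the (population) variances of the component scores.
    """
    if n_comp < 1:
        raise ValidationError("n_comp must be >= 1")
    n, p = X.values.shape
    if n_comp > min(n, p):
        raise ValidationError(f"n_comp={n_comp} exceeds min(n_spots, n_genes)={min(n, p)}")
    Xc, mu, sd = _center_scale(X, scale)
    C = (Xc.T @ Xc) / n
    vals, vecs = eigh(C, subset_by_index=(p - n_comp, p - 1))
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    scores = Xc @ vecs
    _canonicalize_signs(vecs, scores)
    return MultispatiModel(vals, vecs, scores, mu, sd, None, list(X.gene_ids))


def fit_multispati(
    X: ExpressionMatrix,
    g: WeightedGraph | None,
    n_comp: int = 30,
    n_neg: int = 0,
    scale: bool = False,
    row_normalize: bool = True,
    weight_matrix: sparse.spmatrix | None = None,
) -> MultispatiModel:
    """Spatially weighted PCA via the symmetric eigenproblem of
    H = Xc' (W + W') Xc / (2n).

    Keeps the ``n_comp`` largest eigenvalues, optionally plus the ``n_neg``
    smallest (negative spatial autocorrelation).  ``weight_matrix`` overrides
    the graph-derived W (escape hatch; e.g. the identity recovers plain PCA).
    """
    if n_comp < 1:
        raise ValidationError("n_comp must be >= 1")
    n, p = X.values.shape
    if n_comp + n_neg > min(n, p):
        raise ValidationError("n_comp + n_neg exceeds matrix rank bound")
    if weight_matrix is not None:
        W = sparse.csr_matrix(weight_matrix)
    else:
        if g is None:
            raise ValidationError("a spatial graph (or weight_matrix) is required")
        if g.n_nodes != n:
            raise ValidationError("graph node count does not match matrix")
        if g.n_edges == 0:
            raise ValidationError("spatial graph has no edges")
        iso = int((g.degrees() == 0).sum())
        if iso:
            logger.warning("%d isolated node(s); their weight rows are zero", iso)
        W = g.row_normalized() if row_normalize else g.to_csr()
    Wsym = (W + W.T) * 0.5

    Xc, mu, sd = _center_scale(X, scale)
    if n <= DENSE_SPOT_LIMIT or n_comp + n_neg >= p - 1:
        H = (Xc.T @ (Wsym @ Xc)) / n
        H = (H + H.T) * 0.5  # numerical symmetry
        vals, vecs = eigh(H)
    else:
        # implicit operator v -> Xc'(W+W')(Xc v)/(2n); H never materialized
        def matvec(v: np.ndarray) -> np.ndarray:
            return Xc.T @ (Wsym @ (Xc @ v)) / n

        op = LinearOperator((p, p), matvec=matvec, dtype=float)
        k = n_comp + n_neg
        vals_hi, vecs_hi = eigsh(op, k=n_comp, which="LA")
        if n_neg:
            vals_lo, vecs_lo = eigsh(op, k=n_neg, which="SA")
            vals = np.concatenate([vals_hi, vals_lo])
            vecs = np.hstack([vecs_hi, vecs_lo])
        else:
            vals, vecs = vals_hi, vecs_hi
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    keep_idx = list(range(n_comp))
    if n_neg:
        keep_idx += list(range(vals.size - n_neg, vals.size))
    vals, vecs = vals[keep_idx], vecs[:, keep_idx]
    scores = Xc @ vecs
    _canonicalize_signs(vecs, scores)
    return MultispatiModel(vals, vecs, scores, mu, sd, sparse.csr_matrix(W), list(X.gene_ids))


def transform(model: MultispatiModel, X_new: ExpressionMatrix) -> np.ndarray:
    """Project new spots into the fitted component space."""
    if list(X_new.gene_ids) != list(model.gene_ids):
        raise ValidationError("gene set/order does not match the fitted model")
    Xc = X_new.dense() - model.centering
    if model.scaling is not None:
        Xc = Xc / model.scaling
    return Xc @ model.components


def eigenvalue_decomposition_table(model: MultispatiModel):
    """Per-component variance and Moran's I of the scores.

    For the spatially weighted fit the product variance * I reproduces the
    eigenvalue (exact when W has no zero rows, since then S0 = n).
    """
    import pandas as pd

    n = model.scores.shape[0]
    var = model.scores.var(axis=0, ddof=0)
    if model.W is not None:
        W = model.W
        s0 = float(W.sum())
        num = np.einsum("ij,ij->j", model.scores, W @ model.scores)
        denom = np.einsum("ij,ij->j", model.scores, model.scores)
        mi = n / s0 * num / denom
    else:
        mi = np.full(model.n_components, np.nan)
    return pd.DataFrame(
        {
            "component": np.arange(model.n_components),
            "eigenvalue": model.eigenvalues,
            "variance": var,
            "morans_i": mi,
        }
    )
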