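"""Core domain types and text-based IO for spatial omics matrices.

The package operates on three aligned tables: a spots x genes count (or
log-normalized) matrix, a per-spot 2-D coordinate table, and an optional
per-spot label table.  Matrices are stored spots x genes everywhere; the
MatrixMarket reader accepts either orientation via ``transpose=True``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """Raised when an input file cannot be parsed or is dimensionally inconsistent."""


class ValidationError(ValueError):
    """Raised when parsed data violates a domain invariant."""


class LayerTag(str, Enum):
    RAW = "raw"
    NORMALIZED = "normalized"
    LOG = "log"


class Technology(str, Enum):
    HEX_GRID = "hex_grid"
    SQUARE_GRID = "square_grid"
    GENERIC = "generic"


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    dups = []
    for i in ids:
        if i in seen:
            dups.append(i)
        seen.add(i)
    if dups:
        raise ValidationError(f"duplicate {what}: {sorted(set(dups))[:5]}")


@dataclass
class ExpressionMatrix:
    """Spots x genes expression values with aligned string identifiers.

    ``values`` may be a dense ndarray or a scipy sparse matrix (CSR); all
    entries must be finite and non-negative.
    """

    values: np.ndarray | sparse.spmatrix
    spot_ids: list[str]
    gene_ids: list[str]
    layer_tag: LayerTag = LayerTag.RAW

    def __post_init__(self) -> None:
        n, p = self.values.shape
        if n != len(self.spot_ids) or p != len(self.gene_ids):
            raise ValidationError(
                f"matrix shape {self.values.shape} inconsistent with "
                f"{len(self.spot_ids)} spot ids / {len(self.gene_ids)} gene ids"
            )
        _check_unique(self.spot_ids, "spot ids")
        _check_unique(self.gene_ids, "gene ids")
        data = self.values.data if sparse.issparse(self.values) else self.values
        if data.size and not np.all(np.isfinite(data)):
            raise ValidationError("expression matrix contains NaN/inf")
        if data.size and data.min() < 0:
            raise ValidationError("expression matrix contains negative entries")

    @property
    def n_spots(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def dense(self) -> np.ndarray:
        if sparse.issparse(self.values):
            return np.asarray(self.values.todense(), dtype=float)
        return np.asarray(self.values, dtype=float)

    def subset_genes(self, keep: Sequence[str] | np.ndarray) -> "ExpressionMatrix":
        """Return a new matrix restricted to ``keep`` (gene ids or boolean mask)."""
        if isinstance(keep, np.ndarray) and keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            pos = {g: i for i, g in enumerate(self.gene_ids)}
            idx = np.array([pos[g] for g in keep], dtype=int)
        vals = self.values.tocsc()[:, idx].tocsr() if sparse.issparse(self.values) else self.values[:, idx]
        return ExpressionMatrix(vals, list(self.spot_ids), [self.gene_ids[i] for i in idx], self.layer_tag)


@dataclass
class SpotCoordinates:
    """Per-spot 2-D positions in platform units (Euclidean, no conversion)."""

    spot_ids: list[str]
    xy: np.ndarray  # (n, 2) float
    technology: Technology = Technology.GENERIC

    def __post_init__(self) -> None:
        self.xy = np.asarray(self.xy, dtype=float)
        if self.xy.ndim != 2 or self.xy.shape[1] != 2:
            raise ValidationError(f"coordinates must be (n, 2), got {self.xy.shape}")
        if self.xy.shape[0] != len(self.spot_ids):
            raise ValidationError("coordinate row count does not match spot ids")
        _check_unique(self.spot_ids, "spot ids")
        if not np.all(np.isfinite(self.xy)):
            raise ValidationError("non-finite coordinate")
        if self.technology in (Technology.HEX_GRID, Technology.SQUARE_GRID):
            uniq = {tuple(r) for r in np.round(self.xy, 9)}
            if len(uniq) != len(self.spot_ids):
                raise ValidationError("duplicate coordinates on a grid technology")

    @property
    def n_spots(self) -> int:
        return len(self.spot_ids)


@dataclass
class LabelVector:
    """Categorical per-spot labels (ground-truth domains or cluster calls)."""

    spot_ids: list[str]
    labels: list[str]

    def __post_init__(self) -> None:
        if len(self.spot_ids) != len(self.labels):
            raise ValidationError("labels not aligned to spot ids")
        _check_unique(self.spot_ids, "spot ids")
        if len(set(self.labels)) < 1:
            raise ValidationError("need at least one label")

    def as_codes(self) -> np.ndarray:
        cats = sorted(set(self.labels))
        lut = {c: i for i, c in enumerate(cats)}
        return np.array([lut[l] for l in self.labels], dtype=int)


@dataclass
class RunConfig:
    """Pipeline configuration; defaults follow the standard workflow values
    (3000 selected genes, 30 latent components, 15 latent neighbors, 10
    spatial neighbors for generic point sets)."""

    n_top_genes: int = 3000
    n_components: int = 30
    latent_k: int = 15
    spatial_k: int = 10
    spatial_weight: float = 1.0
    target_clusters: int = 4
    seed: int = 0
    graph_mode: str = "grid"  # grid | delaunay | knn
    feature_mode: str = "hvg"  # hvg | svg | all
    dimred_mode: str = "pca"  # pca | multispati
    target_sum: float = 1e4
    latent_kernel: str = "local_gaussian"  # local_gaussian | binary

    def __post_init__(self) -> None:
        for name in ("n_top_genes", "n_components", "latent_k", "spatial_k", "target_clusters"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be positive")
        if self.spatial_weight < 0:
            raise ValidationError("spatial_weight must be >= 0")
        for name, allowed in (
            ("graph_mode", {"grid", "delaunay", "knn"}),
            ("feature_mode", {"hvg", "svg", "all"}),
            ("dimred_mode", {"pca", "multispati"}),
            ("latent_kernel", {"local_gaussian", "binary"}),
        ):
            if getattr(self, name) not in allowed:
                raise ValidationError(f"{name} must be one of {sorted(allowed)}")


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

def _read_id_file(path: str | Path, what: str) -> list[str]:
    ids = [ln.split("\t")[0].strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    if not ids:
        raise FormatError(f"empty {what} file: {path}")
    return ids


def read_expression(
    path_matrix: str | Path,
    path_spots: str | Path,
    path_genes: str | Path,
    transpose: bool = False,
) -> ExpressionMatrix:
    """Read a MatrixMarket coordinate file (or dense TSV) plus id files.

    Orientation on disk is spots x genes; pass ``transpose=True`` for
    genes x spots files (common for CellRanger-style exports).
    """
    path_matrix = Path(path_matrix)
    spot_ids = _read_id_file(path_spots, "spot id")
    gene_ids = _read_id_file(path_genes, "gene id")
    if path_matrix.suffix == ".mtx":
        try:
            mat = spio.mmread(str(path_matrix))
        except Exception as e:  # noqa: BLE001 - surface as format error
            raise FormatError(f"cannot parse MatrixMarket file {path_matrix}: {e}") from e
        mat = sparse.csr_matrix(mat)
    else:
        df = pd.read_csv(path_matrix, sep="\t", header=None)
        mat = df.to_numpy(dtype=float)
    if transpose:
        mat = mat.T
        if sparse.issparse(mat):
            mat = mat.tocsr()
    if mat.shape != (len(spot_ids), len(gene_ids)):
        raise FormatError(
            f"matrix shape {mat.shape} does not match id files "
            f"({len(spot_ids)} spots, {len(gene_ids)} genes)"
        )
    return ExpressionMatrix(mat, spot_ids, gene_ids, LayerTag.RAW)


def write_expression(X: ExpressionMatrix, path_matrix: str | Path,
                     path_spots: str | Path, path_genes: str | Path) -> None:
    """Write matrix as MatrixMarket coordinate + one-id-per-line files."""
    vals = X.values if sparse.issparse(X.values) else sparse.csr_matrix(X.values)
    spio.mmwrite(str(path_matrix), sparse.coo_matrix(vals))
    Path(path_spots).write_text("\n".join(X.spot_ids) + "\n")
    Path(path_genes).write_text("\n".join(X.gene_ids) + "\n")


def read_coordinates(path: str | Path, technology: str | Technology = Technology.GENERIC) -> SpotCoordinates:
    """Read a TSV with header ``id``, ``x``, ``y``; row order is preserved."""
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as e:  # noqa: BLE001
        raise FormatError(f"cannot parse coordinate file {path}: {e}") from e
    missing = {"id", "x", "y"} - set(df.columns)
    if missing:
        raise FormatError(f"coordinate file {path} missing columns {sorted(missing)}")
    xy = df[["x", "y"]].to_numpy()
    try:
        xy = xy.astype(float)
    except ValueError as e:
        raise FormatError(f"non-numeric coordinate in {path}: {e}") from e
    return SpotCoordinates(df["id"].astype(str).tolist(), xy, Technology(technology))


def write_coordinates(coords: SpotCoordinates, path: str | Path) -> None:
    pd.DataFrame({"id": coords.spot_ids, "x": coords.xy[:, 0], "y": coords.xy[:, 1]}).to_csv(
        path, sep="\t", index=False
    )


def read_labels(path: str | Path) -> LabelVector:
    """Read a TSV with header ``id``, ``label``."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"id", "label"} - set(df.columns)
    if missing:
        raise FormatError(f"label file {path} missing columns {sorted(missing)}")
    return LabelVector(df["id"].tolist(), df["label"].tolist())


def write_labels(labels: LabelVector, path: str | Path) -> None:
    pd.DataFrame({"id": labels.spot_ids, "label": labels.labels}).to_csv(path, sep="\t", index=False)


def normalize_log1p(X: ExpressionMatrix, target_sum: float = 1e4) -> ExpressionMatrix:
    """Total-count scale each spot to ``target_sum``, then log(1 + v).

    Requires raw counts; spots with zero total are rejected (their scaling is
    undefined) and listed in the error message.
    """
    if X.layer_tag != LayerTag.RAW:
        raise ValidationError(f"normalize_log1p requires raw counts, got layer '{X.layer_tag.value}'")
    if target_sum <= 0:
        raise ValidationError("target_sum must be positive")
    if sparse.issparse(X.values):
        totals = np.asarray(X.values.sum(axis=1)).ravel()
    else:
        totals = X.values.sum(axis=1)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        bad = [X.spot_ids[i] for i in zero[:10]]
        raise ValidationError(f"{zero.size} spot(s) with zero total count: {bad}")
    if sparse.issparse(X.values):
        scaled = sparse.diags(target_sum / totals) @ X.values.tocsr()
        out = scaled.copy()
        out.data = np.log1p(out.data)
    else:
        out = np.log1p(X.values * (target_sum / totals)[:, None])
    return ExpressionMatrix(out, list(X.spot_ids), list(X.gene_ids), LayerTag.LOG)
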