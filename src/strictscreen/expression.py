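"""Single-cell expression matrices with cell-type annotation.

The in-memory container is an :class:`anndata.AnnData` (cells x genes) with
the cell-type label in ``obs["cell_type"]``, wrapped in a thin
:class:`ExpressionStore` that enforces this package's contracts: non-negative
finite values, exactly one annotation per retained cell, and uppercase gene
symbols for case-insensitive panel matching.

Input formats: MatrixMarket sparse triplets (the common genes-as-rows
convention; transposed on load) with one-column gene and cell ID files, or a
dense delimited table with a gene-symbol header row and a cell-ID first
column. Annotations are a two-column table (cell_id, cell_type).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

log = logging.getLogger(__name__)

__all__ = ["ExpressionStore", "CellTypeMeans", "load_matrix", "normalize_cpm", "mean_by_celltype"]

#: Annotation labels treated as missing; cells carrying them are dropped.
_MISSING_LABELS = {"", "NA", "N/A", "NAN", "NONE"}


@dataclass
class CellTypeMeans:
    """Per-cell-type mean expression.

    Attributes
    ----------
    means
        cell types x genes DataFrame of arithmetic mean expression.
    n_cells
        Series of cell counts per retained cell type.
    """

    means: pd.DataFrame
    n_cells: pd.Series

    def __post_init__(self) -> None:
        if (self.n_cells < 1).any():
            raise ValueError("every retained cell type needs >= 1 cell")
        if (self.means.to_numpy() < 0).any():
            raise ValueError("negative mean expression")


class ExpressionStore:
    """cells x genes expression values plus a cell-type label per cell."""

    def __init__(self, adata: ad.AnnData):
        if "cell_type" not in adata.obs:
            raise ValueError('annotation missing: obs["cell_type"]')
        X = adata.X
        data = X.data if sp.issparse(X) else np.asarray(X)
        if not np.all(np.isfinite(data)):
            raise ValueError("expression values must be finite")
        if data.size and data.min() < 0:
            raise ValueError("expression values must be non-negative")
        adata.var_names = [str(g).strip().upper() for g in adata.var_names]
        self.adata = adata

    # -- convenience views -------------------------------------------------
    @property
    def gene_ids(self) -> pd.Index:
        return self.adata.var_names

    @property
    def cell_ids(self) -> pd.Index:
        return self.adata.obs_names

    @property
    def cell_types(self) -> pd.Series:
        return self.adata.obs["cell_type"]

    @property
    def n_cells(self) -> int:
        return self.adata.n_obs

    @property
    def n_genes(self) -> int:
        return self.adata.n_vars

    def values(self, dense: bool = False) -> np.ndarray | sp.spmatrix:
        X = self.adata.X
        if dense and sp.issparse(X):
            return np.asarray(X.todense())
        return X

    @classmethod
    def from_arrays(
        cls,
        values,
        gene_ids,
        cell_ids,
        cell_types: dict[str, str] | pd.Series,
    ) -> "ExpressionStore":
        """Build a store from raw arrays and a cell -> cell-type mapping.

        Cells without an annotation (or labelled NA) are dropped with a
        logged count; an error is raised if none remain.
        """
        values = values if sp.issparse(values) else np.asarray(values, dtype=float)
        gene_ids = pd.Index([str(g) for g in gene_ids])
        cell_ids = pd.Index([str(c) for c in cell_ids])
        if values.shape != (len(cell_ids), len(gene_ids)):
            raise ValueError(
                f"matrix shape {values.shape} does not match "
                f"{len(cell_ids)} cells x {len(gene_ids)} genes"
            )
        ann = pd.Series(dict(cell_types) if not isinstance(cell_types, pd.Series) else cell_types)
        ann.index = ann.index.astype(str)
        ann = ann.astype(str).str.strip()
        ann = ann[~ann.str.upper().isin(_MISSING_LABELS)]
        keep = cell_ids.isin(ann.index)
        n_drop = int((~keep).sum())
        if n_drop:
            log.warning("dropping %d cell(s) without annotation", n_drop)
        if not keep.any():
            raise ValueError("no annotated cells")
        kept_ids = cell_ids[keep]
        X = values[np.flatnonzero(keep), :] if sp.issparse(values) else values[keep, :]
        obs = pd.DataFrame({"cell_type": ann.loc[kept_ids].to_numpy()}, index=kept_ids)
        adata = ad.AnnData(X=sp.csr_matrix(X) if sp.issparse(X) else X, obs=obs,
                           var=pd.DataFrame(index=gene_ids))
        return cls(adata)


def _read_id_file(path: str | Path) -> list[str]:
    return [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]


def _read_annotation(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise ValueError("annotation must have two columns: cell_id, cell_type")
    if df.iloc[0, 0].strip().lower() in {"cell_id", "cell", "barcode"}:
        df = df.iloc[1:]
    return pd.Series(df.iloc[:, 1].to_numpy(), index=df.iloc[:, 0].str.strip().to_numpy())


def load_matrix(
    matrix_path: str | Path,
    genes_path: str | Path | None = None,
    cells_path: str | Path | None = None,
    annotation_path: str | Path | None = None,
    *,
    orientation: str = "genes-as-rows",
) -> ExpressionStore:
    """Read an expression matrix and annotation from disk.

    ``matrix_path`` may be a MatrixMarket ``.mtx`` file (with ``genes_path``
    and ``cells_path`` one-ID-per-line files) or a dense TSV/CSV whose header
    row holds gene symbols and whose first column holds cell IDs.
    ``orientation`` declares the MTX layout (``"genes-as-rows"``, the common
    convention, or ``"cells-as-rows"``).
    """
    matrix_path = Path(matrix_path)
    if orientation not in {"genes-as-rows", "cells-as-rows"}:
        raise ValueError(f"unknown orientation {orientation!r}")
    if annotation_path is None:
        raise ValueError("annotation_path is required")
    if matrix_path.suffix == ".mtx":
        if genes_path is None or cells_path is None:
            raise ValueError("MTX input needs genes_path and cells_path")
        m = sp.csr_matrix(scipy.io.mmread(matrix_path))
        if orientation == "genes-as-rows":
            m = m.T.tocsr()
        genes = _read_id_file(genes_path)
        cells = _read_id_file(cells_path)
    else:
        sep = "," if matrix_path.suffix == ".csv" else "\t"
        df = pd.read_csv(matrix_path, sep=sep, index_col=0)
        m = df.to_numpy(dtype=float)
        genes = [str(g) for g in df.columns]
        cells = [str(c) for c in df.index]
    if m.shape[1] != len(genes):
        raise ValueError(f"genes file lists {len(genes)} genes but matrix has {m.shape[1]} columns")
    if m.shape[0] != len(cells):
        raise ValueError(f"cells file lists {len(cells)} cells but matrix has {m.shape[0]} rows")
    return ExpressionStore.from_arrays(m, genes, cells, _read_annotation(annotation_path))


def normalize_cpm(store: ExpressionStore) -> ExpressionStore:
    """Counts-per-million normalization: each cell's values sum to 1e6.

    Cells with zero total counts are dropped (logged). Already-normalized
    input is unchanged (the operation is idempotent).
    """
    X = store.adata.X
    totals = np.asarray(X.sum(axis=1)).ravel()
    keep = totals > 0
    if not keep.any():
        raise ValueError("all cells have zero total counts")
    if not keep.all():
        log.warning("dropping %d all-zero cell(s) before CPM", int((~keep).sum()))
    sub = store.adata[keep].copy()
    scale = 1e6 / totals[keep]
    if sp.issparse(sub.X):
        sub.X = sp.diags(scale) @ sub.X.tocsr()
    else:
        sub.X = np.asarray(sub.X) * scale[:, None]
    return ExpressionStore(sub)


def mean_by_celltype(store: ExpressionStore, min_cells_per_type: int = 1) -> CellTypeMeans:
    """Arithmetic mean expression per cell type.

    Cell types with fewer than ``min_cells_per_type`` cells are dropped
    (logged); the mean is over each type's own cells only.
    """
    labels = store.cell_types
    counts = labels.value_counts()
    kept = counts[counts >= min_cells_per_type]
    if kept.empty:
        raise ValueError("no cell type meets min_cells_per_type")
    if len(kept) < len(counts):
        log.warning("dropping %d cell type(s) below %d cells",
                    len(counts) - len(kept), min_cells_per_type)
    X = store.adata.X
    rows = {}
    for ct in sorted(kept.index):
        mask = (labels == ct).to_numpy()
        sub = X[np.flatnonzero(mask), :] if sp.issparse(X) else X[mask, :]
        rows[ct] = np.asarray(sub.mean(axis=0)).ravel()
    means = pd.DataFrame.from_dict(rows, orient="index", columns=store.gene_ids)
    return CellTypeMeans(means=means, n_cells=kept.sort_index())
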