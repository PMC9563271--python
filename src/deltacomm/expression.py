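"""Expression matrix handling: loading, library-size log normalization,
condition fold changes, and (complex) ligand/receptor expression summaries.

The container is a thin wrapper over :class:`anndata.AnnData` (cells x genes)
with two mandatory per-cell labels, ``cell_type`` and ``condition`` (exactly
``disease`` and ``control``).  On disk, counts are CellRanger-style sparse
MatrixMarket (genes x cells, 1-based indices) with ``genes.tsv`` /
``barcodes.tsv`` side files, or a dense TSV with gene rows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

CONDITIONS = ("disease", "control")


@dataclass
class GroupSummary:
    cell_type: str
    gene: str
    statistic: str  # "mean" or "quantile:q"
    value: float


@dataclass
class FoldChangeTable:
    """Per-gene log2 fold change (disease vs control) within one receiver
    cell type, on normalized means with pseudocount ``epsilon``."""

    cell_type: str
    fc: pd.Series  # index: gene symbol
    epsilon: float


class AnnotatedMatrix:
    """Genes-by-cells expression with per-cell ``cell_type`` and ``condition``.

    Wraps an AnnData (cells x genes).  ``normalized`` is False for raw counts
    and set by :meth:`normalize_log_scaled`.
    """

    def __init__(self, adata: ad.AnnData):
        for col in ("cell_type", "condition"):
            if col not in adata.obs.columns:
                raise ValueError(f"cell metadata must provide {col!r}")
            if adata.obs[col].isna().any():
                bad = adata.obs.index[adata.obs[col].isna()].tolist()
                raise ValueError(f"cells missing {col!r}: {bad[:5]}")
        levels = set(adata.obs["condition"].unique())
        if levels != set(CONDITIONS):
            raise ValueError(
                f"condition must have exactly the levels {CONDITIONS}, got {sorted(levels)}"
            )
        if adata.var_names.duplicated().any():
            dup = adata.var_names[adata.var_names.duplicated()].tolist()
            raise ValueError(f"duplicate gene symbols: {dup[:5]}")
        adata.uns.setdefault("normalized", False)
        self.adata = adata

    # -- basic accessors ---------------------------------------------------
    @property
    def genes(self) -> pd.Index:
        return self.adata.var_names

    @property
    def cells(self) -> pd.Index:
        return self.adata.obs_names

    @property
    def cell_meta(self) -> pd.DataFrame:
        return self.adata.obs

    @property
    def normalized(self) -> bool:
        return bool(self.adata.uns["normalized"])

    @property
    def cell_types(self) -> list[str]:
        return sorted(self.adata.obs["cell_type"].unique())

    def cell_mask(self, cell_type: str | None = None, condition: str | None = None) -> np.ndarray:
        mask = np.ones(self.adata.n_obs, dtype=bool)
        if cell_type is not None:
            mask &= (self.adata.obs["cell_type"] == cell_type).to_numpy()
        if condition is not None:
            mask &= (self.adata.obs["condition"] == condition).to_numpy()
        return mask

    def gene_values(self, gene: str, mask: np.ndarray | None = None) -> np.ndarray:
        """Dense per-cell vector for one gene (0 everywhere if absent)."""
        n = self.adata.n_obs if mask is None else int(mask.sum())
        if gene not in self.adata.var_names:
            return np.zeros(n)
        col = self.adata[:, gene].X
        v = np.asarray(col.todense()).ravel() if sp.issparse(col) else np.asarray(col).ravel()
        return v[mask] if mask is not None else v

    def matrix(self, genes: list[str], mask: np.ndarray | None = None) -> np.ndarray:
        """Dense (cells x genes) block for several genes; absent genes are 0."""
        present = [g for g in genes if g in self.adata.var_names]
        sub = self.adata[:, present].X if present else None
        if sub is not None and sp.issparse(sub):
            sub = np.asarray(sub.todense())
        elif sub is not None:
            sub = np.asarray(sub)
        n = self.adata.n_obs
        out = np.zeros((n, len(genes)))
        if present:
            pos = {g: i for i, g in enumerate(present)}
            for j, g in enumerate(genes):
                if g in pos:
                    out[:, j] = sub[:, pos[g]]
        return out[mask] if mask is not None else out

    def copy(self) -> "AnnotatedMatrix":
        return AnnotatedMatrix(self.adata.copy())


def load_expression(matrix_path, genes_path=None, barcodes_path=None, meta_path=None) -> AnnotatedMatrix:
    """Assemble an AnnotatedMatrix from disk (raw counts).

    ``matrix_path`` is either a MatrixMarket file (genes x cells, with
    ``genes_path`` and ``barcodes_path`` side files) or a dense TSV with gene
    rows and barcode columns.  ``meta_path`` is a TSV with columns
    ``barcode``, ``cell_type``, ``condition`` covering every barcode.
    """
    matrix_path = Path(matrix_path)
    if matrix_path.suffix == ".mtx":
        if genes_path is None or barcodes_path is None:
            raise ValueError("MTX input requires genes and barcodes side files")
        X = scipy.io.mmread(str(matrix_path)).tocsr()  # genes x cells
        genes = pd.read_csv(genes_path, sep="\t", header=None)[0].astype(str)
        barcodes = pd.read_csv(barcodes_path, sep="\t", header=None)[0].astype(str)
        if X.shape != (len(genes), len(barcodes)):
            raise ValueError(
                f"dimension mismatch: matrix {X.shape}, {len(genes)} genes, {len(barcodes)} barcodes"
            )
        adata = ad.AnnData(
            X=X.T.tocsr().astype(np.float64),
            obs=pd.DataFrame(index=barcodes.values),
            var=pd.DataFrame(index=genes.values),
        )
    else:
        dense = pd.read_csv(matrix_path, sep="\t", index_col=0)
        adata = ad.AnnData(
            X=np.asarray(dense.values, dtype=np.float64).T,
            obs=pd.DataFrame(index=dense.columns.astype(str)),
            var=pd.DataFrame(index=dense.index.astype(str)),
        )
    if meta_path is None:
        raise ValueError("cell metadata TSV is required")
    meta = pd.read_csv(meta_path, sep="\t", dtype=str)
    for col in ("barcode", "cell_type", "condition"):
        if col not in meta.columns:
            raise ValueError(f"metadata missing column {col!r}")
    meta = meta.set_index("barcode")
    missing = [b for b in adata.obs_names if b not in meta.index]
    if missing:
        raise ValueError(f"metadata missing barcodes: {missing[:5]}")
    adata.obs["cell_type"] = meta.loc[adata.obs_names, "cell_type"].values
    adata.obs["condition"] = meta.loc[adata.obs_names, "condition"].values
    if np.asarray(adata.X.min() if not sp.issparse(adata.X) else adata.X.min()) < 0:
        raise ValueError("raw counts must be non-negative")
    adata.uns["normalized"] = False
    return AnnotatedMatrix(adata)


def normalize_log_scaled(matrix: AnnotatedMatrix, scale: float = 1e4) -> AnnotatedMatrix:
    """Library-size normalization: value <- log2(1 + scale * count / cell_total).

    ``scale=1e4`` matches the common per-10k convention; ``scale=1e5``
    reproduces log2(CPM/10 + 1).  Cells with zero total are rejected.
    """
    if matrix.normalized:
        raise ValueError("matrix is already normalized")
    if scale <= 0:
        raise ValueError("scale must be positive")
    out = matrix.copy()
    X = out.adata.X
    totals = np.asarray(X.sum(axis=1)).ravel()
    zero = totals == 0
    if zero.any():
        raise ValueError(f"cells with zero total counts: {out.cells[zero].tolist()[:5]}")
    if sp.issparse(X):
        X = X.tocsr(copy=True).astype(np.float64)
        # scale rows then log-transform the stored (nonzero) entries
        inv = sp.diags(scale / totals)
        X = inv @ X
        X.data = np.log2(1.0 + X.data)
        out.adata.X = X
    else:
        out.adata.X = np.log2(1.0 + scale * np.asarray(X, dtype=np.float64) / totals[:, None])
    out.adata.uns["normalized"] = True
    out.adata.uns["normalize_scale"] = float(scale)
    return out


def complex_expression(subunit_values) -> float:
    """Geometric mean of subunit expression values; 0 if any subunit is 0."""
    v = np.asarray(list(subunit_values), dtype=float)
    if v.size == 0:
        raise ValueError("subunit list must be non-empty")
    if (v < 0).any():
        raise ValueError("expression values must be non-negative")
    if (v == 0).any():
        return 0.0
    return float(np.exp(np.mean(np.log(v))))


def complex_expression_per_cell(matrix: AnnotatedMatrix, subunits, mask=None) -> np.ndarray:
    """Per-cell geometric mean over the subunits of a complex (vectorized)."""
    block = matrix.matrix(list(subunits), mask=mask)  # cells x subunits
    if block.shape[1] == 1:
        return block[:, 0]
    nonzero = (block > 0).all(axis=1)
    out = np.zeros(block.shape[0])
    if nonzero.any():
        out[nonzero] = np.exp(np.mean(np.log(block[nonzero]), axis=1))
    return out


def group_summary(
    matrix: AnnotatedMatrix,
    cell_type: str,
    gene_or_complex,
    statistic: str = "mean",
    q: float | None = None,
    condition_scope: str = "all",
) -> GroupSummary:
    """Summary statistic of a gene or complex over one cell type's cells.

    ``statistic`` is ``mean`` or ``quantile`` (with ``q``); the quantile uses
    lower interpolation (the order statistic at ceil(q*n)).  For complexes the
    per-cell geometric mean is computed first.  Absent genes contribute 0
    (with a warning).
    """
    subunits = [gene_or_complex] if isinstance(gene_or_complex, str) else list(gene_or_complex)
    condition = None if condition_scope == "all" else condition_scope
    mask = matrix.cell_mask(cell_type=cell_type, condition=condition)
    if not mask.any():
        raise ValueError(f"no cells for cell_type={cell_type!r}, scope={condition_scope!r}")
    absent = [g for g in subunits if g not in matrix.genes]
    if absent:
        warnings.warn(f"genes absent from matrix treated as 0: {absent}")
    values = complex_expression_per_cell(matrix, subunits, mask=mask)
    if statistic == "mean":
        val, label = float(values.mean()), "mean"
    elif statistic == "quantile":
        if q is None or not (0 < q <= 1):
            raise ValueError("quantile statistic requires q in (0, 1]")
        k = int(np.ceil(q * values.size))  # 1-based order statistic, lower interpolation
        val = float(np.sort(values)[k - 1])
        label = f"quantile:{q}"
    else:
        raise ValueError(f"unknown statistic {statistic!r}")
    name = "+".join(sorted(subunits))
    return GroupSummary(cell_type=cell_type, gene=name, statistic=label, value=val)


def compute_fold_changes(
    matrix: AnnotatedMatrix, receiver_cell_type: str, epsilon: float = 0.01
) -> FoldChangeTable:
    """Per-gene log2((mean_disease + eps) / (mean_control + eps)) over the
    receiver cell type's cells, on the normalized matrix."""
    if not matrix.normalized:
        raise ValueError("fold changes require a normalized matrix")
    means = {}
    for cond in CONDITIONS:
        mask = matrix.cell_mask(cell_type=receiver_cell_type, condition=cond)
        if not mask.any():
            raise ValueError(
                f"condition {cond!r} absent within cell type {receiver_cell_type!r}"
            )
        X = matrix.adata.X[mask]
        means[cond] = np.asarray(X.mean(axis=0)).ravel()
    fc = np.log2((means["disease"] + epsilon) / (means["control"] + epsilon))
    return FoldChangeTable(
        cell_type=receiver_cell_type,
        fc=pd.Series(fc, index=matrix.genes, name="log2fc"),
        epsilon=epsilon,
    )
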