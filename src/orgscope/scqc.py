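"""Cell-level quality control and normalization for UMI count matrices.

Cells are filtered on three per-cell metrics — total UMI, number of
detected genes, and mitochondrial transcript fraction — with strict
("less than"/"more than") boundaries, then depth-normalised to counts per
million and log2(CPM + 1) transformed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

__all__ = [
    "CountMatrix",
    "QcThresholds",
    "compute_cell_metrics",
    "apply_qc",
    "cpm_log_normalize",
    "read_counts_dir",
    "write_counts_dir",
]


@dataclass
class CountMatrix:
    """Genes x cells UMI counts with identifiers.

    ``X`` is a scipy sparse matrix (genes on rows, cells on columns) of
    non-negative integers; ``genes`` and ``barcodes`` are unique labels.
    """

    X: sp.spmatrix
    genes: pd.Index
    barcodes: pd.Index

    def __post_init__(self) -> None:
        self.X = sp.csr_matrix(self.X)
        self.genes = pd.Index(self.genes)
        self.barcodes = pd.Index(self.barcodes)
        if self.X.shape != (len(self.genes), len(self.barcodes)):
            raise ValueError("matrix shape does not match gene/barcode labels")
        if not self.genes.is_unique or not self.barcodes.is_unique:
            raise ValueError("gene and barcode identifiers must be unique")
        if self.X.nnz and self.X.data.min() < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n_genes(self) -> int:
        return self.X.shape[0]

    @property
    def n_cells(self) -> int:
        return self.X.shape[1]

    def subset_cells(self, mask) -> "CountMatrix":
        mask = np.asarray(mask)
        return CountMatrix(self.X[:, mask], self.genes, self.barcodes[mask])


@dataclass
class QcThresholds:
    """Strict-inequality filter bounds; boundary values are kept."""

    umi_min: int = 1200
    umi_max: int = 25000
    gene_min: int = 600
    gene_max: int = 6000
    mito_max: float = 0.10

    def __post_init__(self) -> None:
        if self.umi_min >= self.umi_max or self.gene_min >= self.gene_max:
            raise ValueError("min thresholds must be below max thresholds")
        if not (0 < self.mito_max <= 1):
            raise ValueError("mito_max must lie in (0, 1]")


def compute_cell_metrics(counts: CountMatrix, mito_genes) -> pd.DataFrame:
    """Per-cell total UMI, detected-gene count and mitochondrial fraction.

    ``mito_genes`` may be an explicit list or a prefix string such as
    ``"MT-"``.  Mito fraction is mito UMI / total UMI, defined as 0 (and
    flagged) for zero-total cells.
    """
    if counts.n_genes == 0 or counts.n_cells == 0:
        raise ValueError("empty count matrix")
    if isinstance(mito_genes, str):
        mito_mask = counts.genes.str.startswith(mito_genes)
    else:
        mito_genes = list(mito_genes)
        missing = sorted(set(mito_genes) - set(counts.genes))
        if missing:
            warnings.warn(
                f"{len(missing)} mito genes not in the matrix are ignored: {missing[:5]}",
                stacklevel=2,
            )
        mito_mask = counts.genes.isin(mito_genes)
    X = counts.X
    total = np.asarray(X.sum(axis=0)).ravel()
    n_genes = np.asarray((X > 0).sum(axis=0)).ravel()
    mito = np.asarray(X[np.asarray(mito_mask)].sum(axis=0)).ravel()
    zero_total = total == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(zero_total, 0.0, mito / np.where(zero_total, 1, total))
    return pd.DataFrame(
        {
            "total_umi": total.astype(int),
            "n_genes": n_genes.astype(int),
            "mito_frac": frac,
            "zero_total": zero_total,
        },
        index=counts.barcodes,
    )


def apply_qc(metrics: pd.DataFrame, thresholds: QcThresholds | None = None):
    """Keep mask plus a per-criterion removal report.

    A cell is removed iff UMI < umi_min OR UMI > umi_max OR genes <
    gene_min OR genes > gene_max OR mito fraction > mito_max; boundary
    values survive under the strict inequalities.
    """
    thr = thresholds or QcThresholds()
    fail = {
        "umi_low": metrics["total_umi"] < thr.umi_min,
        "umi_high": metrics["total_umi"] > thr.umi_max,
        "gene_low": metrics["n_genes"] < thr.gene_min,
        "gene_high": metrics["n_genes"] > thr.gene_max,
        "mito_high": metrics["mito_frac"] > thr.mito_max,
    }
    removed = np.logical_or.reduce([f.to_numpy() for f in fail.values()])
    keep = pd.Series(~removed, index=metrics.index, name="keep")
    report = {name: int(f.sum()) for name, f in fail.items()}
    report["n_input"] = len(metrics)
    report["n_removed"] = int(removed.sum())
    report["n_kept"] = int(keep.sum())
    return keep, report


def cpm_log_normalize(counts: CountMatrix | np.ndarray) -> np.ndarray:
    """log2(CPM + 1) normalisation: per cell, count/total x 1e6, then log2.

    Every cell must have total UMI > 0 (QC-filter first).  Returns a dense
    genes x cells float array.
    """
    X = counts.X.toarray() if isinstance(counts, CountMatrix) else np.asarray(counts, float)
    totals = X.sum(axis=0)
    if np.any(totals <= 0):
        bad = int(np.flatnonzero(totals <= 0)[0])
        raise ValueError(f"cell {bad} has zero total UMI; filter before normalising")
    cpm = X / totals * 1e6
    return np.log2(cpm + 1.0)


def read_counts_dir(path) -> tuple[CountMatrix, pd.DataFrame | None]:
    """Read a CellRanger-layout directory: matrix.mtx + features.tsv +
    barcodes.tsv, plus metadata.csv when present."""
    path = Path(path)
    X = sp.csr_matrix(mmread(path / "matrix.mtx"))
    genes = pd.read_csv(path / "features.tsv", sep="\t", header=None)[0]
    barcodes = pd.read_csv(path / "barcodes.tsv", sep="\t", header=None)[0]
    meta = None
    meta_path = path / "metadata.csv"
    if meta_path.exists():
        meta = pd.read_csv(meta_path, index_col=0)
    return CountMatrix(X, genes, barcodes), meta


def write_counts_dir(path, counts: CountMatrix, metadata: pd.DataFrame | None = None) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    mmwrite(path / "matrix.mtx", sp.coo_matrix(counts.X))
    counts.genes.to_series().to_csv(path / "features.tsv", sep="\t", header=False, index=False)
    counts.barcodes.to_series().to_csv(path / "barcodes.tsv", sep="\t", header=False, index=False)
    if metadata is not None:
        metadata.to_csv(path / "metadata.csv")
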