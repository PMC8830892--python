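"""Readers and writers for sparse UMI counts and per-cell metadata.

Counts travel as Matrix Market triplet files (genes as rows, the 10x
convention) with ``features.tsv`` / ``barcodes.tsv`` sidecars; cell
metadata travels as a tab-separated table keyed by barcode.  Reads are
gzip-transparent.  Round trips are lossless.
"""

from __future__ import annotations

import gzip
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "CountMatrix",
    "read_counts",
    "write_counts",
    "read_cell_table",
    "write_cell_table",
    "validate_cell_table",
    "align_counts_cells",
]

#: columns of a cell table that are always present
REQUIRED_CELL_COLUMNS = ("barcode",)

#: prefix of topic-loading columns in a cell table
TOPIC_PREFIX = "topic_"

#: prefix of embedding-coordinate columns in a cell table
EMBEDDING_PREFIX = "dim_"


@dataclass
class CountMatrix:
    """Sparse genes x cells matrix of non-negative integer UMI counts."""

    values: sp.csr_matrix
    gene_ids: np.ndarray
    barcodes: np.ndarray

    def __post_init__(self) -> None:
        self.values = sp.csr_matrix(self.values)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.barcodes = np.asarray(self.barcodes, dtype=object)
        n_genes, n_cells = self.values.shape
        if len(self.gene_ids) != n_genes:
            raise ValueError(
                f"gene_ids has {len(self.gene_ids)} entries but matrix has "
                f"{n_genes} rows"
            )
        if len(self.barcodes) != n_cells:
            raise ValueError(
                f"barcodes has {len(self.barcodes)} entries but matrix has "
                f"{n_cells} columns"
            )
        if len(set(self.gene_ids)) != n_genes:
            raise ValueError("duplicate gene ids")
        if len(set(self.barcodes)) != n_cells:
            raise ValueError("duplicate barcodes")
        if self.values.nnz and self.values.data.min() < 0:
            raise ValueError("negative counts are not allowed")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def subset_cells(self, mask_or_idx) -> "CountMatrix":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return CountMatrix(self.values[:, idx], self.gene_ids, self.barcodes[idx])

    def subset_genes(self, mask_or_idx) -> "CountMatrix":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return CountMatrix(self.values[idx, :], self.gene_ids[idx], self.barcodes)

    def total_counts(self) -> int:
        return int(self.values.sum())


def _opener(path: Path, mode: str):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def _find(path: Path, stem: str) -> Path:
    """Locate ``stem`` or ``stem + '.gz'`` inside ``path``."""
    for cand in (path / stem, path / (stem + ".gz")):
        if cand.exists():
            return cand
    raise FileNotFoundError(f"{stem}[.gz] not found in {path}")


def read_counts(path: str | os.PathLike) -> CountMatrix:
    """Read a 10x-style directory (matrix.mtx + features.tsv + barcodes.tsv)."""
    path = Path(path)
    with _opener(_find(path, "matrix.mtx"), "rb") as fh:
        mat = sp.csr_matrix(scipy.io.mmread(fh))
    genes = pd.read_csv(_find(path, "features.tsv"), sep="\t", header=None)[0].to_numpy(object)
    barcodes = pd.read_csv(_find(path, "barcodes.tsv"), sep="\t", header=None)[0].to_numpy(object)
    if mat.shape != (len(genes), len(barcodes)):
        raise ValueError(
            f"matrix is {mat.shape} but sidecars declare "
            f"({len(genes)} genes, {len(barcodes)} barcodes)"
        )
    return CountMatrix(mat, genes, barcodes)


def write_counts(counts: CountMatrix, path: str | os.PathLike) -> None:
    """Write ``counts`` as matrix.mtx / features.tsv / barcodes.tsv."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(path / "matrix.mtx"), sp.coo_matrix(counts.values))
    pd.Series(counts.gene_ids).to_csv(path / "features.tsv", sep="\t", header=False, index=False)
    pd.Series(counts.barcodes).to_csv(path / "barcodes.tsv", sep="\t", header=False, index=False)


def validate_cell_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check cell-table invariants; returns the table unchanged on success."""
    if "barcode" not in table.columns:
        raise ValueError("cell table must have a 'barcode' column")
    if table["barcode"].duplicated().any():
        dups = table.loc[table["barcode"].duplicated(), "barcode"].tolist()[:5]
        raise ValueError(f"duplicated barcodes, e.g. {dups}")
    topic_cols = [c for c in table.columns if c.startswith(TOPIC_PREFIX)]
    if topic_cols:
        sums = table[topic_cols].sum(axis=1).to_numpy(float)
        if not np.allclose(sums, 1.0, atol=1e-8):
            bad = int(np.argmax(np.abs(sums - 1.0)))
            raise ValueError(
                f"topic loadings must sum to 1 per cell; row {bad} sums to {sums[bad]:.6g}"
            )
    if "mito_fraction" in table.columns:
        mf = table["mito_fraction"].to_numpy(float)
        if np.nanmin(mf) < 0 or np.nanmax(mf) > 1:
            raise ValueError("mito_fraction must lie in [0, 1]")
    return table


def read_cell_table(path: str | os.PathLike) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", dtype={"barcode": str})
    return validate_cell_table(table)


def write_cell_table(table: pd.DataFrame, path: str | os.PathLike) -> None:
    validate_cell_table(table)
    table.to_csv(path, sep="\t", index=False)


def align_counts_cells(counts: CountMatrix, table: pd.DataFrame) -> None:
    """Fail loudly when the barcode sets of a matrix and a table differ."""
    a = set(counts.barcodes)
    b = set(table["barcode"])
    if a != b:
        only_a = sorted(a - b)[:3]
        only_b = sorted(b - a)[:3]
        raise ValueError(
            "count matrix and cell table disagree on barcodes: "
            f"only in matrix {only_a}, only in table {only_b}"
        )
    if list(counts.barcodes) != list(table["barcode"]):
        raise ValueError("count matrix and cell table barcodes are ordered differently")
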