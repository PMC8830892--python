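"""Cell- and gene-level threshold filters.

Two cell-QC profiles are provided.  The primary profile keeps cells with
a mitochondrial read fraction between 3% and 20% (inclusive) that express
more than 1500 genes.  The additional-lines profile removes cells with
more than 15% or less than 3% mitochondrial reads or fewer than 1000
unique genes expressed.  Whether each bound is strict or inclusive is
configurable because the original thresholds are stated in prose.

Gene filters: keep genes expressed in at least 20% of cells in at least
one cluster (used before pseudobulk differential expression and variance
partitioning), genes expressed in a minimum number of cells, or genes
with minimum pseudobulk support (at least 10 counts in one sample and at
least 15 in total).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import CountMatrix

__all__ = [
    "QCProfile",
    "PRIMARY_PROFILE",
    "ADDITIONAL_LINES_PROFILE",
    "compute_qc_metrics",
    "filter_cells",
    "filter_genes_cluster_fraction",
    "filter_genes_min_support",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class QCProfile:
    """Thresholds for cell-level QC.

    ``*_inclusive`` flags say whether a cell sitting exactly on the bound
    is kept.
    """

    mito_min: float = 0.03
    mito_max: float = 0.20
    min_genes: int = 1500
    mito_min_inclusive: bool = True
    mito_max_inclusive: bool = True
    min_genes_inclusive: bool = False  # "more than 1500" is strict

    def __post_init__(self) -> None:
        if not 0 <= self.mito_min < self.mito_max <= 1:
            raise ValueError("require 0 <= mito_min < mito_max <= 1")
        if self.min_genes < 0:
            raise ValueError("min_genes must be non-negative")

    def keep(self, mito_fraction: np.ndarray, n_genes: np.ndarray) -> np.ndarray:
        lo = mito_fraction >= self.mito_min if self.mito_min_inclusive else mito_fraction > self.mito_min
        hi = mito_fraction <= self.mito_max if self.mito_max_inclusive else mito_fraction < self.mito_max
        ng = n_genes >= self.min_genes if self.min_genes_inclusive else n_genes > self.min_genes
        return lo & hi & ng


#: mito in [3%, 20%], more than 1500 genes
PRIMARY_PROFILE = QCProfile()

#: remove mito > 15%, mito < 3%, or fewer than 1000 genes (keep >= 1000)
ADDITIONAL_LINES_PROFILE = QCProfile(
    mito_min=0.03,
    mito_max=0.15,
    min_genes=1000,
    min_genes_inclusive=True,
)


def compute_qc_metrics(counts: CountMatrix, mito_prefix: str = "MT-") -> pd.DataFrame:
    """Per-cell (n_genes_detected, mito_fraction, flag for empty cells).

    ``n_genes_detected`` counts genes with a positive count;
    ``mito_fraction`` is mitochondrial counts over total counts, defined
    as 0 for cells with zero total (flagged in ``zero_total``).
    """
    mat = counts.values.tocsc()
    n_genes = np.asarray((mat > 0).sum(axis=0)).ravel()
    total = np.asarray(mat.sum(axis=0)).ravel().astype(float)
    is_mito = np.array([str(g).startswith(mito_prefix) for g in counts.gene_ids])
    mito = np.asarray(mat[is_mito, :].sum(axis=0)).ravel().astype(float) if is_mito.any() else np.zeros_like(total)
    zero = total == 0
    if zero.any():
        logger.warning("%d cells have zero total counts; mito_fraction set to 0", int(zero.sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(zero, 0.0, mito / np.where(zero, 1.0, total))
    return pd.DataFrame(
        {
            "barcode": counts.barcodes,
            "n_genes_detected": n_genes.astype(int),
            "mito_fraction": mito_frac,
            "zero_total": zero,
        }
    )


def filter_cells(
    counts: CountMatrix,
    cell_table: pd.DataFrame,
    profile: QCProfile = PRIMARY_PROFILE,
    mito_prefix: str = "MT-",
) -> tuple[CountMatrix, pd.DataFrame]:
    """Apply a QC profile; returns the surviving (counts, cell_table).

    Barcode order is preserved.  An empty result is a warning, not an
    error.
    """
    metrics = compute_qc_metrics(counts, mito_prefix=mito_prefix)
    keep = profile.keep(
        metrics["mito_fraction"].to_numpy(), metrics["n_genes_detected"].to_numpy()
    )
    if not keep.any():
        warnings.warn("QC removed every cell", stacklevel=2)
    kept_barcodes = set(metrics.loc[keep, "barcode"])
    out_counts = counts.subset_cells(keep)
    out_table = cell_table[cell_table["barcode"].isin(kept_barcodes)].reset_index(drop=True)
    return out_counts, out_table


def filter_genes_cluster_fraction(
    counts: CountMatrix,
    clusters: pd.Series | np.ndarray,
    min_fraction: float = 0.2,
    exclude_ribosomal: bool = False,
) -> np.ndarray:
    """Boolean gene mask: expressed in >= min_fraction of cells of some cluster.

    ``exclude_ribosomal`` additionally drops genes with an RPS/RPL name
    prefix (used for the expression heatmap, which omits ribosomal genes).
    """
    clusters = np.asarray(clusters)
    if len(clusters) != counts.n_cells:
        raise ValueError("one cluster label per cell is required")
    mask = np.zeros(counts.n_genes, dtype=bool)
    detected = counts.values > 0
    for cl in pd.unique(clusters):
        idx = np.flatnonzero(clusters == cl)
        if len(idx) == 0:
            raise ValueError(f"cluster {cl!r} has no cells")
        frac = np.asarray(detected[:, idx].sum(axis=1)).ravel() / len(idx)
        mask |= frac >= min_fraction
    if exclude_ribosomal:
        ribo = np.array(
            [str(g).startswith(("RPS", "RPL")) for g in counts.gene_ids]
        )
        mask &= ~ribo
    return mask


def filter_genes_min_support(
    values,
    mode: str,
    min_cells: int = 10,
    per_sample: int = 10,
    total: int = 15,
) -> np.ndarray:
    """Boolean gene mask under a minimum-support rule.

    mode="min_cells": gene detected (count > 0) in at least ``min_cells``
    cells.  mode="pseudobulk_counts": gene has at least ``per_sample``
    counts in some sample AND at least ``total`` counts across samples.
    ``values`` is a genes x (cells or samples) matrix (sparse or dense) or
    a CountMatrix.
    """
    mat = values.values if isinstance(values, CountMatrix) else values
    if mode == "min_cells":
        det = mat > 0
        n = np.asarray(det.sum(axis=1)).ravel()
        return n >= min_cells
    if mode == "pseudobulk_counts":
        if sp.issparse(mat):
            max_per = np.asarray(mat.max(axis=1).todense()).ravel()
            tot = np.asarray(mat.sum(axis=1)).ravel()
        else:
            arr = np.asarray(mat)
            max_per = arr.max(axis=1)
            tot = arr.sum(axis=1)
        return (max_per >= per_sample) & (tot >= total)
    raise ValueError(f"unknown mode {mode!r}; expected 'min_cells' or 'pseudobulk_counts'")
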