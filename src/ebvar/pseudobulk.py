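"""Pseudobulk aggregation, TMM normalization factors, voom precision weights.

Pseudobulk expression is the per-gene sum of counts over all cells of the
same (individual, replicate, cluster) group, turning the single-cell
matrix into a bulk-like matrix that standard count machinery can model.
TMM (trimmed mean of M-values) computes a between-sample scaling factor
per column that is robust to composition bias; the voom procedure turns
the empirical mean-variance trend of log-counts into per-observation
precision weights for downstream weighted least squares.

TMM and the voom transform are implemented here directly (their reference
implementations live in R); both are checked against independent
brute-force oracles in the test suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import rankdata
from statsmodels.nonparametric.smoothers_lowess import lowess

from .io import CountMatrix, align_counts_cells

__all__ = [
    "PseudobulkMatrix",
    "WeightedExpression",
    "make_pseudobulk",
    "tmm_factors",
    "voom_weights",
    "log_cpm",
]


@dataclass
class PseudobulkMatrix:
    """Genes x groups summed expression with group metadata."""

    values: np.ndarray  # genes x groups, non-negative reals
    gene_ids: np.ndarray
    group_meta: pd.DataFrame  # one row per group; includes n_cells
    norm_factors: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("pseudobulk values must be non-negative")
        if self.values.shape[1] != len(self.group_meta):
            raise ValueError("group_meta must have one row per column")
        if self.norm_factors is None:
            self.norm_factors = np.ones(self.values.shape[1])
        self.norm_factors = np.asarray(self.norm_factors, float)
        if np.any(self.norm_factors <= 0):
            raise ValueError("norm factors must be positive")

    @property
    def library_sizes(self) -> np.ndarray:
        return self.values.sum(axis=0)

    @property
    def n_groups(self) -> int:
        return self.values.shape[1]


@dataclass
class WeightedExpression:
    """log2-CPM expression with voom precision weights and the fitted trend."""

    log_expression: np.ndarray  # genes x groups
    weights: np.ndarray  # genes x groups, positive
    trend_x: np.ndarray  # mean log2-count knots
    trend_y: np.ndarray  # sqrt-sd values at the knots
    group_meta: pd.DataFrame = field(default_factory=pd.DataFrame)
    gene_ids: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.log_expression.shape != self.weights.shape:
            raise ValueError("expression and weights must be the same shape")
        if not np.all(np.isfinite(self.weights)) or np.any(self.weights <= 0):
            raise ValueError("weights must be finite and positive")


def make_pseudobulk(
    counts: CountMatrix,
    cell_table: pd.DataFrame,
    group_by: Sequence[str] = ("individual", "replicate", "cluster"),
) -> PseudobulkMatrix:
    """Sum counts per group of cells sharing all ``group_by`` factor levels.

    Groups with zero cells simply do not appear.  Cells with a missing
    level in any grouping factor are an error.
    """
    align_counts_cells(counts, cell_table)
    for col in group_by:
        if col not in cell_table.columns:
            raise ValueError(f"cell table has no column {col!r}")
        bad = cell_table.loc[cell_table[col].isna(), "barcode"].tolist()
        if bad:
            raise ValueError(f"cells with missing {col!r}: {bad[:5]}")
    keys = cell_table[list(group_by)].astype(str).agg("|".join, axis=1)
    codes, uniques = pd.factorize(keys, sort=True)
    n_groups = len(uniques)
    # indicator matrix cells x groups; pseudobulk = counts @ indicator
    ind = sp.csr_matrix(
        (np.ones(len(codes)), (np.arange(len(codes)), codes)),
        shape=(len(codes), n_groups),
    )
    pb = np.asarray((counts.values @ ind).todense())
    meta_rows = [u.split("|") for u in uniques]
    meta = pd.DataFrame(meta_rows, columns=list(group_by))
    meta["n_cells"] = np.bincount(codes, minlength=n_groups)
    return PseudobulkMatrix(pb, counts.gene_ids, meta)


def _quantile_column(values: np.ndarray, p: float = 0.75) -> np.ndarray:
    lib = values.sum(axis=0)
    return np.array([np.quantile(values[:, j] / lib[j], p) for j in range(values.shape[1])])


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    trim_M: float,
    trim_A: float,
) -> float:
    """TMM factor of one column vs the reference (on the log2 scale -> 2^f)."""
    n_obs, n_ref = obs.sum(), ref.sum()
    usable = (obs > 0) & (ref > 0)
    o, r = obs[usable], ref[usable]
    if len(o) < 2:
        warnings.warn("fewer than 2 usable genes for TMM; factor set to 1", stacklevel=3)
        return 1.0
    po, pr = o / n_obs, r / n_ref
    M = np.log2(po / pr)
    A = 0.5 * np.log2(po * pr)
    # inverse asymptotic variance of M under binomial sampling
    w = 1.0 / ((n_obs - o) / (n_obs * o) + (n_ref - r) / (n_ref * r))
    if np.allclose(M.max(), M.min()):
        # pure depth change: all M equal; trimming removes everything
        return float(2 ** np.average(M, weights=w))
    n = len(M)
    lo_M = np.floor(n * trim_M) + 1
    hi_M = n + 1 - lo_M
    lo_A = np.floor(n * trim_A) + 1
    hi_A = n + 1 - lo_A
    rM = rankdata(M)
    rA = rankdata(A)
    keep = (rM >= lo_M) & (rM <= hi_M) & (rA >= lo_A) & (rA <= hi_A)
    if keep.sum() < 2:
        warnings.warn("fewer than 2 genes survive TMM trimming; factor set to 1", stacklevel=3)
        return 1.0
    f = np.sum(w[keep] * M[keep]) / np.sum(w[keep])
    return float(2**f)


def tmm_factors(
    pb: PseudobulkMatrix,
    reference: Optional[int] = None,
    trim_M: float = 0.3,
    trim_A: float = 0.05,
) -> np.ndarray:
    """Trimmed-mean-of-M-values normalization factor per pseudobulk column.

    The reference column defaults to the one whose upper-quartile
    expression fraction is closest to the mean upper quartile.  Factors
    are rescaled to geometric mean 1 and also stored on ``pb``.
    """
    values = pb.values
    if values.shape[1] < 2:
        raise ValueError("TMM needs at least two columns")
    if np.any(values.sum(axis=0) <= 0):
        raise ValueError("every column must have a positive total")
    if reference is None:
        f75 = _quantile_column(values)
        reference = int(np.argmin(np.abs(f75 - f75.mean())))
    factors = np.array(
        [
            1.0
            if j == reference
            else _tmm_pair(values[:, j], values[:, reference], trim_M, trim_A)
            for j in range(values.shape[1])
        ]
    )
    factors = factors / np.exp(np.mean(np.log(factors)))
    pb.norm_factors = factors
    return factors


def log_cpm(pb: PseudobulkMatrix, prior_count: float = 0.5) -> np.ndarray:
    """log2 counts-per-million with the voom offset convention."""
    lib = pb.library_sizes * pb.norm_factors
    return np.log2((pb.values + prior_count) / (lib + 1.0)[None, :] * 1e6)


def voom_weights(
    pb: PseudobulkMatrix,
    design: Optional[np.ndarray] = None,
    span: float = 0.5,
    weight_bounds: tuple[float, float] = (1e-6, 1e6),
) -> WeightedExpression:
    """Mean-variance precision weights for pseudobulk log2-CPM.

    Per gene, an ordinary least-squares fit under ``design`` yields a
    residual standard deviation; the square root of that SD is smoothed
    against mean log2-count with a lowess curve, and each observation's
    weight is the interpolated predicted SD at its fitted log-count raised
    to the power -4, clipped to ``weight_bounds``.
    """
    y = log_cpm(pb)
    n_genes, n_groups = y.shape
    if design is None:
        design = np.ones((n_groups, 1))
    design = np.asarray(design, float)
    if design.shape[0] != n_groups:
        raise ValueError("design must have one row per pseudobulk column")
    if n_groups <= design.shape[1]:
        raise ValueError(
            f"need more groups ({n_groups}) than design columns ({design.shape[1]})"
        )
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("design is rank deficient")

    coef, _, _, _ = np.linalg.lstsq(design, y.T, rcond=None)
    fitted = (design @ coef).T  # genes x groups, log2-CPM scale
    resid = y - fitted
    dof = n_groups - design.shape[1]
    sigma = np.sqrt((resid**2).sum(axis=1) / dof)

    lib = pb.library_sizes * pb.norm_factors
    amean = y.mean(axis=1)
    sx = amean + np.mean(np.log2(lib + 1.0)) - np.log2(1e6)
    sy = np.sqrt(sigma)
    smoothed = lowess(sy, sx, frac=span, return_sorted=True)
    trend_x, trend_y = smoothed[:, 0], np.maximum(smoothed[:, 1], 1e-6)

    # fitted log2-count per observation; interpolation clamps outside the range
    fitted_logcount = fitted + np.log2(lib + 1.0)[None, :] - np.log2(1e6)
    pred_sqrt_sd = np.interp(fitted_logcount, trend_x, trend_y)
    w = np.clip(pred_sqrt_sd**-4.0, *weight_bounds)
    return WeightedExpression(
        log_expression=y,
        weights=w,
        trend_x=trend_x,
        trend_y=trend_y,
        group_meta=pb.group_meta.copy(),
        gene_ids=pb.gene_ids,
    )
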