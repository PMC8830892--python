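"""Marker-gene differential expression on weighted pseudobulk.

Per gene, a no-intercept weighted linear model

    y = beta_cluster * x + beta_replicate * x + beta_individual * x

is fit by weighted least squares with voom precision weights, where the
design carries an indicator column for every cluster level and indicator
columns for all but one replicate and individual level (for
identifiability under the missing intercept).  The marker contrast for
cluster k is beta_k minus the unweighted mean of the other cluster
coefficients ("cluster k vs rest"), tested with a two-sided t-test on
the residual degrees of freedom.  Variances are plain WLS residual
variances — no empirical-Bayes moderation is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .pseudobulk import WeightedExpression

__all__ = [
    "DEResult",
    "build_design",
    "fit_contrast_model",
    "adjust_pvalues",
    "rank_markers",
]


@dataclass
class DEResult:
    """Per (gene, contrast) marker statistics."""

    table: pd.DataFrame  # gene, contrast, logFC, t, p_value, adjusted_p, mean_expr

    def __post_init__(self) -> None:
        t = self.table
        if ((t["adjusted_p"] < t["p_value"] - 1e-12).any()
                or (t["p_value"] < 0).any() or (t["adjusted_p"] > 1 + 1e-12).any()):
            raise ValueError("p-values must satisfy 0 <= p <= adjusted_p <= 1")


def build_design(meta: pd.DataFrame,
                 cluster_col: str = "cluster",
                 replicate_col: str = "replicate",
                 individual_col: str = "individual") -> tuple[np.ndarray, list[str], list[str]]:
    """No-intercept design: all cluster indicators + drop-first replicate and
    individual indicators.  Returns (design, column names, cluster levels)."""
    clusters = pd.Categorical(meta[cluster_col])
    cl_levels = list(clusters.categories)
    blocks = [pd.get_dummies(clusters, prefix="cluster").to_numpy(float)]
    names = [f"cluster:{lev}" for lev in cl_levels]
    for col, tag in ((replicate_col, "replicate"), (individual_col, "individual")):
        dummies = pd.get_dummies(pd.Categorical(meta[col]), drop_first=True, prefix=tag)
        if dummies.shape[1]:
            blocks.append(dummies.to_numpy(float))
            names += [f"{tag}:{lev}" for lev in pd.Categorical(meta[col]).categories[1:]]
    X = np.hstack(blocks)
    return X, names, cl_levels


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify aliased columns by QR pivoting
        _, r = np.linalg.qr(X)
        aliased = [names[j] for j in range(X.shape[1]) if abs(r[j, j]) < 1e-10] if r.shape[0] >= X.shape[1] else names
        raise ValueError(f"rank-deficient design (rank {rank} < {X.shape[1]}); aliased: {aliased}")


def fit_contrast_model(expr: WeightedExpression,
                       cluster_col: str = "cluster",
                       replicate_col: str = "replicate",
                       individual_col: str = "individual") -> DEResult:
    """Weighted least squares per gene with cluster-vs-rest contrasts."""
    meta = expr.group_meta
    X, names, cl_levels = build_design(meta, cluster_col, replicate_col, individual_col)
    _check_rank(X, names)
    Y = expr.log_expression
    W = expr.weights
    n_genes, n_obs = Y.shape
    p = X.shape[1]
    df = n_obs - p
    if df <= 0:
        raise ValueError("no residual degrees of freedom")

    n_cl = len(cl_levels)
    # contrast matrix: rows = contrasts, cols = coefficients
    C = np.zeros((n_cl, p))
    for k in range(n_cl):
        C[k, :n_cl] = -1.0 / (n_cl - 1)
        C[k, k] = 1.0

    rows = []
    for g in range(n_genes):
        w = W[g]
        y = Y[g]
        Xw = X * w[:, None]
        XtWX = X.T @ Xw
        XtWy = Xw.T @ y
        XtWX_inv = np.linalg.inv(XtWX)
        beta = XtWX_inv @ XtWy
        resid = y - X @ beta
        s2 = float(resid @ (w * resid)) / df
        est = C @ beta
        var = np.einsum("ij,jk,ik->i", C, XtWX_inv, C) * s2
        se = np.sqrt(np.maximum(var, 1e-300))
        t = est / se
        pvals = 2.0 * scipy.stats.t.sf(np.abs(t), df)
        gid = expr.gene_ids[g] if expr.gene_ids is not None else g
        mean_expr = float(y.mean())
        for k, lev in enumerate(cl_levels):
            rows.append((gid, f"{lev}_vs_rest", est[k], t[k], pvals[k], mean_expr))
    table = pd.DataFrame(
        rows, columns=["gene", "contrast", "logFC", "t", "p_value", "mean_expr"]
    )
    # BH correction within each contrast, across genes
    table["adjusted_p"] = (
        table.groupby("contrast")["p_value"].transform(lambda s: adjust_pvalues(s.to_numpy()))
    )
    return DEResult(table[["gene", "contrast", "logFC", "t", "p_value", "adjusted_p", "mean_expr"]])


def adjust_pvalues(p: np.ndarray, method: str = "BH") -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p, float)
    if np.any(np.isnan(p)):
        raise ValueError("NaN p-values are not allowed")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if method != "BH":
        raise ValueError(f"unsupported method {method!r}")
    return multipletests(p, method="fdr_bh")[1]


def rank_markers(result: DEResult, per_cluster: int = 10) -> dict[str, dict[str, pd.DataFrame]]:
    """Top markers per contrast: by adjusted p ascending and by logFC descending.

    Ties in adjusted p break by |t| descending, then by gene id; ties in
    logFC break by adjusted p, then gene id.  Asking for more genes than
    exist returns the full list.
    """
    out: dict[str, dict[str, pd.DataFrame]] = {}
    tab = result.table.assign(abs_t=lambda d: d["t"].abs())
    for contrast, grp in tab.groupby("contrast"):
        by_p = grp.sort_values(
            ["adjusted_p", "abs_t", "gene"], ascending=[True, False, True]
        ).head(per_cluster)
        by_lfc = grp.sort_values(
            ["logFC", "adjusted_p", "gene"], ascending=[False, True, True]
        ).head(per_cluster)
        out[contrast] = {
            "by_adjusted_p": by_p.drop(columns="abs_t").reset_index(drop=True),
            "by_logFC": by_lfc.drop(columns="abs_t").reset_index(drop=True),
        }
    return out
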