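"""eQTL study-design power calculator.

The analytic power to detect an eQTL of standardized additive effect
``beta`` with ``n`` individuals at per-test level ``alpha`` and phenotype
standard deviation ``sigma`` under simple linear regression is

    Pow(beta, alpha, n, sigma) = Phi(Phi^-1(alpha/2) + beta/sigma * sqrt(n))

with Phi the standard normal CDF.  The formula keeps only one tail and
uses the normal rather than the t distribution; ``mc_power_oracle``
quantifies that approximation error by simulating the actual two-sided
regression test.  The per-test alpha comes from a Bonferroni correction
of the family-wise error rate over the number of genes tested.

The phenotype SD for a given experiment size E (total cells) is
estimated by downsampling cells evenly across individual x replicate
groups, partitioning the variance of each draw's pseudobulk, and fitting
an exponential decay  v(E) = a * exp(-b * E) + c  to the median residual
variance; sigma(E) = sqrt(v(E)).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.optimize
from scipy.stats import norm, t as t_dist

from .io import CountMatrix
from .pseudobulk import make_pseudobulk, tmm_factors, log_cpm
from .qc import filter_genes_cluster_fraction
from .varpart import partition_matrix

__all__ = [
    "PowerParams",
    "DecayFit",
    "power",
    "bonferroni_alpha",
    "mc_power_oracle",
    "estimate_sigma_curve",
    "fit_decay",
    "power_grid",
]


@dataclass(frozen=True)
class PowerParams:
    """Arguments of the analytic power function."""

    beta: float  # standardized additive effect size
    alpha: float  # per-test significance level
    n: int  # number of individuals
    sigma: float = 1.0  # phenotype standard deviation

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.n < 2:
            raise ValueError("need at least two individuals")


@dataclass
class DecayFit:
    """Exponential decay of residual variance with experiment size."""

    a: float
    b: float
    c: float
    sizes: np.ndarray
    variances: np.ndarray
    rss: float
    converged: bool

    def __post_init__(self) -> None:
        if self.a < 0 or self.b <= 0 or self.c < 0:
            raise ValueError("require a >= 0, b > 0, c >= 0")
        if np.any(self.predict(self.sizes) <= 0):
            raise ValueError("fitted variance must stay positive over the data range")

    def predict(self, E) -> np.ndarray:
        E = np.asarray(E, float)
        return self.a * np.exp(-self.b * E) + self.c

    def sigma(self, E) -> np.ndarray:
        return np.sqrt(self.predict(E))


def power(params: PowerParams) -> float:
    """Analytic eQTL detection power (see module docstring)."""
    z = norm.ppf(params.alpha / 2.0)
    return float(norm.cdf(z + params.beta / params.sigma * np.sqrt(params.n)))


def bonferroni_alpha(fwer: float, n_tests: int) -> float:
    """Per-test level controlling the family-wise error rate."""
    if not 0 < fwer < 1:
        raise ValueError("fwer must lie in (0, 1)")
    if n_tests <= 0:
        raise ValueError("n_tests must be positive")
    return fwer / n_tests


def mc_power_oracle(
    beta: float,
    alpha: float,
    n: int,
    sigma: float = 1.0,
    maf: float = 0.3,
    n_sims: int = 100_000,
    seed: int = 0,
    chunk: int = 20_000,
) -> tuple[float, float]:
    """Empirical rejection rate of the two-sided eQTL regression t-test.

    Per replicate: genotypes ~ Binomial(2, maf), standardized to unit
    sample variance; phenotype = beta * g_std + Normal(0, sigma^2); the
    slope is tested two-sided at level ``alpha``.  Monomorphic genotype
    draws are resampled.  Returns (rate, Monte-Carlo standard error).
    """
    if n < 3:
        raise ValueError("need n >= 3 for the regression t-test")
    rng = np.random.default_rng(seed)
    t_crit = t_dist.ppf(1.0 - alpha / 2.0, df=n - 2)
    n_reject = 0
    done = 0
    while done < n_sims:
        m = min(chunk, n_sims - done)
        # Binomial(2, maf) as two Bernoulli passes; float32 keeps the large
        # arrays cheap without hurting the rejection-rate resolution
        g = (rng.random((m, n), dtype=np.float32) < maf).astype(np.float32)
        g += rng.random((m, n), dtype=np.float32) < maf
        # resample monomorphic rows
        while True:
            mono = g.var(axis=1) == 0
            if not mono.any():
                break
            k = int(mono.sum())
            g[mono] = (rng.random((k, n), dtype=np.float32) < maf).astype(np.float32)
            g[mono] += rng.random((k, n), dtype=np.float32) < maf
        g -= g.mean(axis=1, keepdims=True)
        g /= g.std(axis=1, keepdims=True)
        y = rng.standard_normal((m, n), dtype=np.float32)
        y *= sigma
        y += beta * g
        y -= y.mean(axis=1, keepdims=True)
        num = np.einsum("ij,ij->i", g, y, dtype=np.float64)
        den = np.einsum("ij,ij->i", y, y, dtype=np.float64)
        r = num / np.sqrt(n * den)
        r = np.clip(r, -0.999999999, 0.999999999)
        t_stat = r * np.sqrt((n - 2) / (1.0 - r**2))
        n_reject += int((np.abs(t_stat) > t_crit).sum())
        done += m
    rate = n_reject / n_sims
    se = float(np.sqrt(max(rate * (1 - rate), 1e-12) / n_sims))
    return rate, se


def _even_subsample(
    cell_table: pd.DataFrame, size: int, rng: np.random.Generator
) -> np.ndarray:
    """Indices of ``size`` cells split as evenly as possible across
    individual x replicate groups; remainder assigned by seeded shuffle."""
    groups = cell_table.groupby(["individual", "replicate"], sort=True).indices
    keys = sorted(groups)
    quota = {k: size // len(keys) for k in keys}
    order = list(keys)
    rng.shuffle(order)
    for k in order[: size % len(keys)]:
        quota[k] += 1
    chosen = []
    for k in keys:
        idx = np.asarray(groups[k])
        take = quota[k]
        if take > len(idx):
            warnings.warn(
                f"group {k} has only {len(idx)} cells for a quota of {take}; "
                "sampling it fully",
                stacklevel=3,
            )
            take = len(idx)
        chosen.append(rng.choice(idx, size=take, replace=False))
    return np.sort(np.concatenate(chosen))


def estimate_sigma_curve(
    counts: CountMatrix,
    cell_table: pd.DataFrame,
    sizes: Sequence[int],
    n_draws: int = 10,
    seed: int = 0,
    min_cluster_fraction: float = 0.2,
) -> pd.DataFrame:
    """Median residual variance of pseudobulk expression per experiment size.

    For each size E: draw ``n_draws`` subsamples of E cells sampled evenly
    across individual x replicate groups; per draw, build the (cluster,
    individual, replicate) pseudobulk, keep genes passing the
    20%-in-a-cluster filter computed on the FULL data, TMM-normalize,
    partition variance, and record the median residual variance component
    over genes.  Returns per-size medians across draws.
    """
    if "cluster" not in cell_table.columns:
        raise ValueError("cluster assignments are required")
    n_cells = counts.n_cells
    for E in sizes:
        if E > n_cells:
            raise ValueError(f"size {E} exceeds available {n_cells} cells")
    gene_mask = filter_genes_cluster_fraction(
        counts, cell_table["cluster"], min_fraction=min_cluster_fraction
    )
    rng = np.random.default_rng(seed)
    rows = []
    for E in sizes:
        draw_medians = []
        for d in range(n_draws):
            idx = _even_subsample(cell_table, E, rng)
            sub_counts = counts.subset_cells(idx).subset_genes(gene_mask)
            sub_table = cell_table.iloc[idx].reset_index(drop=True)
            pb = make_pseudobulk(sub_counts, sub_table)
            tmm_factors(pb)
            expr = log_cpm(pb)
            res = partition_matrix(
                expr,
                pb.group_meta,
                factors=("cluster", "individual", "replicate"),
                gene_ids=pb.gene_ids,
            )
            draw_medians.append(float(res.components["residual"].median()))
        rows.append(
            {
                "size": int(E),
                "median_residual_variance": float(np.median(draw_medians)),
                "n_draws": n_draws,
            }
        )
    return pd.DataFrame(rows)


def fit_decay(
    sizes: Sequence[float],
    variances: Sequence[float],
    n_starts: int = 5,
    seed: int = 0,
) -> DecayFit:
    """Nonlinear least squares for v(E) = a * exp(-b * E) + c.

    Initialization: c0 = min(v), a0 = max(v) - c0, b0 from a log-linear
    fit of (v - c0); ``n_starts`` jittered restarts, best residual sum of
    squares kept.
    """
    E = np.asarray(sizes, float)
    v = np.asarray(variances, float)
    if len(np.unique(E)) < 3:
        raise ValueError("need at least 3 distinct sizes")
    if np.any(v <= 0):
        raise ValueError("variances must be positive")

    c0 = float(v.min())
    a0 = max(float(v.max() - c0), 1e-8 * v.max())
    pos = v - c0 > 0
    if pos.sum() >= 2:
        slope = np.polyfit(E[pos], np.log(v[pos] - c0), 1)[0]
        b0 = max(-slope, 1.0 / (E.max() - E.min() + 1.0))
    else:
        b0 = 1.0 / (E.max() - E.min() + 1.0)

    def resid(theta):
        a, b, c = theta
        return a * np.exp(-b * E) + c - v

    rng = np.random.default_rng(seed)
    best = None
    for s in range(n_starts):
        jitter = np.ones(3) if s == 0 else rng.uniform(0.5, 2.0, size=3)
        x0 = np.array([a0, b0, max(c0, 1e-12)]) * jitter
        try:
            sol = scipy.optimize.least_squares(
                resid,
                x0,
                bounds=([0.0, 1e-300, 0.0], [np.inf, np.inf, np.inf]),
                xtol=1e-15,
                ftol=1e-15,
                gtol=1e-15,
            )
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not best.success:
        raise RuntimeError(
            f"decay fit failed from all {n_starts} starts; "
            f"sizes={E.tolist()}, variances={v.tolist()}"
        )
    a, b, c = best.x
    return DecayFit(
        a=float(a),
        b=float(b),
        c=float(c),
        sizes=E,
        variances=v,
        rss=float(2 * best.cost),
        converged=bool(best.success),
    )


def power_grid(
    betas: Sequence[float],
    ns: Sequence[int],
    cells_per_individual: Sequence[int],
    decay: DecayFit,
    fwer: float = 0.05,
    n_genes: int = 10_000,
    extrapolation_factor: float = 5.0,
    power_threshold: float = 0.80,
) -> pd.DataFrame:
    """Analytic power over (effect size, sample size, cells per individual).

    Experiment size E = n * cells; sigma = sqrt of the fitted decay at E;
    alpha = Bonferroni-corrected fwer.  Long-format result with a column
    marking grid points reaching the ``power_threshold`` reference line.
    """
    alpha = bonferroni_alpha(fwer, n_genes)
    guard = extrapolation_factor * float(np.max(decay.sizes))
    rows = []
    for beta in betas:
        for n in ns:
            for cells in cells_per_individual:
                E = n * cells
                if E > guard:
                    warnings.warn(
                        f"experiment size {E} extrapolates beyond "
                        f"{extrapolation_factor}x the largest fitted size",
                        stacklevel=2,
                    )
                sigma = float(decay.sigma(E))
                val = power(PowerParams(beta=beta, alpha=alpha, n=n, sigma=sigma))
                rows.append(
                    {
                        "beta": beta,
                        "n": n,
                        "cells_per_individual": cells,
                        "experiment_size": E,
                        "sigma": sigma,
                        "alpha": alpha,
                        "power": val,
                        "reaches_threshold": val >= power_threshold,
                    }
                )
    return pd.DataFrame(rows)
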