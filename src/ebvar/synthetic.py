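"""Synthetic data with known ground truth for every pipeline stage.

The generator emulates a multi-individual embryoid-body scRNA-seq
experiment: C cell types x I individuals x R replicates, with per-gene
log-scale random effects for each factor, Poisson-lognormal UMI sampling,
variable library sizes, a mitochondrial gene subset ("MT-" prefix), an
optional low-differentiation-efficiency individual, discordant-read
tables for species demultiplexing, labeled reference/query embeddings
for label transfer, and genotypes for power simulations.

The hierarchical count model: the rate for cell c of type t, individual
i, replicate r at gene g is

    lambda = s_c * exp(mu_g + a_{g,t} + b_{g,i} + c_{g,r} + e_c)

with a, b, c ~ Normal(0, sd_k^2) per gene, e_c ~ Normal(0,
cell_noise_sd^2) per cell, and s_c a lognormal library-size factor.
Counts are Poisson given the rate, so the lognormal cell factor supplies
the overdispersion.  On the log scale the theoretical variance fraction
of factor k is sd_k^2 / (sum over factors of sd_k^2 + cell_noise_sd^2).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import CountMatrix

__all__ = [
    "SimConfig",
    "TruthRecord",
    "default_config",
    "simulate_counts",
    "simulate_composition",
    "simulate_discordant_reads",
    "simulate_embeddings",
    "simulate_genotypes",
    "simulate_gaussian_genes",
]

#: cell-type labels used when none are supplied, in differentiation order
DEFAULT_CELL_TYPES = (
    "pluripotent",
    "early_ectoderm",
    "mesoderm",
    "neural_crest",
    "endoderm",
    "neurons",
    "endothelial",
)


@dataclass
class SimConfig:
    """Parameters of the synthetic embryoid-body experiment.

    Defaults mirror the statistical structure the analysis assumes: seven
    broad cell types across three individuals and three replicates, with
    log-scale effect SDs chosen so the theoretical variance fractions are
    (0.60, 0.05, 0.05, 0.30) for (cell type, individual, replicate,
    residual).
    """

    n_genes: int = 500
    n_individuals: int = 3
    n_replicates: int = 3
    cell_types: Sequence[str] = DEFAULT_CELL_TYPES
    #: rows = individuals, columns = cell types; each row a probability vector
    mixing_proportions: Optional[np.ndarray] = None
    cells_per_group: int = 100
    baseline_log_mean: float = 0.0
    baseline_log_sd: float = 1.0
    sd_celltype: float = float(np.sqrt(6.0))
    sd_individual: float = float(np.sqrt(0.5))
    sd_replicate: float = float(np.sqrt(0.5))
    cell_noise_sd: float = float(np.sqrt(3.0))
    library_size_log_mean: float = float(np.log(5000.0))
    library_size_log_sd: float = 0.3
    mito_fraction: float = 0.05
    #: Dirichlet concentration for replicate-level composition noise
    composition_concentration: float = 200.0
    #: (individual index, pluripotent-type proportion), or None
    low_efficiency_individual: Optional[tuple[int, float]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_individuals", "n_replicates", "cells_per_group"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be a positive integer")
        if len(self.cell_types) == 0:
            raise ValueError("at least one cell type is required")
        for name in ("sd_celltype", "sd_individual", "sd_replicate", "cell_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0 <= self.mito_fraction <= 1:
            raise ValueError("mito_fraction must lie in [0, 1]")
        if self.mixing_proportions is None:
            p = np.full(
                (self.n_individuals, len(self.cell_types)), 1.0 / len(self.cell_types)
            )
            if self.low_efficiency_individual is not None:
                idx, prop = self.low_efficiency_individual
                rest = (1.0 - prop) / max(len(self.cell_types) - 1, 1)
                p[idx] = rest
                p[idx, 0] = prop
            self.mixing_proportions = p
        else:
            self.mixing_proportions = np.asarray(self.mixing_proportions, float)
            if self.mixing_proportions.shape != (
                self.n_individuals,
                len(self.cell_types),
            ):
                raise ValueError("mixing_proportions must be individuals x cell types")
            if np.any(self.mixing_proportions < 0):
                raise ValueError("mixing proportions must be non-negative")
            if not np.allclose(self.mixing_proportions.sum(axis=1), 1.0, atol=1e-12):
                raise ValueError("each mixing-proportion row must sum to 1")

    def theoretical_fractions(self) -> dict[str, float]:
        """Log-scale variance fractions implied by the effect SDs."""
        v = {
            "cluster": self.sd_celltype**2,
            "individual": self.sd_individual**2,
            "replicate": self.sd_replicate**2,
            "residual": self.cell_noise_sd**2,
        }
        total = sum(v.values())
        if total == 0:
            # fully deterministic gene: all mass assigned to residual by convention
            return {k: (1.0 if k == "residual" else 0.0) for k in v}
        return {k: val / total for k, val in v.items()}

    def to_json(self) -> str:
        d = asdict(self)
        d["cell_types"] = list(self.cell_types)
        d["mixing_proportions"] = self.mixing_proportions.tolist()
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SimConfig":
        d = json.loads(text)
        if d.get("mixing_proportions") is not None:
            d["mixing_proportions"] = np.asarray(d["mixing_proportions"], float)
        if d.get("low_efficiency_individual") is not None:
            d["low_efficiency_individual"] = tuple(d["low_efficiency_individual"])
        return cls(**d)


@dataclass
class TruthRecord:
    """Ground truth realized by a simulation run."""

    #: per-gene realized effects, keyed by factor name; arrays of shape (genes, levels)
    gene_effects: dict[str, np.ndarray]
    #: theoretical log-scale variance fraction per factor (residual included)
    theoretical_fractions: dict[str, float]
    #: per-cell true assignments
    cell_truth: pd.DataFrame

    def __post_init__(self) -> None:
        fr = np.array(list(self.theoretical_fractions.values()))
        if np.any(fr < 0) or not np.isclose(fr.sum(), 1.0, atol=1e-9):
            raise ValueError("theoretical fractions must be non-negative and sum to 1")


def default_config(**overrides) -> SimConfig:
    """The default synthetic scenario (see class docstring)."""
    return SimConfig(**overrides)


def simulate_counts(config: SimConfig) -> tuple[CountMatrix, pd.DataFrame, TruthRecord]:
    """Draw a hierarchical Poisson-lognormal UMI matrix plus metadata and truth."""
    rng = np.random.default_rng(config.seed)
    n_types = len(config.cell_types)
    G = config.n_genes

    mu = rng.normal(config.baseline_log_mean, config.baseline_log_sd, size=G)
    a = rng.normal(0.0, config.sd_celltype, size=(G, n_types))
    b = rng.normal(0.0, config.sd_individual, size=(G, config.n_individuals))
    c = rng.normal(0.0, config.sd_replicate, size=(G, config.n_replicates))

    # assemble cells group by group (individual x replicate)
    cols, types, inds, reps, barcodes = [], [], [], [], []
    cell_idx = 0
    for i in range(config.n_individuals):
        for r in range(config.n_replicates):
            t_draw = rng.choice(n_types, size=config.cells_per_group,
                                p=config.mixing_proportions[i])
            for t in t_draw:
                types.append(int(t))
                inds.append(i)
                reps.append(r)
                barcodes.append(f"cell{cell_idx:06d}")
                cell_idx += 1
    types = np.asarray(types)
    inds = np.asarray(inds)
    reps = np.asarray(reps)
    n_cells = len(types)

    e = rng.normal(0.0, config.cell_noise_sd, size=n_cells)
    # relative depth factor; the mean library size is set by a single global
    # rescaling below, which only shifts the grand mean on the log scale and
    # leaves the variance structure untouched
    s = rng.lognormal(0.0, config.library_size_log_sd, size=n_cells)

    log_rate = mu[:, None] + a[:, types] + b[:, inds] + c[:, reps] + e[None, :]
    rate = np.exp(log_rate)
    if not np.all(np.isfinite(rate)):
        g_bad, c_bad = np.argwhere(~np.isfinite(rate))[0]
        raise FloatingPointError(
            f"non-finite Poisson rate at gene {g_bad}, cell {c_bad}"
        )
    kappa = np.exp(config.library_size_log_mean) / rate.sum(axis=0).mean()
    rate = rate * (kappa * s[None, :])
    counts = rng.poisson(rate)
    mat = sp.csr_matrix(counts)

    n_mito = int(round(config.mito_fraction * G))
    gene_ids = np.array(
        [f"MT-G{g:05d}" if g < n_mito else f"G{g:05d}" for g in range(G)], dtype=object
    )

    cell_table = pd.DataFrame(
        {
            "barcode": barcodes,
            "individual": [f"ind{i}" for i in inds],
            "replicate": [f"rep{r}" for r in reps],
            "cluster": [config.cell_types[t] for t in types],
        }
    )
    cm = CountMatrix(mat, gene_ids, np.asarray(barcodes, dtype=object))
    truth = TruthRecord(
        gene_effects={"cluster": a, "individual": b, "replicate": c, "grand_mean": mu[:, None]},
        theoretical_fractions=config.theoretical_fractions(),
        cell_truth=cell_table.assign(cell_noise=e, library_factor=s),
    )
    return cm, cell_table, truth


def simulate_composition(config: SimConfig) -> pd.DataFrame:
    """Replicate-level cell-type proportions, Dirichlet around individual means.

    Returns a long table (individual, replicate, cell_type, proportion).  A
    ``low_efficiency_individual`` entry pins that individual's mean
    pluripotent-type proportion (default mimics the 0.89 observed for the
    poorly differentiating line).
    """
    if config.composition_concentration <= 0:
        raise ValueError("composition_concentration must be positive")
    rng = np.random.default_rng(config.seed)
    rows = []
    for i in range(config.n_individuals):
        mean = config.mixing_proportions[i]
        for r in range(config.n_replicates):
            if np.isinf(config.composition_concentration):
                p = mean.copy()
            else:
                alpha = np.maximum(mean * config.composition_concentration, 1e-12)
                p = rng.dirichlet(alpha)
            for t, ct in enumerate(config.cell_types):
                rows.append((f"ind{i}", f"rep{r}", ct, p[t]))
    return pd.DataFrame(rows, columns=["individual", "replicate", "cell_type", "proportion"])


def simulate_discordant_reads(
    n_cells: int,
    human_fraction: float,
    seed: int,
    human_rate: float = 50.0,
    other_rate: float = 50.0,
    human_purity: float = 0.95,
    other_purity: float = 0.05,
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-barcode discordant-read summaries with known species truth.

    Human cells carry many discordant reads favoring the human genome
    (binomial with success probability ``human_purity``); other-species
    cells the reverse.
    """
    if not 0 <= human_fraction <= 1:
        raise ValueError("human_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    is_human = rng.random(n_cells) < human_fraction
    n_disc = rng.poisson(np.where(is_human, human_rate, other_rate))
    p = np.where(is_human, human_purity, other_purity)
    n_hh = rng.binomial(n_disc, p)
    table = pd.DataFrame(
        {
            "barcode": [f"bc{i:06d}" for i in range(n_cells)],
            "n_discordant": n_disc,
            "n_human_higher": n_hh,
        }
    )
    truth = pd.Series(np.where(is_human, "human", "other"), index=table["barcode"], name="species")
    return table, truth


def simulate_embeddings(
    n_ref: int,
    n_query: int,
    n_types: int,
    separation: float,
    seed: int,
    n_dims: int = 10,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Gaussian blobs per cell type in a shared embedding.

    Type centers are ``separation`` within-type SDs apart; the reference
    frame carries labels, the query frame carries the truth column for
    scoring a transfer.
    """
    if n_types < 2:
        raise ValueError("need at least two cell types")
    if separation < 0:
        raise ValueError("separation must be non-negative")
    rng = np.random.default_rng(seed)
    centers = rng.normal(size=(n_types, n_dims))
    centers /= np.maximum(np.linalg.norm(centers, axis=1, keepdims=True), 1e-12)
    centers *= separation

    def blob(n: int) -> tuple[np.ndarray, np.ndarray]:
        labels = rng.integers(n_types, size=n)
        coords = centers[labels] + rng.normal(size=(n, n_dims))
        return coords, labels

    ref_xy, ref_lab = blob(n_ref)
    q_xy, q_lab = blob(n_query)
    dim_cols = [f"dim_{d}" for d in range(n_dims)]
    ref = pd.DataFrame(ref_xy, columns=dim_cols)
    ref.insert(0, "barcode", [f"ref{i:06d}" for i in range(n_ref)])
    ref["label"] = [f"type{t}" for t in ref_lab]
    query = pd.DataFrame(q_xy, columns=dim_cols)
    query.insert(0, "barcode", [f"qry{i:06d}" for i in range(n_query)])
    query["true_label"] = [f"type{t}" for t in q_lab]
    return ref, query


def simulate_genotypes(
    n_individuals: int, maf: float, seed: int, max_retries: int = 50
) -> tuple[np.ndarray, np.ndarray]:
    """Biallelic dosages Binomial(2, maf) plus a standardized copy.

    The standardized copy has sample mean 0 and sample variance exactly 1.
    Monomorphic draws are resampled up to ``max_retries`` times.
    """
    if not 0 < maf < 0.5:
        raise ValueError("maf must lie in (0, 0.5)")
    rng = np.random.default_rng(seed)
    for _ in range(max_retries):
        g = rng.binomial(2, maf, size=n_individuals).astype(float)
        if g.var() > 0:
            g_std = (g - g.mean()) / g.std()
            return g, g_std
    raise RuntimeError(
        f"monomorphic genotypes after {max_retries} draws (n={n_individuals}, maf={maf})"
    )


def simulate_gaussian_genes(
    n_genes: int,
    variances: dict[str, float],
    n_levels: dict[str, int],
    seed: int,
) -> tuple[np.ndarray, pd.DataFrame, dict[str, float]]:
    """Gaussian observations from the crossed random-intercepts model itself.

    One observation per combination of factor levels (a fully crossed,
    balanced design), with y = mu + sum_k u_k[level] + e and
    u_k ~ Normal(0, variances[k]), e ~ Normal(0, variances['residual']).
    Used for parameter-recovery tests where the truth must be exact on the
    observation scale.  Returns (genes x observations, metadata, truth
    fractions).
    """
    rng = np.random.default_rng(seed)
    factors = [k for k in variances if k != "residual"]
    grids = np.meshgrid(*[np.arange(n_levels[k]) for k in factors], indexing="ij")
    codes = {k: g.ravel() for k, g in zip(factors, grids)}
    n_obs = len(next(iter(codes.values())))
    y = np.zeros((n_genes, n_obs))
    for k in factors:
        u = rng.normal(0.0, np.sqrt(variances[k]), size=(n_genes, n_levels[k]))
        y += u[:, codes[k]]
    y += rng.normal(0.0, np.sqrt(variances["residual"]), size=(n_genes, n_obs))
    meta = pd.DataFrame({k: [f"{k}{v}" for v in codes[k]] for k in factors})
    total = sum(variances.values())
    fractions = {k: v / total for k, v in variances.items()}
    return y, meta, fractions
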