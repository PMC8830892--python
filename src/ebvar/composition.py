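"""Cell-type composition matrices and hierarchical sample clustering.

A composition row describes one (individual, replicate) sample either as
its vector of cluster proportions or as the mean topic loading of its
cells.  Samples are then clustered agglomeratively with complete linkage
(Euclidean distance by default); a run "clusters by individual" when
cutting the dendrogram into one group per individual exactly reproduces
the individual partition, scored by the adjusted Rand index.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.spatial.distance as ssd
from sklearn.metrics import adjusted_rand_score

from .io import TOPIC_PREFIX

__all__ = [
    "CompositionMatrix",
    "cluster_proportions",
    "topic_mean_loadings",
    "hclust_samples",
    "dendrogram_to_newick",
    "clusters_by_individual",
]


@dataclass
class CompositionMatrix:
    """Samples x (cluster proportions or mean topic loadings)."""

    values: pd.DataFrame  # index = sample id, columns = cluster/topic
    sample_meta: pd.DataFrame  # individual, replicate per sample

    def __post_init__(self) -> None:
        v = self.values.to_numpy(float)
        if np.any(v < -1e-12):
            raise ValueError("composition entries must be non-negative")
        if len(self.sample_meta) != len(self.values):
            raise ValueError("sample_meta must match values rows")


def _sample_ids(meta: pd.DataFrame) -> pd.Series:
    return meta["individual"].astype(str) + ":" + meta["replicate"].astype(str)


def cluster_proportions(cell_table: pd.DataFrame) -> CompositionMatrix:
    """Per-sample proportion of cells in each cluster; rows sum to 1."""
    for col in ("individual", "replicate", "cluster"):
        if col not in cell_table.columns:
            raise ValueError(f"cell table lacks column {col!r}")
    tab = pd.crosstab(
        _sample_ids(cell_table), cell_table["cluster"]
    )
    totals = tab.sum(axis=1)
    if (totals == 0).any():
        raise ValueError("empty sample encountered")
    props = tab.div(totals, axis=0)
    meta = (
        cell_table.assign(sample=_sample_ids(cell_table))[
            ["sample", "individual", "replicate"]
        ]
        .drop_duplicates()
        .set_index("sample")
        .loc[props.index]
        .reset_index(drop=True)
    )
    props.index.name = "sample"
    return CompositionMatrix(props, meta)


def topic_mean_loadings(cell_table: pd.DataFrame) -> CompositionMatrix:
    """Per-sample mean topic loading; rows sum to 1 because cell rows do."""
    topic_cols = [c for c in cell_table.columns if c.startswith(TOPIC_PREFIX)]
    if not topic_cols:
        raise ValueError("cell table has no topic loading columns")
    means = (
        cell_table.assign(sample=_sample_ids(cell_table))
        .groupby("sample")[topic_cols]
        .mean()
    )
    meta = (
        cell_table.assign(sample=_sample_ids(cell_table))[
            ["sample", "individual", "replicate"]
        ]
        .drop_duplicates()
        .set_index("sample")
        .loc[means.index]
        .reset_index(drop=True)
    )
    return CompositionMatrix(means, meta)


def hclust_samples(
    comp: CompositionMatrix,
    metric: str = "euclidean",
    linkage: str = "complete",
    z_scale: bool = False,
) -> np.ndarray:
    """Agglomerative clustering of composition rows.

    Returns the scipy linkage matrix (merge pairs + heights).  With
    ``z_scale``, columns are standardized first (constant columns are
    dropped).  Ties between merge candidates resolve to the lowest-index
    pair, which is scipy's deterministic behavior for these inputs.
    """
    X = comp.values.to_numpy(float)
    if X.shape[0] < 2:
        raise ValueError("need at least two samples to cluster")
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite composition entries")
    if z_scale:
        sd = X.std(axis=0)
        keep = sd > 0
        X = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    d = ssd.pdist(X, metric=metric)
    return sch.linkage(d, method=linkage)


def dendrogram_to_newick(Z: np.ndarray, leaf_names: list[str]) -> str:
    """Serialize a linkage matrix as a Newick string with merge heights."""
    tree = sch.to_tree(Z)

    def rec(node, parent_height):
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{leaf_names[node.id]}:{length:.10g}"
        left = rec(node.left, node.dist)
        right = rec(node.right, node.dist)
        return f"({left},{right}):{length:.10g}"

    return rec(tree, tree.dist) + ";"


def clusters_by_individual(
    Z: np.ndarray, sample_meta: pd.DataFrame
) -> tuple[bool, float]:
    """Does cutting into n_individuals groups recover the individual partition?

    Returns (exact match, adjusted Rand index of the cut vs individual
    labels).
    """
    individuals = sample_meta["individual"].astype(str).to_numpy()
    n_ind = len(np.unique(individuals))
    cut = sch.fcluster(Z, t=n_ind, criterion="maxclust")
    ari = float(adjusted_rand_score(individuals, cut))
    # exact: the cut partition equals the individual partition
    exact = True
    for lab in np.unique(cut):
        members = individuals[cut == lab]
        if len(np.unique(members)) != 1:
            exact = False
            break
    exact = exact and len(np.unique(cut)) == n_ind
    if exact:
        # every individual must also be confined to one group
        for ind in np.unique(individuals):
            if len(np.unique(cut[individuals == ind])) != 1:
                exact = False
                break
    return exact, ari
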