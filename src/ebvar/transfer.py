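"""k-nearest-neighbor cell-type label transfer and concordance statistics.

Each query cell receives the annotation shared by at least ``min_votes``
of its ``k`` nearest reference cells (Euclidean distance in the provided
embedding); otherwise it is labeled "uncertain".  With the default
k=5 / min_votes=3 rule at most one label can reach the vote threshold
(pigeonhole), so the assignment is never ambiguous.  Distance ties at the
k-th neighbor break by reference cell index, making the transfer
deterministic.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

__all__ = ["UNCERTAIN", "knn_transfer", "annotation_concordance", "downsample_reference"]

UNCERTAIN = "uncertain"


def knn_transfer(
    query_coords: np.ndarray,
    ref_coords: np.ndarray,
    ref_labels: Sequence,
    k: int = 5,
    min_votes: int = 3,
    chunk: int = 2048,
) -> np.ndarray:
    """Majority-vote label transfer from reference to query cells."""
    query_coords = np.asarray(query_coords, float)
    ref_coords = np.asarray(ref_coords, float)
    ref_labels = np.asarray(ref_labels, dtype=object)
    if query_coords.shape[1] != ref_coords.shape[1]:
        raise ValueError("query and reference embeddings must share dimensions")
    if k > len(ref_coords):
        raise ValueError(f"k={k} exceeds reference size {len(ref_coords)}")
    if not (np.all(np.isfinite(query_coords)) and np.all(np.isfinite(ref_coords))):
        raise ValueError("embeddings must be finite")

    out = np.empty(len(query_coords), dtype=object)
    ref_idx = np.arange(len(ref_coords))
    for start in range(0, len(query_coords), chunk):
        block = query_coords[start : start + chunk]
        d = cdist(block, ref_coords)
        # stable ordering: by distance, then reference index (documented tie-break)
        order = np.lexsort((np.broadcast_to(ref_idx, d.shape), d), axis=1)[:, :k]
        for i, neigh in enumerate(order):
            labels, counts = np.unique(ref_labels[neigh], return_counts=True)
            winners = labels[counts >= min_votes]
            if len(winners) > 1:
                raise RuntimeError(
                    "two labels reached the vote threshold; impossible for "
                    f"k={k}, min_votes={min_votes} unless min_votes <= k/2"
                )
            out[start + i] = winners[0] if len(winners) == 1 else UNCERTAIN
    return out


def annotation_concordance(
    labels_a: Sequence,
    labels_b: Sequence,
    fallback_labels: frozenset | set = frozenset({"hESC", UNCERTAIN}),
) -> tuple[float, float]:
    """Agreement between two annotations of the same cells.

    Returns ``(fraction_same, fraction_discordant_in_fallback)``: the
    fraction of cells with identical labels, and — among discordant cells
    — the fraction whose label in either annotation is a fallback label
    (pluripotent-reference or uncertain calls).  The second value is NaN
    when there are no discordant cells.
    """
    a = np.asarray(labels_a, dtype=object)
    b = np.asarray(labels_b, dtype=object)
    if len(a) != len(b):
        raise ValueError(f"label vectors differ in length: {len(a)} vs {len(b)}")
    same = a == b
    frac_same = float(same.mean()) if len(a) else float("nan")
    disc = ~same
    if not disc.any():
        return frac_same, float("nan")
    in_fb = np.array(
        [(x in fallback_labels) or (y in fallback_labels) for x, y in zip(a[disc], b[disc])]
    )
    return frac_same, float(in_fb.mean())


def downsample_reference(
    ref: pd.DataFrame,
    label_col: str = "label",
    max_per_type: int = 500,
    seed: int = 0,
) -> pd.DataFrame:
    """Cap the reference at ``max_per_type`` cells per annotation (data-prep
    utility for very large references)."""
    rng = np.random.default_rng(seed)
    parts = []
    for _, grp in ref.groupby(label_col, sort=True):
        if len(grp) > max_per_type:
            take = rng.choice(len(grp), size=max_per_type, replace=False)
            grp = grp.iloc[np.sort(take)]
        parts.append(grp)
    return pd.concat(parts).reset_index(drop=True)
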