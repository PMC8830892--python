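"""Species assignment from discordant-read mapping summaries.

Samples here mix human and chimpanzee cells in one droplet run; after
aligning each read to both genomes, reads that map with different scores
in the two species ("discordant reads") point to the cell's species of
origin.  A barcode is called human when it carries at least
``min_human_higher`` discordant reads favoring the human genome AND at
least ``min_fraction`` of its discordant reads favor the human genome.
Both conditions are required; the fraction is compared in exact rational
arithmetic so the 4/5 boundary is handled without float artifacts.

Barcodes with zero discordant reads are called "other": the fraction is
undefined and the rule cannot be satisfied.  Reads with equal scores in
both species are by definition not discordant and never enter the
counts.
"""

from __future__ import annotations

import logging
from fractions import Fraction

import numpy as np
import pandas as pd

__all__ = ["call_species", "HUMAN", "OTHER"]

HUMAN = "human"
OTHER = "other"

logger = logging.getLogger(__name__)


def _as_fraction(x) -> Fraction:
    if isinstance(x, Fraction):
        return x
    # floats like 0.8 are meant as short decimals, not their binary expansions
    return Fraction(x).limit_denominator(10**9)


def call_species(
    table: pd.DataFrame,
    min_human_higher: int = 5,
    min_fraction: float | Fraction = Fraction(4, 5),
) -> pd.Series:
    """Label every barcode human/other from its discordant-read summary.

    Parameters
    ----------
    table
        Columns ``barcode``, ``n_discordant``, ``n_human_higher``.
    min_human_higher
        Minimum count of human-favoring discordant reads (inclusive).
    min_fraction
        Minimum fraction of discordant reads favoring human (inclusive).

    Returns
    -------
    pandas.Series of ``"human"``/``"other"`` indexed by barcode.
    """
    n_disc = table["n_discordant"].to_numpy()
    n_hh = table["n_human_higher"].to_numpy()
    if np.any(n_disc < 0) or np.any(n_hh < 0):
        raise ValueError("read counts must be non-negative")
    if np.any(n_hh > n_disc):
        bad = table.loc[n_hh > n_disc, "barcode"].tolist()[:5]
        raise ValueError(f"n_human_higher exceeds n_discordant for barcodes {bad}")

    frac = _as_fraction(min_fraction)
    num, den = frac.numerator, frac.denominator
    # h/d >= num/den  <=>  h*den >= d*num  (d > 0); exact integer comparison
    passes_count = n_hh >= min_human_higher
    passes_frac = (n_disc > 0) & (n_hh.astype(object) * den >= n_disc.astype(object) * num)
    labels = np.where(passes_count & passes_frac, HUMAN, OTHER)

    n_zero = int((n_disc == 0).sum())
    if n_zero:
        logger.info("%d barcodes with zero discordant reads labeled %s", n_zero, OTHER)
    return pd.Series(labels, index=pd.Index(table["barcode"], name="barcode"), name="species")
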