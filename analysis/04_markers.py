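"""Marker genes per cell type from pseudobulk differential expression.

Builds the (individual, replicate, cluster) pseudobulk, TMM-normalizes,
computes voom precision weights, fits the no-intercept weighted linear
model, and ranks each cluster's markers by adjusted p and by log fold
change.
"""

import pandas as pd

from common import simulate, outdir

from ebvar.markers import fit_contrast_model, rank_markers
from ebvar.pseudobulk import make_pseudobulk, tmm_factors, voom_weights
from ebvar.qc import filter_genes_cluster_fraction


def main() -> None:
    out = outdir()
    _, counts, cells, _ = simulate()
    mask = filter_genes_cluster_fraction(counts, cells["cluster"], min_fraction=0.2)
    print(f"gene filter (>=20% of cells in some cluster): kept {mask.sum()}/{len(mask)}")
    counts = counts.subset_genes(mask)

    pb = make_pseudobulk(counts, cells)
    tmm_factors(pb)
    weighted = voom_weights(pb)
    result = fit_contrast_model(weighted)
    ranked = rank_markers(result, per_cluster=10)

    tables = []
    for contrast, lists in ranked.items():
        for key in ("by_adjusted_p", "by_logFC"):
            t = lists[key].assign(ranking=key)
            tables.append(t)
        top = lists["by_adjusted_p"].iloc[0]
        print(
            f"{contrast}: top marker {top['gene']} "
            f"(logFC {top['logFC']:.2f}, adj. p {top['adjusted_p']:.2g})"
        )
    pd.concat(tables).to_csv(out / "markers_top10.tsv", sep="\t", index=False)
    n_sig = int((result.table["adjusted_p"] < 0.05).sum())
    print(f"{n_sig} (gene, contrast) pairs significant at adjusted p < 0.05")


if __name__ == "__main__":
    main()
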