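"""Generate the synthetic embryoid-body experiment and summarize it.

Writes the per-sample cell-type composition table and the scenario's
theoretical variance fractions, which later drivers try to recover.
"""

import json

from common import SEED, simulate, outdir

from ebvar import synthetic
from ebvar.composition import cluster_proportions


def main() -> None:
    out = outdir()
    cfg, counts, cells, truth = simulate()
    print(
        f"simulated {counts.n_genes} genes x {counts.n_cells} cells "
        f"({cfg.n_individuals} individuals x {cfg.n_replicates} replicates, "
        f"{len(cfg.cell_types)} cell types), total UMIs {counts.total_counts():,}"
    )
    print("theoretical log-scale variance fractions:", truth.theoretical_fractions)

    props = cluster_proportions(cells)
    props.values.to_csv(out / "composition_proportions.tsv", sep="\t")
    (out / "sim_truth.json").write_text(
        json.dumps({"seed": SEED, "fractions": truth.theoretical_fractions}, indent=2)
    )

    # the poorly differentiating line: one individual stuck at 89% pluripotent
    low_cfg = synthetic.default_config(
        n_genes=50, cells_per_group=400, low_efficiency_individual=(0, 0.89),
        seed=SEED,
    )
    _, low_cells, _ = synthetic.simulate_counts(low_cfg)
    low_props = cluster_proportions(low_cells)
    share = low_props.values.loc[
        low_props.sample_meta["individual"].to_numpy() == "ind0", "pluripotent"
    ].mean()
    print(f"low-efficiency individual pluripotent share: {share:.1%} (target 89%)")
    low_props.values.to_csv(out / "composition_low_efficiency.tsv", sep="\t")


if __name__ == "__main__":
    main()
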