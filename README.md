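# ebvar

Variance structure and study design for multi-individual embryoid-body
(EB) scRNA-seq experiments.

EBs — aggregates of spontaneously differentiating iPSCs containing cell
types from all three germ layers — are a candidate system for mapping
eQTLs across many developing cell types at once. Before committing to a
large study, one needs to know how much expression variation is
attributable to cell type, to individual, and to technical replicate,
and how detection power scales with the number of individuals and cells.
`ebvar` implements that pilot-analysis toolchain as a reusable, tested
Python package: species demultiplexing by discordant read mapping, QC
threshold filters, pseudobulk aggregation with TMM normalization and
voom-style precision weights, marker-gene differential expression,
per-gene crossed random-effects variance partitioning by REML,
hierarchical clustering of cell-type composition, k-nearest-neighbor
label transfer, and an eQTL power-design calculator. A synthetic-data
generator with known ground truth makes every stage testable without any
external download.

## The models at the core

**Variance partitioning.** Per gene, expression y over samples
(pseudobulk groups or single cells) follows a Gaussian mixed model with
crossed random intercepts,

    y = 1·μ + Σ_k Z_k u_k + e,   u_k ~ N(0, σ_k² I),   e ~ N(0, σ_e² W⁻¹),

for factors k ∈ {cluster, individual, replicate} and optional precision
weights W. Components are estimated by REML (profiled likelihood,
analytic gradients, bounded quasi-Newton); the reported fraction for
factor k is σ_k² / (Σ_j σ_j² + σ_e²).

**Power.** For a simple-linear-regression eQTL test with standardized
effect β, per-test level α, n individuals and phenotype SD σ,

    Pow(β, α, n, σ) = Φ( Φ⁻¹(α/2) + (β/σ)·√n ),

with α = FWER / n_genes (Bonferroni). σ is estimated as a function of
experiment size E (total cells) by evenly downsampling cells, rebuilding
pseudobulk, partitioning variance, and fitting the decay
v(E) = a·e^(−bE) + c with σ(E) = √v(E). A Monte-Carlo oracle quantifies
the formula's normal-approximation error (see `docs/methods.md`).

## Worked example

The numbered drivers under `analysis/` run the whole pipeline on the
default synthetic scenario (7 cell types × 3 individuals × 3 replicates;
log-scale variance fractions 0.60/0.05/0.05/0.30 by construction) and
write their tables to `results/`:

```
cd analysis
python 05_variance_partition.py
```

prints

```
theoretical fractions: {'cluster': 0.6, 'individual': 0.05, 'replicate': 0.05, 'residual': 0.3}
pseudobulk medians: cluster=0.87, individual=0.04, replicate=0.05, residual=0.01
single-cell medians: cluster=0.25, individual=0.02, replicate=0.01, residual=0.70
single-cell residual median (0.70) exceeds pseudobulk (0.01): per-cell noise is retained at cell resolution
```

Pseudobulk aggregation averages away per-cell noise, so the residual
median collapses and the cluster share swells; at single-cell resolution
the residual dominates instead — the two views bracket the same
underlying structure. And `python 08_power_analysis.py` prints

```
decay fit: v(E) = 0.659*exp(-2.92e-04*E) + 0.166
at the 58 x 3000 design (E = 174,000 cells): sigma = 0.408, power = 100.0%
    for standardized effect 0.6 at alpha = 5.0e-06
```

i.e. with the synthetic decay curve, residual variance bottoms out at
~0.17, and a 58-individual × 3,000-cell design has essentially full
power for standardized effects of 0.6 at the Bonferroni threshold.

A thin CLI mirrors the main stages
(`ebvar simulate|demux-species|qc|transfer-labels|power --help`).

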