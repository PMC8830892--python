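# Methods

`ebvar` re-implements, as a tested pipeline, the bespoke computational
stages of a multi-individual embryoid-body (EB) scRNA-seq study design:
species demultiplexing, QC filtering, pseudobulk differential expression,
crossed random-effects variance partitioning, composition clustering,
k-nearest-neighbor label transfer, and an eQTL power calculator. This
note records the models, the defaults and their units, the numerical
choices, and what the synthetic data can and cannot show.

## Synthetic count model

The generator draws UMI counts for cell *c* of type *t*, individual *i*,
replicate *r* at gene *g* as

    count ~ Poisson( s_c * exp(mu_g + a_{g,t} + b_{g,i} + c_{g,r} + e_c) )

with per-gene effects a, b, c ~ Normal(0, sd_k²), a per-cell lognormal
noise factor e_c ~ Normal(0, cell_noise_sd²), and a lognormal relative
library factor s_c. A single global rescaling sets the mean library size
(default e^8.5 ≈ 5,000 UMIs) without touching the variance structure.
The Poisson-lognormal construction was chosen over an explicit negative
binomial because the lognormal cell factor supplies overdispersion while
keeping the additive log-scale random-effects structure that the
variance partition assumes; it is a stand-in for real EB counts, whose
generative distribution is not established, not a claim about them.

Default scenario: 7 cell types × 3 individuals × 3 replicates, with
effect SDs (sd_celltype², sd_individual², sd_replicate², cell_noise_sd²)
= (6, 0.5, 0.5, 3) so the theoretical log-scale variance fractions are
(0.60, 0.05, 0.05, 0.30) for (cell type, individual, replicate,
residual) — the regime the pipeline is designed to resolve, where cell
type dominates and individual and replicate contribute equally and
modestly. Mitochondrial genes are flagged by an "MT-" feature-name
prefix (human nomenclature, which the QC stage keys on). Replicate-level
compositions are Dirichlet draws around individual-specific means
(concentration 200 by default — visible but modest replicate noise on
the simplex); an optional low-differentiation-efficiency individual has
its pluripotent-type mean pinned (default 0.89, the share observed for
the poorly differentiating line in the motivating data set). Genotypes
are Binomial(2, MAF) dosages with an exactly standardized copy.

What the generator does not emulate: doublets, ambient RNA, empty
droplets, batch-specific capture efficiency, trajectories/pseudotime,
and any realistic gene–gene correlation. Passing tests therefore
demonstrate that each algorithm recovers the structure it models, not
that real EB data satisfy those models.

## Species demultiplexing

A barcode is called human iff it has ≥ 5 discordant reads (reads mapping
with different scores against the human and chimpanzee genomes) favoring
human AND ≥ 80% of its discordant reads favor human. Both bounds are
inclusive ("at least"). The fraction is compared by integer
cross-multiplication, so the 4/5 boundary is exact. Barcodes with zero
discordant reads are called "other" (the fraction is undefined and the
rule cannot be met); reads scoring equally in both species are by
definition not discordant and never enter the counts.

## QC filters

Primary cell profile: mitochondrial read fraction in [0.03, 0.20]
(bounds inclusive; the source prose is ambiguous, so inclusivity is
configurable) and strictly more than 1,500 genes detected. The
additional-lines profile removes cells with mito > 0.15, mito < 0.03, or
fewer than 1,000 genes. Gene filters: expressed in ≥ 20% of cells of at
least one cluster (pre-DE and pre-variance-partition), detected in ≥ 10
cells, or pseudobulk support (≥ 10 counts in some sample and ≥ 15
total). Cells with zero total counts get mito fraction 0 and a flag.

## Pseudobulk, TMM, voom

Pseudobulk is the per-gene sum of counts over cells sharing (individual,
replicate, cluster). The summation contract accepts any per-cell
normalized matrix; the synthetic pipeline sums raw counts. TMM factors
follow the standard trimmed-mean-of-M-values recipe: reference column by
upper-quartile closeness to the mean, genes zero in either column
excluded, 30%/5% two-sided trims on M and A by rank, inverse
asymptotic-variance weights, factors rescaled to geometric mean 1. The
voom-style weights use log2((count + 0.5)/(lib·factor + 1)·1e6), a
per-gene OLS residual SD, a lowess fit of sqrt-SD against mean
log2-count (span 0.5, configurable), interpolation at each observation's
fitted log-count, and weight = predicted-SD⁻⁴ clipped to [1e-6, 1e6].
Both are implemented here in Python and are checked against independent
brute-force oracles in the tests. Pseudobulk values are accepted as
reals (not rounded) before TMM/voom.

## Marker differential expression

Per gene, weighted least squares under the no-intercept design with one
indicator per cluster level plus drop-first indicators for replicate and
individual. The "cluster k vs rest" contrast is β_k minus the unweighted
mean of the other cluster coefficients — symmetric and estimable under
this parameterization. Two-sided t-tests on the WLS residual degrees of
freedom; Benjamini–Hochberg adjustment across genes within each
contrast. No empirical-Bayes variance moderation is applied — this is
the one deliberate simplification relative to the limma-style analysis
the design mimics, and it is visible in the tests as exact agreement
with a plain normal-equations oracle. Marker ranking: top N by adjusted
p (ties by |t|, then gene id) and top N by logFC (ties by adjusted p,
then gene id).

## Variance partitioning

Per gene, a Gaussian linear mixed model with a global mean and
independent random intercepts per factor:

    y = 1·mu + Σ_k Z_k u_k + e,  u_k ~ N(0, σ_k² I),  e ~ N(0, σ_e² W⁻¹)

with optional voom precision weights W. Estimation is REML with the
residual variance profiled out analytically, leaving a bounded
optimization over the variance ratios γ_k = σ_k²/σ_e². The profiled
restricted likelihood and its analytic gradient are evaluated through
the Woodbury identity on the stacked random-effects design, so one
evaluation costs O(n·K + q³) (q = total factor levels) — cheap even with
thousands of cells as samples. The optimizer is multi-start L-BFGS-B
(starts at γ = 0.1, 1, 10) with bounds γ ≥ 0; ratios below 1e-10 are
pinned to zero and flagged as singular. A gradient-based optimizer was
chosen over EM-style updates because EM's linear convergence near the
optimum could not reliably reproduce closed-form balanced-ANOVA
components to 1e-8, which the test suite requires; with analytic
gradients the agreement is ~1e-12. Non-convergence is flagged, never
raised. Fractions are σ_k²/(Σσ_j² + σ_e²).

Modes: pseudobulk (log2-CPM of group sums, voom weights when supplied),
single-cell (each cell a sample — residual fractions are much larger
because per-cell noise is not averaged away), and per-cluster
(replicate + individual only; clusters without ≥ 2 individuals and ≥ 2
replicates are skipped with a reason). The cluster factor is
algorithm-derived, so its fraction is an upper bound on cell-type
variance; every result object carries this caveat. Genes with zero
variance get fractions (0, …, 0, 1) and a "constant" flag.

## Composition clustering

Samples are (individual, replicate) pairs described by cluster
proportions or mean topic loadings. Agglomerative clustering uses
complete linkage on Euclidean distances (the distance is configurable;
raw columns by default, optional z-scaling). "Clusters by individual" is
true when cutting the tree into one group per individual exactly
reproduces the individual partition, and is scored by the adjusted Rand
index — a quantitative stand-in for a qualitative claim.

## Label transfer

Each query cell takes the annotation shared by ≥ 3 of its 5 nearest
reference cells (Euclidean distance in the provided embedding, dimension
count free); otherwise "uncertain". With k = 5 and 3 votes, two winners
are impossible (pigeonhole), which the code asserts defensively.
Distance ties at the k-th neighbor break by reference index for
reproducibility. No embedding or batch correction is performed here —
the module consumes an integrated embedding or a synthetic one.
Concordance between two annotations reports the fraction of identically
labeled cells and, among discordant cells, the fraction whose label in
either annotation is a fallback label (default {hESC, uncertain}); the
second value is NaN when nothing is discordant.

## Power analysis

Analytic power for a simple-linear-regression eQTL test:

    Pow(β, α, n, σ) = Φ( Φ⁻¹(α/2) + (β/σ)·√n )

implemented exactly as printed — a one-tail, normal-theory
approximation. β is the standardized additive effect size (the source
text's "additive significance level" is read as a typo for effect
size). α is the Bonferroni-corrected per-test level (FWER 0.05 over
10,000 genes gives α = 5×10⁻⁶). At β = 0 the formula returns α/2 by
construction.

A Monte-Carlo oracle simulates the actual study: Binomial(2, MAF)
genotypes standardized to unit sample variance, phenotype
β·g + Normal(0, σ²), two-sided t-test of the slope. Its purpose is to
quantify the formula's approximation error, which has two sources: the
dropped second tail (negligible at any useful power) and the normal-vs-t
critical value (large when residual degrees of freedom are small
relative to the stringency of α). The calibration tests therefore
compare formula and oracle on a 12-point lattice with large df — α =
0.05 at n ∈ {400, 900} and α = 5×10⁻⁶ at n = 2500, all with β√n ≥ 2 —
where exact noncentral-t computation puts the true gap below 0.002. At a
small-sample stringent-α design such as 58 individuals with α = 5×10⁻⁶,
the formula overstates the true two-sided t-test power by ≈ 0.16 at
mid-range power; the suite asserts this gap as a documented property of
the formula rather than pretending it is small. Design conclusions drawn
from the formula at small n should be read as optimistic.

The phenotype SD for an experiment of E total cells comes from
downsampling: draw subsamples of E cells split as evenly as possible
across individual × replicate groups (remainders assigned by seeded
shuffle; exhausted groups are sampled fully with a warning), rebuild the
(cluster, individual, replicate) pseudobulk, apply the 20%-in-a-cluster
gene filter computed on the full data, TMM-normalize, partition
variance, and record the median residual variance component; the
per-size value is the median over draws (default 10). An exponential
decay v(E) = a·exp(−b·E) + c (a ≥ 0 amplitude, b > 0 rate per cell,
c ≥ 0 asymptote, all in squared-log2-CPM units) is fit by nonlinear
least squares with c₀ = min v, a₀ = max v − c₀, b₀ from a log-linear fit
of v − c₀, and five jittered restarts; σ(E) = √v(E). The decay family is
named in the source; the specific three-parameter form, offsets and
fitter are this package's choices. Power grids over (β, n, cells per
individual) use E = n·cells and warn when E extrapolates beyond 5× the
largest fitted size (grids at realistic designs always extrapolate from
desk-scale simulations; the σ used is then essentially the asymptote c).

## Problem sizes

The analysis drivers and acceptance script run at desk scale: 300 genes
× 1,350 cells for the main scenario, 200 genes × 5,400 cells for the
downsampling curve (sizes E ∈ {1350, 2700, 4050, 5400}, 3 draws),
1,000 genes for variance-component recovery, 100,000 simulations per
Monte-Carlo calibration point. Headline numbers of the motivating study
(42,488 QC-passing cells, the 60/5/5/30 and 93% variance medians, the
79%/82% concordance, 93% power at the 58×3,000 design) depend on the
deposited data or on an unpublished fitted σ and are reproduced here
only as qualitative synthetic analogues.
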