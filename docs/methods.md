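# Methods

## Scope and data model

The pipeline consumes a beta-value matrix (CpGs × samples), a raw count
matrix (genes × samples), a sample table (donor, group, timepoint, cell
type, state, covariates), a CpG→gene annotation, a STRING-dialect PPI edge
list and GMT gene sets. Matrices enter post array-level normalization;
array QC (detection p-value, bead count, GC start, SNP proximity) is
available as a separate `filter_probes` step. A probe is removed when it
*fails* detection (p ≥ 0.01) in any sample, has a bead count < 3 anywhere,
lacks a GC start, or sits near a SNP — the standard array-QC reading of
the filter list. Batch is handled, when present, as an additive fixed
effect in the design; no empirical batch-correction algorithm is applied.

## Differential model

Methylation is tested on M-values, `M = log2(β/(1−β))` with β clipped to
[1e−6, 1−1e−6] — the variance-stabilized scale on which linear modelling
of methylation is well behaved. Expression is tested on log-CPM:
`log2((count + 0.5)/(lib·f + 1) · 1e6)` with TMM scaling factors `f`.

**TMM.** Factors follow the published trimmed-mean-of-M-values recipe:
reference = sample whose upper-quartile CPM is closest to the mean upper
quartile; per-gene log-ratios doubly trimmed (30% on M, 5% on A); weighted
mean with inverse asymptotic binomial-variance weights; factors rescaled
to geometric mean 1. The trim fractions are the method's published
defaults. The implementation agrees with edgeR's `calcNormFactors` to
1e−8 on test matrices (checked by a test that shells out to Rscript).
Note the sign of composition corrections: a sample in which a few genes
are strongly inflated receives a factor *below* 1, because the inflation
enlarges its library size and leaves every other gene looking
undersampled.

**Low-count filter.** A gene is dropped when its CPM (library size =
pre-filter column sum) is below 10 in at least 70% of samples. Filtering
precedes TMM computation, matching the edgeR workflow order.

**Design.** One indicator per observed (group, timepoint) cell, dropping
each group's reference timepoint (default T1), plus numeric covariates
(age, memory-cell fraction, viability; optionally activation level and
batch). Groups missing a timepoint — e.g. controls with no
before-pregnancy visit — simply contribute no column for it, so
unbalanced designs are handled without special-casing. Rank deficiency is
detected by pivoted QR and reported with the implicated column names.

**Donor correlation.** Repeated samples of a donor are modelled by a
single consensus equicorrelation ρ. Per feature, OLS residuals `r = My`
(M = I − H) give a within-donor cross-product sum `q = ½ r'Pr` (P = same-
donor off-diagonal indicator) and residual sum of squares `v = r'r`. Both
have first moments linear in ρ:
`E[q] = σ²[(1−ρ)·tr(PM)/2 + ρ·tr(PMBM)/2]`,
`E[v] = σ²[(1−ρ)(n−p) + ρ·tr(MB)]` (B = same-donor block indicator).
Each feature's ratio q/v is mapped through this linear-fractional relation
to a per-feature ρ̂, which removes the attenuation the hat-matrix
projection would otherwise introduce; the consensus is the
back-transformed 5%-trimmed mean of the Fisher-z values. This is a
deliberate, testable simplification of the REML-based estimator used in
the reference workflow: simulations recover ρ ∈ {0, 0.3, 0.5, 0.7} within
±0.02 at 5,000 features with 16 donors × 4 timepoints, and the
acceptance suite enforces ±0.1.

**Precision weights.** For counts, OLS is fitted per gene on log-CPM, the
square root of the residual SD is smoothed against average log2 count by
lowess (span 0.5), and each observation's weight is the trend value at
its fitted log-count to the power −4 — the standard mean-variance
weighting for RNA-seq. Fewer than 50 genes triggers a warning and uniform
weights.

**GLS.** Per feature, errors have covariance `diag(w)^{-1/2} C
diag(w)^{-1/2}` with C block-equicorrelated at ρ; fitting whitens by the
Cholesky factor of C after scaling by √w. With ρ = 0 and unit weights
this is exactly OLS (tested to 1e−10); with arbitrary ρ and weights it
matches a direct solve of the GLS normal equations (tested to 1e−8).

**Moderation.** The prior (d₀, s₀²) is estimated by matching the first
two moments of `log s²_g` to a scaled F distribution via trigamma
inversion (Newton iteration); `s̃²_g = (d₀s₀² + d_g s²_g)/(d₀ + d_g)`;
moderated t uses d₀ + d_g degrees of freedom. Degenerate cases: equal
variances → d₀ = ∞ (all variances replaced by s₀², normal reference);
d₀ = 0 reproduces the ordinary t exactly. A contrast with zero standard
error (e.g. the all-zero contrast) reports estimate 0 and p = 1.

**Calling.** DMP: nominal p ≤ 0.05 and |Δβ| > 0.05, where Δβ is the
difference of group-mean beta values between the two timepoints (group
mean, not paired within-donor mean — the simpler reading of an
unbalanced design). Direction follows the sign of Δβ; a probe whose Δβ
and M-scale coefficient disagree in sign (possible near β = 0 or 1) is
excluded and counted. DEG: nominal p ≤ 0.05, direction from the
coefficient sign. Both thresholds include the boundary p = 0.05; the
Δβ threshold is strict (|Δβ| = 0.05 is not called). BH adjustment is
computed per contrast within omic.

## Rebound classification

A feature rebounds when significant in both the (3rd − 1st) and
(PP − 3rd) windows with opposite directions; same-direction
double-significant features are reported separately (the two sets
partition the significant-in-both set). For DMPs the |Δβ| criterion is
required in both windows, for symmetry. The shared rebound set contains
features rebounding in both groups with the identical pattern; per
window, the percentage of direction agreement between groups is emitted
(the quadrant table). Shared rebound DMPs map to genes (DMGs) by
annotation union, keeping all genes of multi-mapped probes.

## Network modules

The PPI network keeps edges with combined score ≥ 700 (≥ 950 for the
exported visualization subgraph), deduplicating symmetric pairs (higher
score wins) and dropping self-loops. DIAMOnD expansion: at each step,
every outside node with ≥ 1 link into the module is scored by
`P(X ≥ k_s)` for a hypergeometric draw of its degree k from the N-node
network containing the s-node module; the smallest p joins. N is the
node count of the score-filtered graph. Ties break toward smaller
degree, then lexicographically smaller gene id, making the expansion
fully deterministic (the original algorithm leaves ties unspecified).
The optional integer seed weight α ≥ 1 counts seed nodes and seed links
α times (α = 1, the default, is the plain algorithm). Tails are computed
in log space by the pmf ratio recurrence — no underflow for N up to at
least 20,000 and degrees in the thousands — and match exact rational
enumeration to ~1e−9 relative. Expansion stops after `n_added` genes
(default 200) or when no candidate remains. Seeds are the shared rebound
DEGs (expression) and shared rebound DMGs (methylation); seeds missing
from the network are reported, not silently dropped. The rebound
pregnancy module is the intersection of the two per-omic modules, with a
Fisher overlap test against the network's node set.

## Enrichment

Fisher enrichment reports the sample odds ratio ad/bc (an `inf` sentinel
when bc = 0) and the one-sided exact p (two-sided by flag). Pathway
enrichment over a GMT collection uses one-sided hypergeometric tails with
BH correction across sets; the universe is the measured genes, extended
by the network's genes when module genes are tested (module genes may be
unmeasured network genes — without the extension their enrichment would
be inflated). GWAS SNPs with p < 1e−6 map to the gene with the nearest
TSS provided the signed, strand-aware distance lies within −3000..+3000;
equidistant ties go to the lexicographically smaller gene id. BED inputs
(0-based half-open) are converted to 1-based TSS tables by a documented
helper.

The correlation-conservation analysis computes, per group, the Spearman
correlation of each annotated CpG–gene pair across that group's paired
samples (pooled across timepoints within a cell type), bins |ρ| into
within-group deciles (independently per group), and Fisher-tests
per-decile co-membership across groups. Spearman makes the analysis
invariant to monotone transformations of either omic.

## Synthetic cohorts

The generator emulates the study conditions the pipeline assumes:
default 11 + 7 donors in two groups over BP/T1/T2/T3/PP with the BP visit
absent in controls; recovery and calibration studies use the balanced
8 + 8 donors × 4 timepoints design. Methylation is generated on the M
scale — per-CpG baseline from a bimodal mixture (mostly methylated /
mostly unmethylated / intermediate), planted time effects, centered
covariate terms, a donor random intercept with SD `σ·sqrt(ρ/(1−ρ))` (so
the intra-donor correlation is exactly ρ), Gaussian noise with per-CpG σ
log-normal around 0.3 — then mapped to β. Planted rebound CpGs draw
their baseline from the intermediate range (M ∈ [−1.5, 1.5]) so that an
M-scale shift of 2 is visible on the beta scale; this mirrors the
empirical fact that responsive CpGs sit at intermediate methylation, and
without it the |Δβ| > 0.05 filter would silently censor planted truth at
the extremes. Counts are gamma-Poisson (negative binomial, dispersion
0.1) around a log2-CPM design with the same structure; library sizes are
log-uniform over [1.5e6, 6e6] (a 4-fold range, making TMM/CPM
non-trivial). Note that ρ applies to the latent log-scale signal; count
sampling noise dilutes the realized log-CPM correlation, as in real
RNA-seq. The planted rebound profile is 0 at BP/T1, half effect at T2,
full effect at T3 and 0 at PP, sign randomized per feature and identical
in both groups. Rebound CpGs annotate round-robin onto the rebound genes
(so both omics point at the same planted gene set); background CpGs map
to one (∼80%) or two (∼10%) random background genes or carry no
annotation (∼10%). The PPI graph is preferential attachment (3 edges per
node) plus extra edges among planted genes up to an internal density of
0.3; edge scores are uniform in [700, 1000]. One designated "disease"
gene set contains a configurable fraction of the planted genes plus
random fillers. All randomness flows from a single master seed through
spawned sub-streams, so every artifact is independently reproducible.

What the generator does *not* emulate: bisulfite chemistry and probe
hybridization artifacts, read-level sequencing, genomic autocorrelation
of CpGs, co-expression structure beyond the planted module, and batch
effects beyond an additive covariate. Passing recovery tests therefore
demonstrates the statistical machinery is correct and calibrated under
the assumed model, not that the thresholds are optimal for any
particular real cohort.

## Numerical and design choices

- Effect sizes of real pregnancy effects are unknown; the planted effect
  of 2 (M-scale / log2 fold change) is a simulation parameter chosen to
  give high but not saturated per-window power at 8 donors per group.
- The moment-matching moderation handles d₀ = ∞ without overflow; the
  trigamma inverse uses the standard Newton scheme with asymptotic
  seeds.
- The consensus-ρ estimator trims 5% of Fisher-z values per tail and
  clips per-feature estimates to the positive-definiteness bound
  −1/(max block − 1).
- The module stage is skipped (with an explicit manifest entry) when a
  shared rebound seed set is empty or disjoint from the network.
- Problem sizes used by the test and acceptance studies (up to 10,000
  CpGs + 4,000 genes for null calibration; 20 seeds × 5,000 features for
  recovery) were chosen as the smallest designs at which the binomial /
  sampling error of the measured quantities is comfortably inside the
  asserted bands.

## Known limitations

- The consensus-correlation estimator assumes a common ρ across
  features; feature-specific donor correlation is absorbed only on
  average.
- Δβ uses group means; a paired within-donor mean would differ in
  strongly unbalanced designs.
- voom weights come from an OLS first pass (no iterated re-weighting
  with the estimated ρ).
- Enrichment is overlap-based only; no ranked (GSEA-style) statistics,
  no GO topology.
- The pipeline analyzes one cell type per invocation; run it per cell
  type and combine tables downstream.
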