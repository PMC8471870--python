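# Methods

This note documents the models, numerical choices, and design decisions
behind the package, and what the synthetic-data tests do and do not show
about real data.

## Scope and data model

The pipeline compares two-group (control vs case) expression cohorts of two
platforms: RNA-seq **counts** (non-negative integers) and array-style
**log-intensities** (finite reals). A cohort is an `ExpressionMatrix`
(genes × samples) plus a sample table (`sample`, `group`, `cohort`,
optional `fibrosis_area`). Cross-species cohorts enter with source-species
gene ids and are re-keyed to human symbols through an orthologue table
(`source_gene`, `human_symbol`, `pct_identity`). Gene sets are GMT files.
All on-disk formats are TSV; readers reject rather than coerce malformed
input, and every writer/reader pair round-trips losslessly.

## Preprocessing

**Orthologue harmonization.** Rows with no mapping are dropped, as are rows
whose identity is ≤ 50% — the cutoff is strict (`> 50`), and the boundary
is tested. When several source genes map to one human symbol the row with
the highest identity wins; ties break by higher mean expression, then by
lexicographically smaller source id. This keep-one rule (rather than
summing colliding rows) avoids mixing paralogue dispersions and is
deterministic under permutation of the map; it is a documented package
choice — collapse conventions vary between studies. A mapping report
counts drops per reason.

**Count filter.** Genes with total count < 200 across all samples are
removed (strict comparison; a gene totalling exactly 200 stays).

**Normalization.** Median-of-ratios size factors:
s_j = median over genes with positive counts in every sample of
k_ij / geomean_i(k_i·). A single sample gets s = 1; a matrix with no
all-positive gene is an error.

**Transform.** `vst_log` computes log2(k_ij/s_j + 1) and tags the result
as intensity platform. This is a pragmatic stand-in for regularized-log
transforms whose shrinkage parameters are implementation-specific; the
downstream consumers (PCA, Pearson correlations, rank-based metrics) are
robust to the difference, and the transform is pluggable.

## Differential expression

**Counts: negative-binomial Wald test.** Per gene, normalized group means
m₀, m₁ (a 0.5 pseudo-count is added to both when either is zero, keeping
fold changes finite); log2FC = log2(m₁/m₀). Dispersion is estimated per
gene by method of moments on normalized counts using the moment equation
Var(k_ij/s_j) = μ/s_j + α·μ² (the Poisson term is scaled by the mean
reciprocal size factor of the group), averaged over the two groups and
floored at 1e-8. The standard error of log2FC comes from the delta method:
se² = [Var(m₀)/m₀² + Var(m₁)/m₁²] / ln²2 with
Var(m_g) = (m_g·mean(1/s) + α·m_g²)/n_g.

The statistic log2FC/se is referred to a **Student t with n₀+n₁−2 df**
rather than a normal. With the group sizes this pipeline targets (n = 6
per group), the dispersion estimate is noisy, and the normal reference is
visibly anticonservative (measured type-I ≈ 0.073–0.079 at α = 0.05 on
5000-gene null cohorts), while the t reference is calibrated
(≈ 0.043–0.052). The t reference is the package's small-sample choice; it
converges to the normal as n grows.

This engine deliberately omits the dispersion-trend shrinkage, fold-change
shrinkage, and outlier handling of full RNA-seq packages. At planted-truth
scale the relevant contract is sign/effect recovery (≥ 90% of planted
genes with |log2FC| ≥ 1 recovered in sign and within ±0.5, enforced in
tests) and null calibration — not bit-equality with any particular
package. The DE engine is pluggable behind the `DEResult` table contract.

**Arrays: empirical-Bayes moderated t.** Per gene, the difference of group
means and the pooled residual variance s²_g with d_g = n₀+n₁−2 df. The
prior (d₀, s₀²) is fitted by moment-matching on log s²_g: under
s²_g ~ s₀²·F(d_g, d₀), Var(log s²) = ψ′(d_g/2) + ψ′(d₀/2), solved with a
Newton inversion of the trigamma function; when the observed spread of
log-variances does not exceed the chi-square sampling noise, d₀ is capped
at 1e6 (all genes effectively share s₀²). The moderated variance is
(d₀s₀² + d_g s²_g)/(d₀+d_g) and t is referred to d₀+d_g df.
`d0_override=0` recovers the ordinary pooled t exactly (tested against an
independent implementation).

**Multiple testing.** Benjamini–Hochberg step-up, implemented directly
(sort ascending, q(i) = min_{j≥i} p(j)·m/j, clip at 1, restore order) and
cross-checked in tests against an independent oracle on random vectors.
DEGs are genes with q strictly < 0.05; ranked signatures filter q < 0.05,
sort by |log2FC| descending with ties broken by gene id.

## Preranked enrichment

Genes are ranked by log2FC (descending, ties by id). For a set S of k
members in a list of N genes, the running sum adds |r_i|^w / Σ_hits |r|^w
at member positions and subtracts 1/(N−k) elsewhere; ES is the signed
maximal deviation from zero (first occurrence on exact ties), and the
leading edge is the members at or before the extremum (at or after it for
negative ES). The default weight exponent is w = 1 (classic preranked);
w = 0 gives the unweighted statistic with closed-form small cases used in
tests. If all member statistics are exactly zero the weights degenerate;
the implementation falls back to unweighted steps.

Significance uses a gene-label permutation null: n_perm random k-subsets
of the ranked universe (vectorized via the position-based form of the
running sum, whose extrema can only occur adjacent to hits). NES divides
ES by the mean |null ES| of the same sign; p = (1 + #{same-sign nulls at
least as extreme}) / (1 + #same-sign nulls). Sets are evaluated against
their intersection with the universe; sets outside [5, 500] members after
intersection are reported as absent and excluded from the BH correction,
which is applied jointly across all evaluated pathways (not per
direction). Some reference implementations normalize positive and negative
scores on split halves of the null; the conventions agree closely, and the
package's contracts (calibration and planted-shift recovery, both tested)
do not depend on the difference.

**Top-50 rule.** Among pathways with q < 0.1: the 25 largest positive NES
plus the 25 most negative NES, fewer if fewer qualify.

## Concordance metrics

- **DEG overlap** reports the intersection size and percentages against
  both set sizes; the headline percentage divides by the *reference*
  (human) set, the convention under which the defining example
  2697/5964 = 45.2% reproduces. Both numbers are emitted so the
  denominator is auditable.
- **Pathway share** divides shared top-50 names by a fixed 50 even when
  fewer qualify (the x/50 reporting convention); direction concordance
  counts NES sign agreement among shared pathways.
- **NES clustering** assembles a pathways × cohorts NES matrix restricted
  to pathways evaluated in every cohort and clusters cohorts with
  Euclidean distance and average linkage. The metric treats
  anti-correlated profiles as distant (documented by a toy test); no
  metric/linkage is canonical for this display, so the choice is fixed
  and stated.
- **PCA** is gene-centered (no scaling) SVD; variance fractions are
  singular values squared over their sum. Signs are fixed by making the
  largest-|loading| gene positive on each component, so results are
  deterministic across SVD implementations.
- **Cross-projection** subsets the target cohort's transformed matrix to
  another cohort's top-200 signature (≥ 50% of the genes must be present),
  runs PCA, and summarizes separation as the rank AUC of PC1 against the
  target labels, folded to [0.5, 1] so it is invariant to PC1 sign and to
  monotone transforms. A scalar was needed where visual separation is the
  usual report; folded rank AUC is the package's definition.

## Biomarker cascade

Pearson correlation with the two-sided t test (t = ρ√(n−2)/√(1−ρ²),
n−2 df; |ρ| = 1 gives p = 0). Per gene the screen computes ρ over all
samples and over case samples alone (requiring ≥ 3 cases), then applies
four criteria: (1) |ρ_all| ≥ 0.8 and |ρ_case| ≥ 0.8; (2) equal correlation
signs; (3) |log2FC| > 1 in the model cohort; (4) equal fold-change sign in
the advanced-disease human cohort, with absence there counting as failure.
Thresholds are read on absolute values — a strongly negatively correlated,
downregulated gene is as much a fibrosis marker as a positive one — and no
p/q filter is applied in the cascade itself (a DEG-membership filter,
q < threshold in the model cohort, is available but off by default).
Correlations are computed on the transformed (log-scale) matrix.

## Synthetic data and what it shows

Every generator is a pure function of its spec including the seed; truth
tables record exactly what was planted (planted_lfc is 0 for unplanted
genes).

- **Counts**: NB(mean s_j·q_i·2^(lfc_i·x_j), dispersion α); baselines
  log2-uniform in [3, 10]; size factors log-uniform in [0.5, 2] so
  normalization is exercised non-trivially. Default dispersion 0.05
  (typical for a well-controlled bulk experiment; 0.1 in the null
  calibration runs).
- **Intensities**: baseline + lfc·x + N(0, σ), σ = 0.5 by default.
- **Fibrosis areas**: normal draws per group at the emulated study's
  histology parameters (1.39 ± 0.24 control, 7.48 ± 1.81 case, percent);
  non-positive draws are redrawn up to 100 times then clamped to 0.01,
  since areas are positive percentages.
- **Correlated genes** are planted on the log scale as
  ρ·z(fibrosis) + √(1−ρ²)·ε and back-transformed (counts are rounded, so
  exactness is asserted on the transformed scale). In exact mode ε is
  residualized against z and rescaled so the all-samples correlation hits
  the target to 1e-9. In **group-aware mode** (groups and a target lfc
  given) the correlation is instead planted exactly *within each group*
  and the group intercepts encode the fold change. This mode exists
  because the screen thresholds the all-samples and case-only correlations
  simultaneously: an all-samples-exact planting leaves the within-case
  correlation a noisy ≈ 0.86 (at ρ = 0.95 under the default fibrosis
  separation), and pinning both scopes *and* the fold change at once is
  infeasible for strongly group-separated fibrosis (the all-samples
  correlation is then bounded near the point-biserial ≈ 0.93). With
  within-group planting at ρ = 0.95 the realized all-samples correlation
  comes out ≈ 0.99, comfortably above the 0.8 threshold.
- **Gene sets** are sampled without replacement; planted sets carry
  per-cohort coordinated shifts (±0.8 log2 by default), enabling
  concordant and discordant cross-cohort designs.
- **Orthologue map**: a configurable mapped fraction, identities uniform
  in a range spanning the 50% cutoff, a small many-to-one collision
  fraction to exercise the collapse rule, and pinned identities for genes
  that must survive harmonization in fixtures.

The default six-cohort study (2000 genes) mirrors the emulated designs:
gp 6+6 counts with fibrosis and nine planted candidates (two down), a
14+16 human-like count cohort sharing a 120-gene DE pool with gp, a 40+32
human-like array cohort sharing 17 same-direction pathway shifts with gp
and carrying concordant candidate effects, and three 5+5 array cohorts
sharing 12, 5 and 6 of those pathways. Scaled-down runs shrink the set
sizes and DE pools proportionally.

**Limitations.** The generator does not emulate gene–gene correlation
structure, batch effects, probe-level artifacts, count overdispersion
trends, or realistic pathway overlap topology. Passing planted-truth tests
therefore demonstrates that the *methods* implement their definitions and
recover signals under their stated assumptions — not that any particular
real-data figure would reproduce, which additionally depends on genome
annotation versions, transform parameters, and cohort composition.

## Problem sizes and determinism

Simulation-based tests use 2000-gene cohorts (5000 for null calibration),
400-permutation GSEA nulls, and 100-shuffle projection nulls — sizes at
which every planted effect in the design is comfortably detectable and the
full suite runs in well under a minute per stage. A single run seed fans
out to per-stage seeds by stable hashing of the stage name (CRC32, kept
below 2^31), so stages are reproducible independently of execution order;
identical seeds give byte-identical output tables.
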