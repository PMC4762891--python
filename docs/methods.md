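# Methods

This note documents the statistical model, the synthetic-data generator, the
numerical choices, and the known limitations of `sexde`.

## Differential-expression model

Each gene's log₂ expression vector is modeled as

y_g = X β_g + b_{g,subject} + ε_g,   ε_g ~ N(0, σ²_g I),  b ~ N(0, τ²_g)

with X holding an intercept, a male indicator (so the sex coefficient is the
male − female log₂ fold difference), and fixed covariates: RIN, age, PMI, pH
(numeric, unstandardized) and cortical lobe (categorical, expanded to
indicators with one reference level). The subject random intercept induces a
compound-symmetry covariance with intra-subject correlation
ρ_g = τ²_g / (τ²_g + σ²_g).

Rather than fitting a free mixed model per gene — unstable with five subjects
per sex — a single **consensus correlation** is shared across genes, and each
gene is then fit by generalized least squares under the block
compound-symmetry covariance. This is the standard approach for
repeated-measures expression designs at this scale. Implementation details:

- The covariance V(ρ) of each subject block is diagonalized by a fixed
  Helmert basis: the block-mean coordinate has eigenvalue 1 + (m−1)ρ and the
  m−1 within-block contrasts have eigenvalue 1 − ρ. Because the basis does
  not depend on ρ, the data are transformed once and the restricted
  likelihood is evaluated for all genes simultaneously at each candidate ρ.
- Per-gene REML estimates are obtained on a ρ grid (step 0.005, lower bound
  max(−0.9, −1/(m_max−1)+1e−3), upper bound 0.99) with parabolic refinement
  of interior optima. The consensus is tanh of the 15 %-trimmed mean of
  atanh of the per-gene estimates, clamped to (−0.99, 0.99). If no subject
  contributes repeated samples the consensus is 0 with a warning.
- GLS at the consensus ρ yields β_g, its unit standard error (design-only
  factor), the residual variance s²_g, and residual degrees of freedom
  d_g = n − rank(X), identical across genes for complete data.

**Moderation.** The variance prior σ²_g ~ scaled-inv-χ²(d₀, s₀²) is fitted by
the closed-form method of moments on log s²_g: with
e_g = log s²_g − ψ(d_g/2) + log(d_g/2), the prior scale is
s₀² = exp(ē + ψ(d₀/2) − log(d₀/2)) and d₀ solves
ψ′(d₀/2) = var(e) − mean ψ′(d_g/2) via Newton inversion of the trigamma
function. If the observed spread of log variances does not exceed its
chi-square expectation, d₀ = ∞ and all posterior variances equal s₀²
(the moderated t is then referenced to the normal, implemented as t with
10⁹ df, which equals the normal to double precision). Posterior variances
s̃²_g = (d₀ s₀² + d_g s²_g)/(d₀ + d_g) always lie strictly between s²_g and
s₀²; the moderated t = β_g/(unit_se · s̃_g) is two-sided on d₀ + d_g df.

Note that in the repeated-measures model s₀² estimates the *total* per-gene
variance on the correlation-normalized scale, σ²_g/(1−ρ); hyperparameter
recovery of the raw noise prior is checked directly on simulated variances.

**Calling.** Sex-DE at tier α requires FD ≥ 1.2 (male-DE) or FD ≤ 1/1.2
(female-DE) and unadjusted p ≤ α, for α ∈ {0.005, 0.01, 0.05}; tiers are
nested by construction. Independently, every gene with log₂FD ≠ 0 is labeled
male-higher or female-higher at any p; genes with log₂FD exactly 0 belong to
neither category (the directional categories are defined by strict
inequalities). BH-adjusted p-values are reported for transparency but the
tier calls use unadjusted p, matching the reference procedure.

## Over-representation

Both tests restrict the query set and the DE list to the set's background
universe before counting. Backgrounds are category-specific: protein-coding
and source-publication universes are intersected with the expressed genes;
the one-to-one human–mouse orthologue universe is used genome-wide,
unintersected.

- **Fisher**: exact two-sided p computed by enumerating the hypergeometric
  support and summing point probabilities ≤ the observed one, with a 1e−7
  relative tolerance guarding exact ties against floating-point rounding.
  Both the sample odds ratio ad/bc and the observed/expected ratio
  (a/(a+b))/((a+c)/N) are reported side by side, since the two summaries are
  easily conflated; zero cells give odds ratio 0 or ∞ with the p-value still
  exact. Bonferroni adjustment is applied within each p tier.
- **Binomial shift**: the background male-higher proportion p_bg (among
  background genes with nonzero log₂FD) is the null; the set's k male-higher
  of n scorable genes gives an exact two-sided minimum-likelihood p, a
  Clopper–Pearson 95 % CI (consistent with the exact test), and the shift
  prop − p_bg. The query set's genes remain in the background by default
  (literal reading of "the corresponding background gene set"); an exclusion
  flag is available. Bonferroni over the number of sets.
- **Adjustment denominators**: the reference parameterization is 62 Fisher
  tests per tier (31 sets × 2 directions) and 31 binomial tests; the
  pipeline config fills these as defaults and the library uses
  2·n_sets / n_sets when not overridden. `run_pipeline` takes the maximum of
  the override and the actual count so the adjustment is never anti-
  conservative.

## Concordance

Cross-dataset comparisons use the product-moment correlation of log₂FD over
shared genes (log scale, so the two directions are treated symmetrically),
with p from the t transform on n−2 df; "expression level" concordance
correlates per-gene mean log₂ expression. Replication overlap requires
FD ≥ 1.2 (or ≤ 1/1.2) in *both* datasets; fold enrichment of an annotation
set within an overlap list is (overlap/|list|)/(|set∩bg|/|bg|) with a
hypergeometric upper-tail p, where the background is the genes tested in
both datasets.

## Preprocessing

Fixed order: filter → outlier passes → quantile normalize → match →
re-filter. Choices:

- **Filter**: a gene is removed iff strictly more than 50 % (RNA-seq; 80 %
  array mode at threshold 6) of either sex's samples fall strictly below the
  expression threshold. Both inequalities are strict; the two readings differ
  only at exact boundaries.
- **Outliers**: per pass (within each sex, then all samples; recomputed after
  each pass), a sample is removed when its mean product-moment correlation
  with the other group members lies more than z (default 2.5) SDs *below*
  the group mean of those means. Only the low side is flagged — an unusually
  high mean correlation cannot indicate a degraded sample. A single
  all-sample pass at z = 2 reproduces the summed-correlation z-score variant
  used for replication-style datasets.
- **Quantile normalization**: every sample is mapped onto the across-sample
  mean of sorted columns; tied values receive the mean of the reference over
  their tied rank span. Rank order within a sample is preserved and the map
  is idempotent.
- **Matching**: all minority-sex samples are paired greedily, in ascending
  absolute age difference (ties broken lexicographically by sample ID), to
  distinct majority-sex samples from the same region; unmatched minority
  samples are dropped and reported. Greedy is deterministic and optimal on
  the small instances this is used for.

## Synthetic cohorts

`generate_cohort` emulates the structure the analyses assume: balanced sexes,
several regions per subject, log₂-scale expression =
baseline + ±log₂FD/2 (sex, so the truth table's FD equals the male−female
mean difference) + covariate effects + subject intercept + noise.

- Residual variances come from scaled-inv-χ²(d₀=4, s₀²=0.05) — typical of
  log-scale RNA-seq variance spreads and exactly matching the moderated-test
  prior. The subject intercept variance is ρ/(1−ρ)·σ²_g so the intra-subject
  correlation is exactly ρ (default 0.3, a plausible placeholder; real
  cohorts' values are not characterized).
- Sex-chromosome markers (one XIST-like female gene, six Y-like male genes
  by default) sit at baseline 6.0 in the expressing sex and 0.05 in the
  other, reproducing extreme-FD volcano wings without modeling copy number.
- Covariates: age (13–40 y), PMI (5–30 h), pH (6–7) drawn per subject, RIN
  (7–10) per sample; per-gene effects are N(0, 0.1²) per standardized
  covariate, plus centered lobe offsets. The DE model includes the same
  covariates, so they are adjusted exactly.
- Planted sets are disjoint draws from the autosomal genes; each planted set
  is accompanied by a same-size unplanted control set (at least one control
  set always exists) as a negative-control surface for enrichment.
- The bundled background category `protein_coding` is the autosomal gene
  universe: markers are excluded so that null backgrounds are genuinely null
  (the reference analyses likewise interpret the directional shift on
  essentially autosomal universes and subset autosomes for visualization).
- `seed` drives the gene-level truth; the optional `noise_seed` redraws
  subjects, covariates, intercepts and noise while keeping the truth fixed,
  which is how replication cohorts are produced. Identical configs are
  bit-reproducible.

What the simulation does *not* emulate: count-level (negative-binomial)
noise, GC/batch artifacts, correlated gene-gene co-expression structure,
X-inactivation dosage nuance, and case/control dimensions. Passing tests
therefore demonstrate correctness of the statistical machinery under its own
assumptions, not robustness to real-data pathologies that the upstream
normalization steps (outside this package's scope) are meant to absorb.

## Problem sizes and numerical choices

The test and acceptance workloads use desk-scale cohorts chosen to make
Monte-Carlo checks sharp: 2 000-gene null cohorts (5+5 subjects × 3 regions,
20 seeds) for type-I error, 5 000-gene cohorts (10+10 × 3, 200-gene planted
set at FD 1.3, 20 seeds) for power/recovery, and 20 000 simulated variances
for hyperparameter recovery. Exact-test verification enumerates every 2×2
table with N ≤ 40 against integer-arithmetic oracles and 1 000 random
binomial cases with n ≤ 500.

Degenerate inputs are handled explicitly: zero-variance genes (perfect fits)
get s² = 0 and are excluded from prior estimation; equal variances across
genes trigger the d₀ = ∞ branch; empty sex strata, all-missing covariates,
rank-deficient designs, sets disjoint from their background, and empty
scorable sets raise parameter errors naming the offender. PMI/pH imputation
uses the subject mean, falling back to the cohort mean (reported) when a
subject has no observed value.

## Limitations

- The consensus-correlation GLS is an approximation to per-gene mixed
  models; with very heterogeneous per-gene ρ the shared value is a
  compromise (mitigated by the trimmed-mean consensus).
- Fisher's two-sided minimum-likelihood rule and the binomial counterpart
  depend on point-probability comparisons; the 1e−7 relative tie tolerance
  matches common practice but other tie conventions exist.
- The matching algorithm is greedy; optimal bipartite matching could differ
  on adversarial age/region configurations.
- p-values for the FD–FD correlation assume bivariate normality of log₂FD
  pairs, which planted-mixture truths only approximate.
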