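# sexde

Sex-differential expression analysis for repeated-measures brain
transcriptomes, with a matched-background gene-set interpretation layer and a
ground-truth synthetic-cohort simulator.

Post-mortem expression cohorts are small and structured: each subject
contributes samples from several cortical regions, the sexes are unbalanced,
and sample quality varies (RIN, post-mortem interval, pH). `sexde` implements
the full analysis chain such studies need:

1. **Preprocessing** — non-expressed gene filtering evaluated within each
   sex, correlation-based outlier-sample removal, quantile normalization, and
   sex-balanced sample matching by age and brain region.
2. **Differential expression** — per-gene sex contrast (log₂ fold difference,
   FD; positive = male-higher) from generalized least squares under a
   compound-symmetry covariance with a consensus intra-subject correlation ρ
   (subject as random effect), fixed covariates (RIN, age, PMI, lobe, pH),
   empirical-Bayes moderated t-statistics, and tiered sex-DE calls
   (|FD| ≥ 1.2 at unadjusted p ≤ 0.005 / 0.01 / 0.05).
3. **Over-representation** — for each annotation gene set against its own
   background universe: two-sided Fisher's exact tests of the male-DE and
   female-DE overlaps at each p tier (Bonferroni over 2 × n_sets tests per
   tier), plus a threshold-free two-sided binomial test of the set's
   male-higher proportion against the background's (Bonferroni over n_sets).
4. **Concordance** — cross-dataset log₂FD correlation, two-dataset
   directional replication overlap at FD ≥ 1.2, and hypergeometric fold
   enrichment of annotation sets within the overlap.
5. **Simulation** — synthetic cohorts with sex-chromosome marker genes,
   planted fold differences confined to designated gene sets, per-gene
   variances drawn from a scaled inverse-χ² prior, subject random intercepts,
   and covariate effects — with a full truth table, so every stage is
   testable without restricted data.

## The model

For gene *g* with expression *y* (log₂ scale) over samples with design matrix
*X* (intercept, male indicator, covariates) and subject blocks:

- Var(y) = σ²_g V(ρ), where V(ρ) is block compound-symmetric (off-diagonal ρ
  within a subject). ρ is estimated per gene by REML and combined across
  genes by a tanh/atanh 15 %-trimmed mean into a single consensus value.
- β_g (the male − female contrast) is the GLS estimate under V(ρ);
  FD_g = 2^β_g.
- Residual variances are shrunk toward a scaled inverse-χ²(d₀, s₀²) prior
  fitted by method of moments on log s²_g:
  s̃²_g = (d₀ s₀² + d_g s²_g)/(d₀ + d_g); the moderated t has d₀ + d_g
  degrees of freedom. Benjamini–Hochberg adjustment is reported alongside the
  tiered unadjusted-p calls.
- A set's **shift** is its male-higher proportion minus the background's,
  where every gene with β_g ≠ 0 is classed male- or female-higher at any p;
  the exact binomial test uses the background proportion as the null.

## Worked example

```python
import numpy as np
from sexde.simulate import SimConfig, generate_cohort
from sexde.de import run_de
from sexde.enrich import run_enrichment_suite

cfg = SimConfig(
    n_subjects_per_sex=10, n_regions_per_subject=3, n_genes=5000,
    planted_sets=[("glial_up", 200, float(np.log2(1.3)))], seed=7,
)
cohort = generate_cohort(cfg)
table, params = run_de(cohort.expression, cohort.samples,
                       covariates=["RIN", "age", "PMI", "lobe", "pH"])
report = run_enrichment_suite(table, cohort.gene_sets,
                              n_fisher_tests=62, n_binomial_sets=31)

print(f"consensus rho = {params.rho:.3f}; variance prior d0 = {params.d0:.2f}, "
      f"s0^2 = {params.s0_sq:.4f}")
print(f"sex-DE at FD>=1.2, p<=0.05: {(table['de_0.05'] == 'male-DE').sum()} male-DE, "
      f"{(table['de_0.05'] == 'female-DE').sum()} female-DE")
planted = cohort.gene_sets.genes_of("glial_up")
print(f"median log2FD in planted set = {table.loc[planted, 'log2FD'].median():.3f} "
      f"(truth {np.log2(1.3):.3f})")
row = report[(report.test == "binomial_shift") & (report.set == "glial_up")].iloc[0]
print(f"glial_up shift: {100 * row['prop']:.0f}% male-higher vs "
      f"{100 * row['p_bg']:.0f}% in background ({100 * row['shift']:+.0f} pp), "
      f"adjusted p = {row['p_adj']:.2e}")
fr = report[(report.test == "fisher") & (report.set == "glial_up")
            & (report.direction == "male-DE") & (report.tier == 0.05)].iloc[0]
print(f"glial_up Fisher male-DE (p<=0.05 tier): odds ratio {fr['odds_ratio']:.1f}, "
      f"{fr['fold_of_expected']:.1f}-fold of expected, adjusted p = {fr['p_adj']:.2e}")
```

prints:

```
consensus rho = 0.286; variance prior d0 = 3.96, s0^2 = 0.0702
sex-DE at FD>=1.2, p<=0.05: 195 male-DE, 38 female-DE
median log2FD in planted set = 0.373 (truth 0.379)
glial_up shift: 99% male-higher vs 52% in background (+47 pp), adjusted p = 8.66e-51
glial_up Fisher male-DE (p<=0.05 tier): odds ratio 385.6, 19.9-fold of expected, adjusted p = 2.15e-204
```

The consensus ρ recovers the simulated intra-subject correlation (0.3), the
planted 1.3-fold set is recovered at its true magnitude, and both the
thresholded (Fisher) and threshold-free (binomial shift) views flag the
planted set while its same-size unplanted control set stays null.

A complete run — simulation through enrichment with a checksum manifest —
is one command:

```sh
sexde run --config demo.yaml --seed 3 --out out/
```

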