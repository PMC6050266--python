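# Methods

## The problem

Bulk RNA-seq case-control studies with very small cohorts (here the
design is ten cases versus ten controls, modelled on an early-course
Parkinson's disease monocyte study design) are a poor fit for
parametric count models: a single outlier sample can create or destroy
a differential-expression call, and gene lists change substantially
when two samples per group are dropped. `ksvar` implements a
nonparametric alternative built on the two-sample Kolmogorov-Smirnov
(KS) test with exact small-sample p-values, applied twice per gene:

* **KS expression test** — the KS test applied directly to the two
  groups' `log2(TPM+1)` values of a gene; sensitive to a difference in
  expression *level*.
* **KS variability test** — each group is centred at its own median,
  and the KS test is applied to the two groups' absolute deviations;
  sensitive to a difference in *spread* while blind to location by
  construction.

Genes are then classified at a per-test significance level α (default
0.01, strict inequality: p exactly equal to α is not significant):

| label | expression test | variability test |
|---|---|---|
| `de_low_var` | p < α | p ≥ α |
| `dysregulated_var` | p ≥ α | p < α |
| `both_flagged` | p < α | p < α |
| `neither` | p ≥ α | p ≥ α |

`de_low_var` genes are the differential-expression signature;
`dysregulated_var` genes changed their expression variability at a
similar median — the configuration a mean-difference test cannot see.
The two-test rule leaves the "both significant" cell open; we report it
as its own label rather than folding it into either set. The four
labels partition the gene list. Direction is assigned afterwards:
level-change genes by the sign of the case-minus-control median
difference, variability genes by the sign of the scaled-MAD difference;
exact zero differences go to explicit tie buckets.

Raw KS p-values drive the classification; Benjamini-Hochberg-adjusted
q-values are carried in the results table as an extra column for
transparency but do not enter the rule. This mirrors the intended use
of the method as a per-gene screen at a strict α rather than an
FDR-controlled discovery procedure.

## Exact KS p-values at n = 10

With ten samples per group the asymptotic Kolmogorov distribution is a
poor approximation, so p-values are computed exactly whenever
`n*m <= exact_limit` (default 10,000):

* **Tie-free data** — the standard distribution-free path-counting
  recursion (`scipy.stats.ks_2samp(method="exact")`), memoised on
  `(n, m, D)` since the exact p depends on the data only through those.
  The recursion can fail for rare `(n, m, D)` combinations, in which
  case scipy silently substitutes the asymptotic value; `ksvar`
  detects that and reroutes to the permutation path below, keeping the
  result exact.
* **Tied data** — ties break the recursion's distribution-free
  assumption, so the permutation null is evaluated directly: all
  `C(n+m, n)` assignments of the pooled values are enumerated when that
  count is within `enum_budget` (default 200,000, which covers
  `C(20,10) = 184,756`), otherwise a seeded Monte-Carlo sample of
  100,000 permutations with an add-one correction is used. The
  enumeration works in integer arithmetic on `D*n*m`, and the
  per-`(n, m)` assignment table is cached so a 2,000-gene scan enumerates
  once, not 2,000 times.

Ties are not an edge case here: for an even-sized group the two central
order statistics are always equidistant from the median, so the
variability test's input contains at least one tied pair per group by
construction and routinely takes the enumeration route.

Because the KS statistic depends only on ranks, the tests are invariant
under any strictly monotone transform of the expression values; whether
they consume TPM or `log2(TPM+1)` is immaterial, and the package
standardises on `log2(TPM+1)`.

## Variability metric

Spread is summarised per gene and group as the **scaled MAD**: the
median absolute deviation from the group median, divided by the group
median. Scaling makes the measure dimensionless and comparable between
genes expressed at tens versus thousands of TPM. A zero median leaves
the scaled MAD undefined (NaN); such genes keep their KS results but
are excluded from spread summaries. The reported `variability_ratio` is
case scaled-MAD over control scaled-MAD.

For numerical robustness the variability test rounds the absolute
deviations to 1e-9 before testing. The subtraction of a group median is
subject to floating-point jitter of order 1e-15, which would otherwise
break the test's exact invariance under location shifts; on the
`log2(TPM+1)` scale genuinely distinct deviations are never within
1e-9 of each other, and any ties the rounding introduces are handled
exactly by the permutation route.

## Input processing

Expression matrices are genes x samples TSV. Raw counts are converted
to TPM with the standard per-million definition
`TPM_g = scale * (count_g/len_g) / sum_h(count_h/len_h)`; the scale is a
knob (default 1e6) because the rank-based tests are invariant to it.
Genes must reach **10 TPM or greater (inclusive) in at least one
sample** to enter the analysis; the filter operates on TPM before the
log transform (the order is immaterial since the log is monotone).
Small-RNA decoys (snoRNA, miRNA biotypes) are excluded via the
annotation table, mirroring the practice of dropping poorly quantified
short genes from poly(A) libraries. The log transform is
`log2(TPM + 1)` with the pseudocount exposed.

## Baseline DE caller and cross-validation

The comparison baseline is a generic fold-change + rank-test caller: a
two-sided Wilcoxon rank-sum test on `log2(TPM+1)` per gene,
Benjamini-Hochberg adjustment across genes, and a gene is called when
`q < 0.05` *and* the absolute log2 fold change of group mean TPM (with
pseudocount 1) reaches `log2(2)`. This is deliberately a stand-in for
negative-binomial count callers — the robustness machinery takes any
caller with the same interface, so an external count-model backend can
be plugged in.

Robustness is probed with leave-2-per-group cohorts: each of k = 5
folds excludes 2 random cases and 2 random controls (drawn without
replacement within a fold, independently across folds — the folds may
overlap), the caller is re-run per fold, and gene lists are compared
through a (k+1) x (k+1) overlap matrix that includes the full cohort.
Separately, each KS-significant gene is re-tested on every fold's
retained samples; a gene is **robust** when its maximum fold p-value
stays strictly below 0.05. The raw fold-wise KS p is used, not a
BH-adjusted one.

## Downstream statistics

* **Direction contingency** — the case/control direction of the
  signature genes is cross-tabulated against their direction in a
  second cell-type contrast, and tested with the Pearson chi-square on
  the 2x2 table, df = 1, **without** Yates continuity correction (the
  correction is deliberately off; with it the statistic for the
  reference table 10/3/11/15 would drop below its known value of 4.18).
  Tied directions are excluded with a warning.
* **Signature PCA** — each signature gene is standardised across
  samples (mean 0, variance 1), samples are the observations, and the
  leading components are returned with explained-variance ratios.
  Component signs follow a deterministic convention (the
  largest-magnitude gene loading of each component is positive) so
  reruns are bit-identical.
* **Clinical correlations** — Spearman's rank correlation (midranks for
  ties) of each signature gene against each clinical covariate, with
  pairwise deletion of missing values and a minimum of 5 complete pairs
  (constant covariates report NaN). Case-only covariates such as
  disease duration naturally correlate over the ten cases.
* **Risk-gene profile** — for an externally supplied gene list, the
  mean `log2(TPM+1)` with a t-based 95% CI (n-1 df) per cell-type
  matrix, and an enrichment category from group means of TPM:
  `monocyte_enriched` when the monocyte-control mean exceeds twice the
  microglia mean, `microglia_enriched` for the converse, `shared`
  otherwise. Genes below 2 TPM everywhere stay in the category counts
  but are dropped from the CI table.

## Synthetic data generator

The generator emulates the cohort structure the analysis targets, on
the scale the analysis consumes: per gene, `log2` expression is
Normal(mu_g, sigma_g) per sample, exponentiated to TPM. Defaults are
the study conditions: 10 cases and 10 controls, 5% mean-shift genes at
lfc = 2 (a 4-fold shift), 10% variance-shift genes at a 3-fold sd
inflation, baseline sigma = 0.3 log2 units, 85% of null genes drawn
from an expressed baseline (mu ~ Normal(6, 1.5), i.e. around 64 TPM)
and the rest near-silent, plus 4% of null genes annotated as
snoRNA/miRNA decoys. Variance inflation multiplies sigma symmetrically
about the group centre, so variance-shift genes are median-matched by
construction — exactly the configuration the variability test assumes.
Planted (non-null) genes always receive an expressed baseline: a spread
or level change in a gene that never clears the 10-TPM filter would be
unobservable, so planting it would only make truth labels meaningless.

Clinical covariates are drawn at magnitudes typical of an early-course
Parkinson cohort (age ~ 60 +/- 4 y; UPDRS-III motor scores in the
teens; disease duration 0.5-3 y; levodopa-equivalent dose of a few
hundred mg/d; cytokines log-normal). Disease-specific fields are NaN
for controls. Selected covariates (disease duration, UPDRS-III, IL-6)
can be coupled to a gene signature with a target Spearman correlation:
a Gaussian-copula construction uses normal scores of the per-sample
mean signature expression, with the latent Pearson correlation chosen
by numerically inverting Moran's small-sample expectation
`E[r_s] = 6/(pi(n+1)) * (asin(r) + (n-2) asin(r/2))`, so the *realised*
Spearman correlation averages the target at the actual sample size
(n = 10 for case-only covariates). With |target| = 1 the covariate is
an exact monotone transform. A companion cell-type matrix (for the
contingency and risk-profile stages of fully synthetic runs) offsets
each gene's log2 mean by Normal(0, 1.5), so roughly half the genes land
higher and half lower than the source cohort.

What the generator does **not** model: library-size or batch effects,
gene-gene correlation, count-level (negative-binomial) noise, and
length-dependent quantification bias. Passing tests therefore
demonstrate the statistical machinery — validity, power at the planted
effect sizes, robustness, determinism — not performance on real
sequencing artefacts.

## Pipeline and reproducibility

The pipeline stages run in a fixed order: data (read or simulate) →
10-TPM filter → biotype exclusion → log transform → per-gene KS tests →
classification and direction split → cross-validation → signature PCA →
Spearman correlations → direction-contingency chi-square → risk-gene
profile → JSON summary. One config seed feeds a `SeedSequence` from
which every random stage derives its own stream (all derived seeds kept
below 2^31), so a rerun with the same config reproduces every output
file byte for byte; the summary contains no timestamps.

## Numerical choices

* α boundary strict (`p < α`); ties in direction splits reported
  separately, never silently assigned.
* KS statistic evaluated with right-continuous ECDFs at pooled points;
  permutation comparisons in exact integer arithmetic on `D*n*m`.
* Exact/enumeration/asymptotic switch-over: `exact_limit = 10,000`
  products, `enum_budget = 200,000` assignments, Monte-Carlo fallback
  100,000 permutations, seeded, with add-one correction.
* Deviations rounded to 1e-9 in the variability test (see above).
* BH adjustment clipped at 1, original order restored.
* PCA uses the full SVD solver; zero-variance genes dropped with a
  warning before standardisation.
* t-based CIs with n-1 df; a single observation yields an undefined CI.

## Test and verification sizes

The statistical test suite runs the full machinery at the sizes the
properties are stated for: 2,000-gene cohorts for the type-I-error,
variability-recovery, expression-recovery and null-FDR checks; 20
replicates of 500-gene cohorts for the PCA separation rate; 500 random
small-sample draws (all group sizes 2-6) for the
exactness-vs-enumeration cross-check, whose oracle enumerates every
`C(n+m, n)` assignment with an independent brute-force ECDF
implementation. `scripts/acceptance.py` recomputes all of these from
scratch from a single command-line seed.

## Known limitations

* The KS variability test conditions on estimated medians; at n = 10
  this costs power (the exact test is conservative, and the observed
  rejection rate under the null is well below the nominal α).
* Power to detect a 3-fold variance inflation at n = 10 and α = 0.01 is
  modest (roughly 10% per gene under the default conditions); the
  procedure is a screen, and its strength is the near-absence of false
  positives, not per-gene sensitivity.
* The baseline caller is not a count model; with real over-dispersed
  counts its behaviour will differ from negative-binomial callers.
* `ks_cv_robustness` re-tests only the genes handed to it; it does not
  correct for the selection step that produced the list.
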