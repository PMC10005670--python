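# Methods

## Study design being modelled

A six-week fish-oil supplementation trial measures plasma
triglycerides (TG, mmol/L) before and after the intervention.
Subjects whose TG fell (change ≤ −0.01 mmol/L) are *responders*;
subjects whose TG stayed stable or rose (change ≥ 0.00 mmol/L) are
*nonresponders*; the open interval between the two bounds is
*unclassified*.  The two printed bounds overlap as published (≤ 0.01
and ≥ 0.00); the responder bound is implemented with the evidently
intended negative sign (≤ −0.01) so the rules are disjoint, and both
bounds are exposed as parameters.  The analysed cohort consists of the
subjects with the most extreme responses: 80 responders (each showing
at least a 10 % relative TG decrease — the "extreme" flag) and 60
nonresponders after one genotyping failure.

## Risk-score construction

Per SNP, minor-allele frequencies are compared between the two groups
as an allele-level odds ratio.  The published table's values are only
consistent with **responder odds over nonresponder odds**
(0.18/0.23 → 0.73), although the accompanying text reads the other way
round; the value-consistent orientation is the default and a `flip`
flag provides the reciprocal.  Scores: +1 if OR < 1 (minor allele
enriched in nonresponders, i.e. a risk allele for nonresponse), −1 if
OR > 1, excluded if the responder-group MAF is 0 or OR is exactly 1.
When allele counts are available the OR is the 2×2 cross-product ratio
with a Woolf (log-normal) 95 % CI; from proportions alone the CI is
undefined.

The GRS is the dosage-weighted signed sum over the scored panel
(0/1/2 minor-allele copies; carrier coding deliberately not used —
"summing the score of risk alleles" is read as allele counting).  The
weighted variant multiplies each term by the magnitude of an
externally supplied interaction effect size; per-SNP effect sizes are
not published, so weights are always user input.  Missing dosages at
scored variants are mean-imputed per variant by default (zero-fill and
subject-drop are options).

The packaged published panel carries a subtlety: six SNPs print group
MAFs of 0.01/0.01 yet non-unit odds ratios (0.73–0.74), because the
published ORs were computed from unrounded allele counts that cannot
be recovered from the two-decimal proportions.  The panel-scoring
helper therefore assigns scores from the published OR column (printed
tables are inputs), and recomputing ORs from the printed proportions
is exact only at the mid-frequency SNPs — which is precisely what the
validation tests assert.

## Quality control

Monomorphic variants (no minor allele observed) are *excluded*; in the
study this removed 2 of 17 genotyped SNPs.  Hardy–Weinberg equilibrium
is tested per variant with the exact conditional test (the sum of
probabilities, given the allele counts, of all heterozygote
configurations no more probable than the observed one; a mid-p option
exists, the standard formulation is the default since the published
test variant is unstated).  HWE failure at α = 0.05 *flags* but never
excludes a variant — the study's exclusions were monomorphism-driven
only.  Per-group MAFs use only subjects with a definite response
label; missing genotypes are excluded pairwise from all frequency
computations.

## Models

**Logistic response model** (`ResponseModel` → `ResponseModelResults`):
binomial MLE with a logit link fitted by Newton/IRLS (statsmodels),
with the responder class as the positive outcome by default and sex
coded 0 = female / 1 = male.  Collinear design columns are dropped via
pivoted QR with a warning.  Separation (perfect-separation signal,
non-convergence, or |coefficient| > 50) triggers a ridge-penalized
IRLS refit (α = 1e-6) flagged in the results.  McFadden's pseudo-R² is
1 − lnL/lnL₀ with the intercept-only null.

**Explained variance (ΔR²)**: R²(covariates + GRS) − R²(covariates)
from nested least-squares fits; non-negative by construction.  The
published explained-variance figure is ambiguous about whether the
outcome is post-supplementation TG or the TG change; both are
supported and the change is the default.

**Group comparisons**: Welch's unequal-variance t-test (the published
analysis does not state pooled vs Welch; Welch is the safer default).

**Genotype-by-visit interaction**: the two-visit mixed model with a
random subject intercept is tested through its change-score
equivalent — regress (TG_post − TG_baseline) on dosage + covariates
and test the dosage coefficient.  In a balanced two-period design the
between-subject stratum carries no information about the interaction,
so this equals the mixed-model interaction contrast exactly; the test
suite verifies the coefficient against a direct ML implementation of
the random-intercept likelihood and the p-value against its LR test
(identical estimates; p-values agree up to the finite-sample t-vs-χ²
denominator difference).

## Evaluation protocol

The labelled cohort is split 50/50 with class stratification (largest-
remainder apportionment keeps each part's responder:nonresponder ratio
within one subject of the overall ratio), deterministically from a
seed.  Tenfold cross-validation runs inside the training half
(stratified folds; single-class held-out folds are skipped with a
warning); the CV report is the unweighted fold mean.  The final model
is refitted on the full training half and evaluated once on the test
half.  Classification uses probability cutoff 0.5 (unstated in the
source; configurable).  Accuracy carries an exact binomial
(Clopper–Pearson) 95 % CI, the AUC a DeLong CI; AUC ties count ½
(Mann–Whitney).  McFadden's pseudo-R² is a likelihood quantity and is
reported in-sample for whichever dataset it describes (the fold-model
for CV, a refit on the test half for the test column); out-of-sample
discrimination is carried by AUC and accuracy.

Two leakage policies exist deliberately.  `run_prediction_protocol`
estimates the per-SNP scores **from the training half only**, so
held-out metrics are free of score-selection leakage — under a null
panel the test AUC then genuinely centers on 0.5, which is what the
calibration experiments require.  The CLI's `evaluate`, like the
original analysis, treats a supplied GRS profile as externally fixed
and only cross-validates the logistic model.

## Threshold selection

Candidate cutoffs sweep every distinct GRS value.  Following the
published convention, responders are counted *at or below* the cutoff
(`responders_captured`, which equals the sensitivity of the rule
"predict responder iff GRS ≤ cutoff") and nonresponders *at or above*
it; ties at the cutoff therefore contribute to both quoted
proportions, reproduced literally.  Specificity uses the strict
complement (GRS > cutoff).  Tertile and median summary points use
nearest-rank sample quantiles at 1/3, 1/2, 2/3 (the published
quantile method is unstated; interpolation is configurable).  The
decision aid labels a subject a likely responder iff GRS ≤ cutoff —
ties favour treating, matching the stated "equal or less than"
optimal-cutoff rule and the rationale that missing a true responder
is the costlier error.

## Synthetic cohorts

The original cohort is not publicly released, so the generator
reproduces its statistical structure:

| parameter | default | basis |
|---|---|---|
| group sizes | 80 responders / 60 nonresponders | study cohort after one genotyping failure |
| panel genotypes | Binomial(2, group MAF) per SNP | published per-group frequencies of the 17-SNP panel |
| base panel | 31 SNPs, MAF 0.20 (R) vs 0.35 (NR) | stands in for the original 31-SNP score; this separation yields held-out AUC ≈ 0.95, matching its reported discrimination |
| TG change, responders | Normal(−0.50, 0.36) mmol/L, truncated to the responder rule (≥10 % decrease by default) | published group means ± SD |
| TG change, nonresponders | Normal(+0.18, 0.17) mmol/L, truncated at ≥ 0 | published group means ± SD |
| baseline TG | log-normal, median 1.3 mmol/L (NR) × 1.45 (R), log-SD 0.30 | responders had significantly higher baseline TG; magnitudes chosen as clinically typical for an overweight cohort |
| age, BMI | Uniform(18, 50) years, Uniform(25, 40) kg/m² | trial eligibility window |
| sex | Bernoulli(0.5) | unreported composition |

Genotypes are drawn independently per variant within each group — so
within-group Hardy–Weinberg equilibrium holds by construction and
there is no linkage disequilibrium (the score treats SNPs
independently; LD simulation is out of scope).  Truncation is by
rejection sampling capped at 10 000 draws per subject, with a small
positive floor (0.05 mmol/L) on post-supplementation TG.  The
permutation-null stream reassigns whole phenotype records (label, TG
values and covariates together) to genotype rows, so the genotype
matrix is bit-identical across the stream and every record remains
internally consistent with the classification rule.

What the generator does **not** emulate: LD structure, genotyping
error and missingness patterns, the real 31 base SNPs' frequencies
(unpublished), population stratification, or any correlation between
covariates and genotype.  Passing recovery tests therefore show the
pipeline is correct and calibrated under the stated generative model,
not that the published cohort-specific effect sizes would replicate.

## Problem sizes and numerical choices

Calibration and recovery experiments use the study-sized cohort
(n = 140): 1000 dosage permutations for interaction-test type-I error,
20 permuted cohorts for the pipeline null, 20 seeds per
parameter-recovery condition, and a 50× cohort (7000 subjects) for
large-sample odds-ratio recovery — sizes chosen so each experiment's
Monte-Carlo error is comfortably inside the asserted bands.  The HWE
oracle sweep is exhaustive for all genotype triples up to 60 subjects
and randomized up to 200, against an exact rational-arithmetic
enumeration (agreement 1e-12).  Logistic convergence: Newton tolerance
1e-8, 100 iterations.  Ties in empirical minor-allele determination
break to the lexicographically later allele; an annotation table
always overrides empirical orientation so that dosage matches the
published major/minor assignment even when a small sample's frequency
crosses 0.5.

## Known limitations

- The change-score interaction test covers the balanced two-visit
  design only; it is not a general mixed-model engine.
- DeLong AUC CIs are Wald-type and can be degenerate at AUC = 1 (as
  happens under strong separation).
- The decision-aid cutoffs are calibrated on the same cohort that
  produced the sweep; no external validation is attempted.
- Odds ratios from two-decimal published proportions reproduce the
  published values only where rounding error is small relative to the
  frequency (the mid-frequency SNPs); low-MAF rows require the
  original counts, which are not public.
- Scores built on a European-descent founder population need not
  transfer to other ancestries; the package makes no portability
  adjustment.
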