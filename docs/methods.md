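# Methods

## The question and the estimand

A randomized PICU nutrition trial (early vs late initiation of supplemental
parenteral nutrition) showed adverse long-term emotional/behavioral outcomes
in the early-PN arm, and a panel of 37 CpG sites whose leukocyte methylation
was altered by the intervention. The analysis implemented here asks a
*statistical mediation* question: how much of the intervention's predictive
contribution to the continuous behavioral scores (internalizing,
externalizing, total problems) is absorbed by the methylation panel when it
is added to multivariable models?

This is deliberately not a causal-mediation estimand (no natural
direct/indirect effects, no Mendelian randomization). The evidence is:

1. **Explanatory power.** Optimism-corrected R² of random-forest regressions
   under four covariate sets — baseline risk factors with/without the
   randomized arm, each with/without the 37 beta-values — and the
   *fold-increase* in corrected R² when the panel is added at a fixed
   intervention setting.
2. **Significance frequencies.** Over B arm-stratified bootstrap replicates,
   the number of replicates in which each covariate is independently
   significant (permutation-importance p ≤ 0.05). Mediation is flagged when
   the intervention is frequently significant in the baseline-only model,
   loses frequency once the panel enters, and at least one CpG exceeds the
   reporting threshold (default B/2) in its place.

## Models and procedures

**Random forest.** `sklearn.ensemble.RandomForestRegressor`; regression
convention mtry = ⌈p/3⌉; apparent R² = 1 − SSE/SST on the training data.
Library default is 500 trees with `min_leaf=5`; the analysis preset
(`ANALYSIS_RF`) is 15 trees with `min_leaf=18` — see *Numerical choices*.

**Permutation-importance p-values** (default scheme): the outcome vector is
permuted and the forest refit N times; covariate j's observed impurity
importance is ranked against its own null importances,
p = (1 + #{null ≥ obs}) / (1 + N). Under independence the observed
importance is exchangeable with the null draws, so p is uniform on its
grid by construction and can never be 0 (floor 1/(N+1)) — the frequency
logic depends on that. This tests *marginal* (any-path) association: a
variable whose effect is wholly carried by other included covariates can
remain significant as long as trees still use it. An alternative
per-feature scheme (permute column j, refit, rank j's importance against
those refits) is available behind `scheme="feature"`.

**Optimism-corrected R²** (Harrell's bootstrap): for each resample b, refit;
optimism_b = R²(fit_b on b) − R²(fit_b on the original data); corrected =
apparent − mean(optimism_b). Negative corrected values are reported with a
warning, never truncated (they are floored at 0 only inside Rubin pooling,
which needs [0, 1]).

**Multiple imputation.** Only outcomes may be missing. Chained equations
over the incomplete outcomes: each is regressed (Bayesian linear draw,
ridge-stabilized) on all covariates, the arm, all beta-values and the other
outcomes, and imputed by type-1 predictive mean matching with k=5 donors,
so imputations stay in the observed range. 10 burn-in cycles by default,
per-iteration imputed-value means exposed as a convergence trace.
Per-imputation seeds derive from the master seed by fixed offsets, so
increasing m never reshuffles earlier datasets. Outcome columns with >30%
missingness are excluded (warning + log) from imputation and modelling —
the inclusion bound that protects imputation-model stability. m defaults to
31; analysis presets use smaller m.

**Pooling.** R² across imputations is combined on the Fisher-z scale of the
multiple correlation: pooled = tanh(mean(atanh(√R²)))² (the Rubin
point-estimate rule applied to a variance-stabilized transform; the rules
are stated for estimates, so the transform choice is ours and is isolated
in `rubin_pool_r2`). Significance frequencies are averaged across
imputations and rounded half-to-even. A stack of identical datasets (zero
missingness) reproduces the single-dataset analysis exactly.

**Clustering.** Outcomes × CpG frequency matrix; Euclidean distance,
average linkage (both configurable), rows and columns independently.
Labels are sorted before linkage so results are invariant to input order
with ties broken by label. Heatmap: sequential orange ramp scaled
0 → B, row/column dendrograms, functional-class colour strip
(eight classes), PNG + SVG + a JSON sidecar that round-trips the matrix
and leaf orders exactly.

**Baseline statistics.** Wilcoxon rank-sum (exact by enumeration for
n+m ≤ 12 without ties, else normal approximation with tie and continuity
correction — the continuity-corrected approximation is within ~0.015 of the
exact p already at n=m=6) and Pearson chi-square without continuity
correction (Yates behind a flag). Chi-square p-values are intrinsically
discrete; uniformity holds in the large-count limit.

## The synthetic cohort

The generator emulates the structure the analysis assumes, not the trial's
data: n = 192 + 211 children; 13 baseline covariates with PICU-plausible
marginals (age mixture with 40% infants, PIM3/PeLOD Gaussian, multinomial
categoricals — scene-setting only); 37 beta-values, logit-normal per site
(site means spread over [−2.5, 2.5], logit SD 0.5) so arm shifts are
additive on the logit scale and values stay in (0, 1); outcomes = covariate
signal + Σ(effect × standardized mediator beta) + direct arm effect +
Gaussian noise, with total = ½(internalizing + externalizing) + noise.
Missingness is MAR: exactly round(frac·n) rows per outcome, drawn without
replacement with logistic weights in standardized PIM3 and age (the exact
count satisfies the realized-fraction contract; Bernoulli draws would not).

**Scenario presets** (`full_mediation`, `partial_mediation`, `null`). The
source study reports no effect magnitudes, so the presets were fixed once by
a pilot calibration with two goals: the mediated signal must be recoverable
at n≈400, and the intervention must be a *borderline* predictor in baseline
models — mirroring the study, where it was significant in only 59–80% of
bootstrap replicates. The calibration exposed two structural facts worth
recording: (i) outcome-permutation importance tests marginal association,
so the intervention's frequency only drops when strong mediators outcompete
it for splits — a ceiling-strength intervention never loses significance;
(ii) in the with-intervention fold, the denominator model's arm variable
already proxies the full mediated signal, so weak arm→CpG coupling with
strong CpG→outcome effects maximizes the fold. Frozen values:
full_mediation has 5 mediator sites, arm→CpG 0.22 (logit), CpG→outcome 0.45
SD per SD, no direct effect, covariate confounding 0.6, noise SD 1.0;
null zeroes all three effects (covariate signal kept so fold denominators
stay positive); partial_mediation halves the mediated path and adds a 0.35
SD direct effect.

What the generator does *not* emulate: probe-level array artifacts, batch
and cell-composition effects, non-Gaussian outcome scales (CBCL scores are
bounded counts), measurement error in covariates, and informative (MNAR)
dropout. Passing recovery tests therefore show the pipeline detects the
assumed structure at trial scale — not that the published effect sizes are
correct.

## Numerical choices

* **Forest regularization.** Harrell optimism correction is only honest for
  bagged trees when leaves are large: on pure-noise outcomes (n=300, 10
  covariates) corrected R² ≈ 0.16 at min_leaf=5 but ≈ 0.00 at min_leaf≥15.
  Very large leaves (25+) underfit the mediated variance (fold → ~1.1).
  The analysis preset uses min_leaf=18, 15 trees; all exposed in `RFParams`.
* **Bootstrap streams.** One stream serves both optimism and frequencies by
  default; `n_bootstrap_optimism` lets the R² estimate use more replicates
  than the (much more expensive) frequency counting. Resampling is
  stratified by arm so both arms survive every replicate (unstratified mode
  available).
* **Determinism.** All child seeds derive from the master seed via
  `numpy.random.SeedSequence` with fixed integer tags; categorical encodings
  follow a fixed level order; dendrogram tie-breaks are by label. Two runs
  with the same config are checksum-identical on all numeric artifacts.
* **Degenerate inputs.** Constant outcomes (SST=0) and all-missing columns
  raise; constant bootstrap resamples contribute zero optimism; a
  single-outcome frequency matrix skips clustering with a log entry; a
  non-positive fold denominator raises `FoldIncreaseError` (reported, never
  clipped).

## Standard problem sizes

Simulation-based checks run at reduced, fixed sizes chosen with the
package's fit-time model: permutation-calibration at 200 null datasets
(n=200, 10 covariates, 99 permutations); optimism honesty at 60 noise runs
(n=300, 30 bootstraps) plus one noiseless run at n=2000; scenario recovery
at 10 end-to-end runs per scenario (n=400, m=2 imputations, frequency B=20,
optimism B=40, 19 permutations); the acceptance script runs the full
pipeline at n=403 with m=3. Larger settings (B=100, 200 permutations,
m=31) are the library defaults and scale linearly in B × (permutations+1) ×
m forest fits.

## Known limitations

* Impurity importance is biased toward high-cardinality features; the
  binary intervention competes on an uneven footing with continuous
  beta-values. The permutation null (each covariate ranked against its own
  permuted-refit importances) cancels most but not all of this.
* The mediation flag is a descriptive decision rule on frequencies, not a
  test with a controlled error rate.
* Fisher-z pooling of R² is one defensible choice among several; it is
  pluggable and documented, and reduces to the identity for m=1 or equal
  inputs.
* With 19 permutations the p-value grid is coarse (floor 0.05 = α), so a
  replicate is "significant" only when a covariate beats all its null
  draws; analysis at larger permutation counts sharpens frequencies but
  scales cost linearly.
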