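# Methods

This note documents the models, defaults and numerical choices behind
`hcmfs`, and what the synthetic studies do and do not demonstrate.

## The selection model

HC-MFS treats feature selection as two coupled problems: *redundancy*
(features that carry the same information) and *relevance* (features that
separate the classes).  Redundancy is modelled by Ward agglomeration of
z-scored feature columns under Euclidean distance; for standardized columns
the squared distance is 2n(1 − r) in the Pearson correlation r, so Ward's
minimum-variance objective is well defined and co-varying features merge
early.  This is the only feature representation under which Ward's
objective is meaningful, which is why the package standardizes internally
(with a warning) when handed a non-standardized table.  A
correlation-distance alternative is deliberately not offered as a default;
Ward heights would lose their variance interpretation.

Relevance is measured by the Fisher score with **population** (1/n_c) class
variances.  The constant matters only as a global factor, but fixing it
makes hand-computed oracle values exact (e.g. the six-point example
[0,1,2 | 3,4,5] scores 13.5/4).  The Fisher score is translation- and
scale-invariant, so it can be computed on any preprocessing variant.

The seeding rule is strict: a feature enters F_FSS only when its score
strictly exceeds its cluster's mean.  Consequences worth knowing: a
singleton cluster never seeds anything (its score equals the cluster mean),
and a cluster of exactly tied scores seeds nothing.  An empty overall seed
is legal; the wrapper searches then start from the empty set, whose CV
"accuracy" is defined as the training-fold majority-class rate.

### Wrapper searches

Both searches are single-pass greedy, visiting each candidate exactly once
("until all features are considered").  Defaults that were genuinely open
and are therefore configuration-visible and logged:

* **Candidate order** — descending Fisher score for the forward pass,
  ascending for the backward pass, consistent with the score-driven
  seeding.
* **Acceptance** — forward requires a *strict* CV-accuracy increase;
  backward removes when removal does *not decrease* accuracy.  The
  asymmetry breaks oscillation and encodes parsimony: an exactly neutral
  feature is never added and always removed.
* **Backward start** — the full feature set, not F_FSS.  Starting from the
  seed would make the backward pass a no-op; starting from the full set is
  the only reading under which a backward winner can be larger than the
  seed, which is a reachable state the benchmarks rely on.
* **Fold freezing** — the stratified 5-fold partition is drawn once per
  search from the run seed, so every candidate comparison is paired;
  re-randomizing per candidate would inflate the variance of accuracy
  differences and make strict-improvement acceptance erratic.
* **Tie between directions** — higher accuracy, then fewer features, then
  forward.

The default wrapper classifier is logistic regression (liblinear): it is
deterministic, fast, and one of the five benchmark models.  Any
`ModelConfig` (KNN/RF/SVM/NB/LR) can be substituted; the shipped
`data/model_settings.json` carries the per-method settings used in the
original benchmark, including the RF winner (max_depth 16, 300 trees).

A property maintained by construction: the winning direction's final
accuracy is never below the seed subset's own CV accuracy (forward never
accepts a loss, backward never accepts a decrease).

Strict-improvement acceptance on noisy CV estimates does admit an
occasional pure-noise feature: measured per-candidate rejection of noise is
roughly 75–95% depending on how close the current subset is to its accuracy
ceiling.  The test suite therefore asserts "at most one chance acceptance
among four noise candidates" rather than perfect rejection; perfect
rejection would require an acceptance margin the method does not use.

## Synthetic cohorts

The generator emulates the structure of the motivating AF cohort (two
groups of 339, 20 mixed features) because the original hospital data are
restricted.  Per feature it reproduces the published per-group mean ± SD
(numeric), season proportions (one 4-level categorical, coded ordinally
1–4), and diabetes/hypertension proportions (binary).  Three design points:

* **Marginals.**  Numeric features are Gaussian — the source table reports
  only mean ± SD, so any heavier-tailed choice would be invention.  A
  physical floor (0 for counts/concentrations) is enforced by conditioning
  the Gaussian on exceeding the bound via the truncated-normal inverse CDF:
  continuous tails, no point mass at the floor, and — because the map is
  monotone in the latent variable — block coupling survives.  Where the
  floor cuts real mass the printed moments cannot be reproduced exactly:
  C-reactive protein (27.74 ± 55.00, ~31% sub-zero mass) generates with
  mean ≈ 57 and SD ≈ 40.  Moment-recovery tests therefore assert agreement
  only where the floor is inactive (<1% truncated mass); heavily truncated
  features are structural stand-ins, not distributional replicas.
* **Dependence.**  Within-block correlation is induced per group by a
  Gaussian copula with one exchangeable latent factor per block at r = 0.8,
  leaving marginals untouched.  The default blocks mirror the three-cluster
  feature topology of the motivating study: a season/cholesterol block
  (season, temperature, pollutants, lipids, CRP, uric acid, comorbidities),
  an age/red-cell block (age, erythrocyte and platelet indices), and
  platelet count alone.  With these defaults, Ward clustering at k = 3
  isolates the platelet feature in effectively every seed.
* **Missingness.**  Cells are masked completely at random; the default rate
  for the emulated cohort is 2% (the source reports missingness but no
  rate; 2% is typical of curated inpatient registries).  Labels are never
  masked.

The planted-signal study condition is 6 informative features with a
standardized group difference of d = 1.0 plus 14 independent noise
features, 150 samples per group — a moderate, clinically plausible effect
at a cohort size where 5-fold CV is stable.  Under these conditions HC-MFS
recovers the informative set with mean recall ≈ 0.98 over 20 seeds.

What the synthetic studies do **not** show: robustness to non-Gaussian
marginals, informative missingness, label noise, or the particular
correlation geometry of the real cohort; the printed real-data relevance
values and benchmark accuracies are not reproducible without the restricted
data and are not targeted.

## Preprocessing

The four benchmark variants apply, in fixed order: drop rows with more than
5 missing feature cells → impute (column mean for numeric, mode for
categorical, smallest code on mode ties) → optionally mean-substitute
outliers → optionally standardize.  The outlier rule is |z| > 3 on the
column (mean and sample SD over all rows), with flagged cells replaced by
the mean of the unflagged cells — this never increases a column's SD.
Whole-table standardization is for exploratory reports only; inside
cross-validation, scaling always uses training-fold statistics (a pipeline
step), so held-out folds leak nothing.

## Statistics

Two-group numeric comparisons use the Welch t (summary-based or raw); with
equal group sizes it coincides with the pooled-SE statistic, which is the
form that reproduces the published Age/PM10/NO2/minimum-temperature rows to
3 decimals from the printed summaries.  Count comparisons use the
uncorrected Pearson chi-square (the published season statistic 36.091
matches the uncorrected form exactly).  A handful of published rows are not
reproducible from their own printed summaries (per-feature n likely varied
with missingness, and two chi-square entries are not chi-square values at
the printed counts); the package reports its own correctly computed
statistics for such rows and no test targets the printed ones.

Mutual information uses the plug-in estimator in nats with 10
equal-frequency bins for numeric features (duplicate quantile edges
collapsed); the plug-in bias on independent pairs is < 0.05 nats at
n = 2000, which the calibration suite checks.  Distance correlation is the
biased sample dCor from double-centered distance matrices, with the
convention dCor = 0 when either distance variance vanishes.  Relief-F uses
all instances by default, k = 10 neighbors (errors if k exceeds the
smallest class size − 1), range-normalized numeric differences and 0/1
categorical indicators, with Manhattan distance for neighbor search and
stable index-order tie-breaking.

## Metrics

For hard 0/1 predictions, RMSE on the labels satisfies
rmse² = 1 − accuracy exactly (124 correct of 136 → 0.9118 / 0.2970).  Two
benchmark quantities have no standard definition and are fixed here as:
"R" = Pearson correlation between true and predicted labels (0 when either
is constant), "std" = sample standard deviation (ddof = 1) of the signed
residuals, which approaches the RMSE when errors are balanced across
classes.  AUC is the rank statistic on continuous scores
(probability/decision function when the model provides one) and is omitted
for hard-label-only input.

## Problem sizes and determinism

Every stochastic procedure is a pure function of an integer seed.  The
shipped studies use: 100 random instances for the Ward and distance-
correlation oracle suites (n ≤ 8 and n ≤ 50), 10 instances for the
forward-search replay, 2000 null replicates for t-test calibration, 20
seeds each for null-AUC and planted-recovery, 10 for null-MI, and 50 for
platelet-block isolation — sizes at which the binomial uncertainty of each
rate is comfortably below the margin being asserted.

## Known limitations

* Missingness is MCAR only; no mechanism for informative missingness.
* The wrapper searches are single-pass greedy by design; no floating
  (SFFS/SBFS) variants.
* Outlier handling offers mean substitution only; median/truncation/
  distribution-based schemes are deliberately out of scope.
* Relief-F is O(m·n·p) with dense distance evaluation — fine for hundreds
  of samples and tens of features, not for wide genomics-scale tables.
* `suggest_k` (silhouette over the feature-distance matrix) is advisory;
  an explicit k always wins.
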