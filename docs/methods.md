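# Methods

`panelminer` implements a biomarker-panel discovery pipeline for imbalanced
case/control metabolomics cohorts: cohort preprocessing, propensity-score
matching, a three-selector ensemble feature-selection stage, set-algebra
cataloguing of the selector outputs, a random panel-sampling search with
frequency consolidation, and a repeated cross-validation evaluation
harness. This note records the models, the defaults and why they were
chosen, the numerical decisions, and what the synthetic-data experiments do
and do not demonstrate.

## Synthetic cohort model

The generator emulates a targeted plasma-metabolomics case/control study.
Its defaults are the reference design: 185 cases vs 53 controls, 138
metabolites of which 6 exceed the 30 % missingness filter, demographic
covariates (age, BMI, 3-level race, 4-level smoking status), an 8-year mean
age excess in cases, and eleven genuinely discriminative metabolites (the
nine panel lipids/acylcarnitines/amino acid at ±1.5 pooled-SD effects plus
the kynurenine-pathway pair at ±0.8 SD, which makes the
Kynurenine-to-Tryptophan ratio informative).

* **Concentrations** are log-normal (`log x ~ N(mu_j, sigma)`, default
  `sigma = 0.5`; per-feature baselines `mu_j ~ N(log 10 µM, 1)` drawn once
  per cohort). Concentrations are positive and right-skewed, as measured
  metabolite panels are; no per-metabolite reference ranges are modelled.
* **Case effects** are additive shifts of `d·sigma` on the log scale, so an
  effect of `d` is `d` pooled-SD units of standardized separation on the
  log scale and positivity is preserved. Note the analysis operates on the
  raw (exponentiated) scale, so the realised raw-scale separation is
  slightly smaller — planted effects are conservative labels.
* **Missingness** is missing-completely-at-random with an exact per-feature
  count `round(rate·n)` (default 2 % per metabolite, 40 % for the six
  sparse columns), so configured rates are met to within `1/n` and the
  sparse columns always trip a strict 30 % filter.
* **Demographics**: age `N(50, 10)` (+ age effect for cases), BMI
  `N(27, 5)` clipped at 15, race `white/African American/other` at
  0.6/0.3/0.1, smoking `never/current/past/history` at 0.5/0.2/0.2/0.1.
  These are fixture conventions, not estimates from any cohort.

What the generator does **not** model: instrument batch effects, LC drift,
censoring at the detection limit (missingness is independent of
concentration), covariate-dependent missingness, correlated metabolite
modules beyond the planted group factor, or any relationship between
demographics and metabolite levels. Passing recovery tests therefore shows
that the pipeline finds planted mean-shift signal under MCAR missingness —
not that it is robust to batch structure or informative missingness.

## Preprocessing

Fixed order: exclude males → drop features with missing fraction **strictly
greater** than 0.30 → impute (metabolites with their instrument detection
limit, default 0.05 µM; numeric demographics with the observed mean) →
one-hot encode race and smoking onto fixed category columns → append the
Kynurenine/Tryptophan ratio → z-score continuous columns with population
(ddof = 0) SDs. On the reference design this yields 132 + 1 + 8 = 141
features. Decisions worth noting:

* Imputation is a single pass over the full cohort (it is a fixed
  preprocessing step); only standardization is refitted fold-wise during
  evaluation, and the fitted means/SDs are returned so held-out data is
  transformed with training moments only.
* The ratio is computed after imputation; since detection limits are
  positive the denominator cannot be zero on conforming inputs.
* Smoking is encoded onto exactly the three named indicator columns
  (current / past / history); never-smokers are the all-zero row. Unknown
  race levels map to `other` with a warning. 0/1 indicator columns are
  never z-scored; zero-variance columns are left unscaled with a warning.
* An 80/20 stratified hold-out split is available
  (`preprocess.train_validation_split`) but the default pipeline evaluates
  by cross-validation only.

## Propensity-score matching

Propensity scores come from a 100-tree random forest. Out-of-bag
probabilities are used where defined (full-fit probabilities saturate at
0/1 on separable data, which destroys the neighbor ordering); samples never
out of bag fall back to the full-fit probability. The default covariates
are the **numeric demographic columns**: the propensity model's job is to
balance confounders, and feeding it the biomarkers themselves makes the
score track the outcome signal rather than the confounding (empirically,
the age-balance improvement disappears). The covariate list is an explicit
argument for users who want the all-features variant.

Each case is matched to its `k = 3` nearest controls by absolute propensity
difference, ties broken by control position, optional caliper off by
default. Augmentation: a control selected by `m > 1` distinct cases is
appended `m − 1` times (configurable per-control limit), allocated
round-robin most-selected-first, and the control arm never grows beyond the
case arm. This is an interpretation — with a 53-control pool the published
arithmetic (53 → 99) is only reachable by duplication, but the exact rule
used there is not recoverable — and the match report flags it as such.
Balance is diagnosed by standardized mean differences,
`|mean₁ − mean₀| / sqrt((s₁² + s₂²)/2)`, reported before and after
matching; zero pooled SD reports an SMD of 0 with a warning.

Matching on absolute score differences is invariant to increasing *affine*
transforms of the scores, not to arbitrary monotone ones (a rank transform
stretches intervals unevenly and can reorder neighbors); the test suite
asserts the affine property.

## Feature selectors

* **Univariate naive Bayes**: every feature is scored alone with a Gaussian
  NB classifier over 100 stratified random 80/20 splits; features are
  ranked by mean accuracy (ties: mean F1, then name) and the top 15 kept.
  The scorer is a vectorised closed-form Gaussian NB (all features at once
  per split) with the same variance-smoothing rule as
  `sklearn.naive_bayes.GaussianNB`; a unit test pins exact agreement.
* **L2 linear SVC** (`C = 0.001`, dual formulation): an L2 penalty yields
  no exact zeros, so "automatic" selection is implemented as the
  conventional select-from-model rule — keep features with
  `|coef| ≥ mean(|coef|)` — ordered by descending magnitude.
* **PCA loadings** (8 components, 50 features): features are ranked by
  `Σ_c w_c · loading²_cj` with `w_c = max(EV_c − λ_bulk, 0)`, where
  `λ_bulk = (1 + sqrt(p/n))²` is the Marchenko–Pastur upper bulk edge for
  standardized data — the largest eigenvalue pure noise produces at this
  shape. Components whose eigenvalue is indistinguishable from noise
  therefore contribute nothing. This choice is deliberate: a uniform
  round-robin allocation over components (kept available as
  `pca_allocation="round_robin"`) gives every retained component an equal
  share of the selection budget, so a signal concentrated on one axis is
  diluted by noise components — measured planted-feature recovery 0.21
  versus 1.0 for the weighted rule on the standard recovery fixture. If no
  eigenvalue exceeds the bulk edge the rule falls back to plain eigenvalue
  weights. The score uses squared loadings, so it is invariant to component
  sign flips.

Whether selectors run on the matched or the original cohort is a pipeline
mode; the default is the matched cohort (matching precedes selection in the
stage order).

## Set algebra

Unions, intersections and symmetric differences are exact set operations
with deterministic member order (left operand first, then novel right
members). The catalogue holds the full feature set, the three selector
sets, all pairwise combinations, the triple intersection and union, and any
consolidated panels — 18 entries on a full run with the three pruned
panels. Set identities (inclusion–exclusion, `AΔB = (A∪B)\(A∩B)`,
`A∩B∩C ⊆ A∩B`) are enforced by construction and property-tested. Note that
published selector-overlap cardinalities of the form |SVC∩PCA| = 17,
|SVC∩NB| = 7, |PCA∩NB| = 15 = |NB| force NB ⊆ PCA and hence a triple
intersection of exactly 7; the package computes true set algebra and will
not reproduce an inconsistent triple-intersection count.

## Panel search

Each iteration draws a panel size uniformly from [9, 12] and a uniform
subset of the pool without replacement (duplicate panels across iterations
are allowed), scoring it by cross-validated mean AUC. Retention is either
an absolute AUC threshold (default 0.95) or a top-quantile rule
(`retain_fraction`). Consolidation keeps features appearing in at least
`core_frequency` retained panels (default 4). Because the *chance*
frequency of any feature scales linearly with the number of retained panels
(≈ `n_retained · panel_size / pool_size`), an absolute threshold tuned for
a long search over a large pool is not selective for a scaled-down search
over a small pool; `core_fraction` therefore optionally raises the
threshold to a fraction of the retained panels (the recovery experiments
use "at least half"). The full 10×50 CV harness is reserved for final
panels; the search loop defaults to a 10×5 scorer, and the scaled-down
recovery experiments use 5×1.

"Leave-one-out" refinement is implemented as greedy backward elimination:
every leave-one-*feature*-out subset is scored by leave-one-*sample*-out
cross-validated AUC (pooled decision scores, one AUC), the best-scoring
removal is applied (ties: remove the lexicographically smallest name), and
the procedure recurses once more. The full candidate score trace is
returned so the refinement can be audited; a cheaper repeated-CV scorer is
available (`prune_scorer="cv"`).

## Evaluation harness

The reference classifier is an SVC with RBF kernel, `C = 5`,
`gamma = "scale"` (1 / (n_features · training-fold feature variance)) and a
balanced class weight — the configuration a grid search over
C ∈ {0.005, 0.05, 0.5, 5} (log-spaced across the stated range), four
kernels and two gamma modes selects by cross-validated AUC, with
deterministic tie-breaking (higher C, then kernel/gamma order as listed).
Repeated stratified k-fold (10 folds × 50 repeats at full fidelity) refits
the scaler and classifier on each training fold; AUC uses decision scores,
the other metrics hard predictions. The AUC interval is a 95 %
normal-approximation CI of the fold AUCs across all repeats. Degenerate
confusion-matrix denominators (MCC, precision, recall, F1) report 0;
single-class folds are skipped with a warning. Metric primitives are
scikit-learn's; the test suite checks them against hand-rolled brute-force
oracles (all-pairs AUC with half-weight ties, direct confusion-matrix
algebra, ROC trapezoid = rank AUC to 1e-12).

## Reporting

Per-feature two-sided Wilcoxon rank-sum tests (exact enumeration when both
groups ≤ 10 and the feature is tie-free, otherwise the tie-corrected normal
approximation); raw p-values by default with an optional Benjamini–Hochberg
column. Z-score matrices (features × samples, population SD, zero-variance
rows zeroed with a warning) and two-component PCA projections (sign-fixed
so each component's largest-|loading| feature loads positively) are emitted
as plot-ready tables; no figures are rendered.

## Problem sizes used in tests and the acceptance script

Recovery experiments run at deliberately reduced scale: 30-feature pools
with 10 planted 1.5-SD features, 150 samples/arm for selector recovery (20
seeds), 120/arm with 2,000 search iterations and a 5×1 CV scorer for panel
recovery (10 seeds in the test suite, 4 in the acceptance script), 100
cases/30 controls for the matching-balance experiment. The full-scale
defaults (15,000 iterations, 10×50 CV) remain the package defaults.

## Known limitations

* The augmentation rule and the PSM covariate choice are interpretations of
  an under-specified procedure; both are configurable and flagged in the
  match report.
* MCAR missingness and independent features-given-group are idealisations;
  results on real targeted panels with censored missingness and correlated
  lipid modules may differ.
* The LOOCV pruning scorer is high-variance; on saturated panels (CV AUC at
  1) removals tie and the name tie-break, not signal, decides.
* No calibration analysis, DeLong variance, or decision-curve analysis is
  provided.
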