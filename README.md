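# panelminer

Biomarker-panel discovery for imbalanced case/control metabolomics cohorts.

Targeted plasma metabolomics measures on the order of a hundred metabolite
concentrations per sample; case/control studies built on such panels are
typically small, heavily imbalanced (many more cases than controls), and
high-dimensional relative to their sample size. `panelminer` implements a
complete discovery pipeline for this setting, aimed at analysts who want a
small, robust, interpretable biomarker panel rather than a black-box
classifier over all features:

1. **Preprocessing** — subject exclusion, removal of features with > 30 %
   missing values, imputation (instrument detection limit for metabolites,
   observed means for demographics), one-hot encoding of categorical
   demographics, engineered metabolite ratios (Kynurenine/Tryptophan), and
   z-scoring.
2. **Propensity-score matching** — a random-forest model estimates
   π(x) = P(case | covariates); each case is matched to its k = 3 nearest
   controls by |π(xᵢ) − π(xⱼ)| and frequently selected controls are
   duplicated into the cohort, shrinking the class imbalance. Balance is
   diagnosed by standardized mean differences,
   SMD = |x̄₁ − x̄₀| / √((s₁² + s₀²)/2).
3. **Ensemble feature selection** — three selectors with complementary
   views: per-feature Gaussian naive Bayes accuracy over 100 stratified
   splits (top 15), an L2-penalised linear SVC (C = 0.001) keeping features
   with |w_j| ≥ mean|w|, and PCA-loading selection over 8 components.
4. **Set algebra** — unions, intersections and symmetric differences of
   the selector sets form a catalogue of candidate feature sets
   (SVC ∪ PCA, SVC ∩ NB, PCA Δ NB, …) that are all evaluated side by side.
5. **Random panel search** — thousands of random 9–12-feature panels from
   the selector union are scored by cross-validated AUC; features recurring
   in the high-performing panels are consolidated into a core panel, which
   a leave-one-feature-out pass (scored by leave-one-sample-out AUC)
   refines further.
6. **Evaluation** — repeated stratified k-fold cross-validation (10 × 50)
   of an RBF-kernel SVC (C = 5, γ = scale, balanced class weights; chosen
   by grid search), reporting AUC with a 95 % CI, accuracy, Matthews
   correlation, F1, precision and recall; plus per-feature Wilcoxon
   rank-sum tests and plot-ready z-score/PCA exports.

Because cohorts of this kind are rarely shareable, the package ships a
synthetic-cohort generator (`panelminer.synthetic_cohort`) that reproduces
the study design the pipeline assumes — 185 cases vs 53 controls, 138
metabolites with 6 sparse columns, an age confound, and a configurable set
of truly discriminative metabolites — so every stage is testable end to
end. See `docs/methods.md` for the generative model and all numerical
decisions.

## Worked example

`examples/` contains one short script per capability. Preprocessing
arithmetic on the reference design (`examples/02_preprocess.py`):

```text
dropped sparse metabolites: ['Met019', 'Met020', 'Met021', 'Met022', 'Met023', 'Met024']
retained metabolites: 132 (expect 132)
values imputed (LOD for metabolites, mean for demographics): 1230
final feature count: 141 (expect 132 + 1 + 8 = 141)
Kyn/Trp ratio column: standardized, mean 5.97e-17, SD 1.00
```

138 metabolites lose the 6 columns above the 30 % missingness filter; the
132 survivors plus the Kynurenine/Tryptophan ratio and 8 encoded
demographic columns give the 141-feature analysis table.

Scoring an 11-feature panel with the repeated-CV harness
(`examples/06_evaluate_and_report.py`):

```text
panel of 11 features, 10-fold CV x 5 repeats:
  AUC  0.995  (95% CI 0.992-0.998)
  accuracy 0.974  MCC 0.927  F1 0.983
```

The panel here is exactly the synthetic cohort's planted signal (nine
discriminative metabolites, the Kyn/Trp ratio and age), so near-perfect
discrimination is the expected outcome; the per-feature rank-sum p-values
printed below it are all ≪ 0.01.

The full pipeline runs from a YAML config:

```bash
panelminer run --config pipeline.yaml
```

with single-stage commands (`panelminer simulate / preprocess / match /
select / combine / search / evaluate / report`) for stepwise use.

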