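"""Random panel search with frequency consolidation and backward pruning.

Thousands of random 9–12-feature panels are drawn from the selector-union
pool and scored by cross-validated AUC.  Features recurring in the
high-performing panels form the core panel, which a leave-one-feature-out
pass then refines.  A scaled-down search (500 iterations, small pool) keeps
this example quick.
"""

import panelminer as pm
from panelminer.feature_select import FeatureSet

names = tuple(f"Met{i:03d}" for i in range(101, 131))
planted = tuple((n, 1.5) for n in names[:10])
cohort = pm.generate_cohort(
    pm.SimConfig(n_cases=120, n_controls=120, n_metabolites=30, feature_names=names,
                 planted_features=planted, sparse_features=(), missing_rate=0.0,
                 age_effect=0.0, seed=4)
)
clean, _ = pm.run_preprocess(
    pm.Cohort(cohort.data.drop(columns=["race", "smoking", "age", "BMI"]),
              cohort.metabolites, ())
)

config = pm.PanelSearchConfig(
    n_iterations=500, panel_size_min=9, panel_size_max=12,
    retain_fraction=0.02, core_fraction=0.5, seed=4,
    eval_config=pm.EvalConfig(n_folds=5, n_repeats=1, seed=4),
)
result = pm.sample_panels(FeatureSet("pool", clean.features), clean, config)
core = pm.consolidate(result, config)

print(f"panels scored: {len(result.panels)}; retained above AUC "
      f"{result.auc_threshold:.3f}: {len(result.high_performers)}")
print(f"unique biomarkers across retained panels: {len(result.unique_biomarkers)}")
truly = set(n for n, _ in planted)
print(f"core panel ({len(core)} features, planted marked *):")
for f in core:
    print(f"  {'*' if f in truly else ' '} {f}  (in {result.frequency_table[f]} retained panels)")

pruned = pm.prune_by_feature_loocv(core, clean, config)
for fs, score in pruned.subsets:
    print(f"pruned to {len(fs)} features, LOOCV AUC {score:.3f} (removed "
          f"{set(core.members) - set(fs.members) or '-'})")
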