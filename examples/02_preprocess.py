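"""Run the preprocessing chain and verify the feature arithmetic.

Exclusion -> 30% missingness filter -> LOD / mean imputation -> one-hot
encoding of race and smoking -> Kynurenine-to-Tryptophan ratio -> z-scoring.
On the reference design this must end at 132 metabolites + 1 ratio + 8
demographic columns = 141 features.
"""

import panelminer as pm

cohort = pm.generate_cohort(pm.SimConfig(seed=1))
clean, report = pm.run_preprocess(cohort)

print(f"dropped sparse metabolites: {report['dropped_sparse_features']}")
print(f"retained metabolites: {report['n_retained_metabolites']} (expect 132)")
print(f"values imputed (LOD for metabolites, mean for demographics): {report['n_imputed_values']}")
print(f"final feature count: {report['n_features']} (expect 132 + 1 + 8 = 141)")
ratio = clean.data["Kyn/Trp"]
print(f"Kyn/Trp ratio column: standardized, mean {ratio.mean():.2e}, SD {ratio.std(ddof=0):.2f}")
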