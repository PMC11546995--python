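"""Generate a synthetic plasma-metabolomics cohort and inspect its design.

The default configuration mirrors the reference study design: 185 cancer
cases vs 53 controls, 138 metabolites (6 with >30% missing values), an
8-year age shift in cases, and eleven genuinely discriminative metabolites.
"""

import panelminer as pm

config = pm.SimConfig(seed=1)
cohort = pm.generate_cohort(config)

print(f"cohort: {cohort.n_cases} cases / {cohort.n_controls} controls")
print(f"metabolite columns: {len(cohort.metabolites)}")
sparse = (cohort.data[list(cohort.metabolites)].isna().mean() > 0.30).sum()
print(f"columns above the 30% missingness filter: {sparse}")
age = cohort.data.groupby("group")["age"].mean()
print(f"mean age, controls vs cases: {age[0]:.1f} vs {age[1]:.1f}")
print("planted case effects (pooled-SD units on the log scale):")
for name, effect in config.planted_features:
    print(f"  {name:15s} {effect:+.1f}")

pm.write_fixture(cohort, "cohort.csv")
print("wrote cohort.csv — sample_id, group, then feature columns; blanks = missing")
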