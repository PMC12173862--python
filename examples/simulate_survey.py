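"""Generate a synthetic household food-consumption survey.

Builds the default stratified design (3 provinces x 4 counties x 3 townships
x 3 villages x 10 households, 3 survey days) and prints what came out: the
sampling counts and the calibrated covariate moments.  The printed means/SDs
should sit near the descriptive targets the generator is calibrated to
(e.g. per-capita income 2.53 +/- 2.51 in 10^4 Yuan, elderly share ~26.8%).
"""

from ruraldiet import generate_survey

data = generate_survey(seed=1)
cov = data.covariates

print(f"households: {cov.household_id.nunique()}")
print(f"villages:   {cov.village_id.nunique()}")
print(f"counties:   {cov.county_id.nunique()}")
print(f"consumption rows: {len(data.consumption)}")
print()
for col in ("income", "ratio_under18", "ratio_over65", "household_size"):
    print(f"{col:>15}: mean {cov[col].mean():6.2f}  sd {cov[col].std():6.2f}")
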