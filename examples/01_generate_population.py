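"""Generate a synthetic screening cohort and inspect its joint structure.

The generator couples age, blood pressure, lipids, glucose, BMI and
baseline EQ-5D utility through a Gaussian copula, with sex-specific
smoking, age-graded prior-CVD prevalence, and diabetes flags consistent
with the generated glucose values.
"""

import pandas as pd

from cvdscreen import PopulationSpec, generate_population

pop = generate_population(PopulationSpec(n=5000, seed=7))

print(f"{len(pop)} persons; weighted population "
      f"{pop.survey_weight.sum():,.0f}")
print("\nMarginal summaries:")
print(pop[["age", "sbp", "dbp", "total_cholesterol", "fasting_glucose",
           "bmi", "baseline_utility"]].describe().loc[["mean", "std"]].round(1))

print("\nPrevalence by flag:")
for col in ("diabetes", "smoker", "prior_cvd"):
    print(f"  {col:10s} {pop[col].mean():6.1%}")

band = (pop.age // 10 * 10).astype(int)
print("\nPrior CVD by age decade (should rise with age):")
print((pop.groupby(band).prior_cvd.mean() * 100).round(1).to_string())

# Age-blood pressure coupling from the copula plus the explicit gradient:
print(f"\ncorr(age, sbp)              = {pop.age.corr(pop.sbp):.2f}")
print(f"corr(age, baseline_utility) = {pop.age.corr(pop.baseline_utility):.2f}")
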