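"""Generate a synthetic claims-like cohort and inspect its shape.

The generator draws elderly-population demographics, comorbidity flags,
recent ICU/CCU utilization and zero-inflated 6-month cost variables,
then assigns a rare binary outcome from a known logistic model whose
intercept is calibrated to a target prevalence.
"""

import riskscores as rs

cohort = rs.make_claims_like_cohort(seed=7, n=50_000)

print(cohort)
print(f"prevalence: {rs.prevalence(cohort):.4%}  (target 0.70%)")
print(f"female fraction: {cohort.frame['female'].mean():.3f}  (template 0.769)")
print("age-band frequencies:")
print(cohort.frame["age_band"].value_counts(normalize=True).sort_index().round(3))
zero_share = (cohort.frame["inpatient_cost_6m"] == 0).mean()
print(f"inpatient cost: {zero_share:.0%} zeros, "
      f"max ${cohort.frame['inpatient_cost_6m'].max():,.0f}")
print()
print("The outcome is rare (~0.7%) and the cost columns are zero-inflated and")
print("right-skewed, which is the regime the scoring methods are built for.")
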