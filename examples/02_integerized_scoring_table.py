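"""Fit an integerized logistic-regression scoring table.

Variables are binned with monotone weight of evidence, dummy-encoded,
and at most 10 bin indicators are kept by a LASSO path.  The logistic
coefficients are scaled by c = |b0| * a and rounded to integers, with a
halved until the total-score range reaches the requested minimum.
"""

import riskscores as rs

cohort = rs.make_claims_like_cohort(seed=7, n=50_000)
model = rs.fit_integerized(cohort, max_features=10, r_star=10)

print("scoring table (points added when the indicator is 1):")
print(model.to_table().to_string(index=False))
print(f"\nscaling factor c = {model.scale_c:.4f}, a = {model.a:g}")
print(f"intercept points = {model.intercept_points}")
print(f"total score range = {list(model.score_range)}")

scores = model.score_frame(cohort)
s_hi = int(scores.max())
print(f"\nhighest observed total {s_hi} -> predicted risk "
      f"{model.score_to_probability(s_hi):.3%}")
print(f"total 0 -> predicted risk {model.score_to_probability(0):.3%}")
print()
print("A clinician sums the points of the conditions a patient meets; the")
print("probability map 1/(1+exp(-c(score+intercept))) recovers calibrated risk.")
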