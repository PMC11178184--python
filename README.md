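# riskscores

Integer risk-score models for rare binary outcomes in tabular
healthcare data.

Clinical and actuarial practice often needs a scoring table a person
can evaluate with pencil and paper: a handful of conditions, integer
points for each, and a total score that maps to a probability.  This
package builds such tables from a flat observation table (rows =
patients or patient-months, mixed binary / continuous / categorical
predictors, a rare binary outcome such as a preventable
hospitalization) using two complementary constructions, together with
the threshold-selection and evaluation machinery the imbalanced-outcome
setting requires.  It is aimed at biostatisticians and health-services
researchers who want interpretable risk models with a fully
reproducible, testable pipeline.

## Methods

**Monotone WOE binning.**  Every variable is partitioned into ordered
categories whose weight of evidence

&nbsp;&nbsp;&nbsp;&nbsp;WOE_j = ln[ (e_j/E) / (n_j/N) ]

is monotone across bins (e_j, n_j: event / non-event counts in bin j;
E, N: group totals; additive smoothing 0.5 guards zero cells).  Higher
WOE means higher risk.  A variable's predictive strength is its
information value IV = Σ_j (e_j/E − n_j/N)·WOE_j ≥ 0.

**Integerized logistic regression.**  Bins are dummy-encoded, a
logistic model ln(p/(1−p)) = β₀ + Σ β_k x_k is fit with an L1 path
keeping at most 10 indicators, and the coefficients are scaled by
c = |β₀|·a and rounded: points β′_k = [β_k/c].  The constant a starts
at 10^⌊log₁₀ max_k|β_k/β₀|⌋ and is halved until the total-score range
R = S_max − S_min reaches a requested minimum R*.  Probabilities come
back through p = 1/(1+exp(−c(score+β′₀))).

**Credit scorecard.**  Values are replaced by their bin WOE, the 15
variables with highest IV enter a LASSO-limited logistic fit (≤ 10
kept), and category j of variable k receives points
s_kj = [B·β_k·WOE_kj] on the scale S = A + B·ln(odds) with
B = ΔS/ln 2, so that ΔS extra points (default 10) exactly double the
odds; A defaults to 0.

**Evaluation.**  Decision thresholds maximize the F_β score with
β = 10 (false negatives weighted β² = 100× false positives), suitable
when missing a rare event is far costlier than a spurious alert.  The
package also computes AUC (midrank-corrected), the overlap of the
event / non-event score distributions, and an intervention-allocation
experiment comparing recall from treating the top-scored fraction of a
cohort against random selection.

A seeded synthetic cohort generator (rare outcome, zero-inflated
costs, ordered demographics, binary history flags, known logistic
ground truth) makes every stage testable without restricted claims
data.

## Worked example

```python
import riskscores as rs

cohort = rs.make_claims_like_cohort(seed=7, n=50_000)   # prevalence ~0.7%
model = rs.fit_integerized(cohort, max_features=10, r_star=10)
print(model.to_table().to_string(index=False))
```

```
                           feature  score
                        diabetes=1      1
              cognitive_disorder=1      2
                     icu_last_3m=1      2
                  uti_history_6m=1      1
 inpatient_cost_6m=[-inf, 226.486)      3
    carrier_cost_6m=[-inf, 13.131)      1
 carrier_cost_6m=[13.131, 231.575)      1
outpatient_cost_6m=[-inf, 166.182)      1
```

Each row is one binary condition; a patient's total score is the sum
of the points of the conditions they meet.  Here the fitted scaling
factor is c = 0.3216 and the achievable total runs from 0 to 12; a
patient scoring 11 maps to a predicted risk of 5.2% versus 0.16% at
score 0.  Note the familiar epidemiology of such cohorts: recent ICU
stays and cognitive disorders add points, while *low* recent spending
(an unmonitored patient) is risk-increasing.

Evaluating the companion scorecard on the same cohort
(`examples/04_threshold_and_allocation.py`) prints

```
selected threshold: -5
AUC 0.675 | recall 0.866 | precision 0.0088 | F1 0.0174 | F10 0.441
event/non-event score-distribution overlap: 0.736
allocation-curve area (risk-based minus random): 0.173
```

— high recall and single-digit-per-mille precision is the expected
operating point at 0.7% prevalence, and the allocation area says
risk-based targeting captures on average 17 percentage points more of
the true events than treating a random subset of the same size.

The `examples/` directory walks through each capability
(simulation, both model fits, threshold selection and allocation); a
thin CLI mirrors the same steps
(`riskscores simulate|fit-integerized|fit-scorecard|score|evaluate`).

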