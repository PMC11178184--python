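# Methods

This note documents the models, numerical choices and limitations of
`riskscores` at the level of detail a maintainer or reviewer needs.
The README gives the user-facing overview; here we record why things
are the way they are.

## Binning with monotone weight of evidence

Continuous variables are pre-split into `n_prebins` quantile bins
(default 20).  Bins are half-open intervals `[lower, upper)`; values
outside the fitted range are clamped to the first/last bin, so scoring
new data is total and deterministic.  Categorical levels are taken in
their natural order when the variable is ordered, otherwise sorted by
event rate.  Adjacent bins are then merged greedily until the WOE
sequence is monotone: among the adjacent pairs violating the target
direction, the pair with the smallest |ΔWOE| is merged first (lowest
index on ties).  The direction is the sign of the Spearman rank
correlation between the variable and the outcome.  The procedure is
deterministic and, on small instances, is checked in the test suite
against exhaustive enumeration of all contiguous monotone merges:
pooling adjacent bins can only lose information (log-sum inequality),
so the exhaustive optimum always bounds the greedy IV from above, and
the tests confirm the greedy result is feasible and near-optimal.

Numerical conventions:

- WOE uses the natural log and additive smoothing (default 0.5 per
  cell): `ln[ (e+s)/(E+2s) / ((n+s)/(N+2s)) ]`.  With smoothing 0 a
  zero cell is a hard error instructing the caller to smooth or merge;
  rare-event data makes zero cells routine, hence the nonzero default.
- IV is computed from the same smoothed frequencies, so every summand
  is of the form (a−b)ln(a/b) ≥ 0 and IV ≥ 0 holds exactly.
- A scheme collapsed to a single whole-population bin stores WOE = 0
  (a full-population bin carries no evidence; smoothing would
  otherwise leave a residue of order s·|E−N|/(EN)).
- Minimum bin size defaults to 5% of n and at least 1 event per bin;
  undersized bins merge into the neighbour with the closer WOE.  When
  the minima cannot be met the variable degrades to a single-bin
  scheme with a warning rather than failing.
- Missing predictor values get a dedicated bin appended outside the
  monotone ordering (standard scorecard practice); rows with missing
  *outcome* are rejected at ingestion.
- Unseen categorical levels at scoring time map to the bin whose WOE
  is nearest zero — the least-informative default — and are logged.

## Integerized logistic regression

The dummy encoding drops one reference category per variable, chosen
as the lowest-WOE (safest) bin so that points are predominantly
non-negative increments over the safest group — the layout clinicians
expect from published scoring tables.

The L1 path uses scikit-learn's liblinear solver over a logarithmic
grid C ∈ 10^[−4, 2] (25 points), walked from the strongest penalty
upward; the selected penalty is the weakest whose non-zero count stays
within `max_features` (default 10).  If the count jumps past the
budget in a single step (exactly collinear columns entering together),
the largest-|coefficient| features of that fit are kept.  By default
the selected features are then refit without penalty: scaling
*shrunken* coefficients would distort the integer points, and the
refit makes the points interpretable as (scaled) log-odds ratios.  A
flag disables the refit.  Possible separation or non-convergence in
the refit triggers a warning and returns the capped iterate.

Integerization: c = |β₀|·a, points = round(β_k/c), with `a`
initialized to the power of 10 matching max_k|β_k/β₀| and halved until
the score range R ≥ R*.  Choices:

- Rounding ties go *away from zero*, so symmetric positive and
  negative effects receive symmetric points.
- `r_star` defaults to 10 — a one-digit scoring table of the size
  practitioners typically publish; raise it for finer resolution.
- `max_halvings` defaults to 20 to bound the loop when all slopes are
  tiny; exhaustion flags the model rather than failing.
- Features whose points round to 0 are dropped from the table; this
  provably never changes a total.
- The probability map uses the *rounded* intercept by default
  (consistent with the integerized log-odds approximation); the exact
  β₀/c is available via a flag for users who want the conversion
  anchored to the un-rounded fit.

The halving loop makes R non-decreasing as `a` falls, which the tests
assert directly.  Integerization fidelity — the rank correlation
between the integer total and the un-rounded fitted linear predictor —
is ≥ 0.95 in the acceptance conditions (measured ≈ 0.99).  Fidelity
against the *generator's* true linear predictor is lower (≈ 0.93 in
the same conditions) because binning and the 10-feature budget discard
within-bin variation of continuous effects; that loss belongs to the
discretization stage, not the rounding, and is reported separately by
the acceptance script.

## Credit scorecard

WOE transformation makes each variable enter the logistic model as a
single numeric column, so "one coefficient per variable" and monotone
category points are structural.  Selection is IV-top-15 (ties broken
lexicographically for determinism) followed by the same LASSO budget
of 10.  Points are s_kj = round(B·β_k·WOE_kj) with B = pdo/ln 2;
`pdo = 10` and offset A = 0 are the defaults.  The natural log is used
throughout so that "B points double the odds" is exact: with
un-rounded category scores, odds(s+pdo)/odds(s) = exp(pdo/B) = 2 to
machine precision.  With rounded points the per-variable error is at
most 0.5 points, bounding the total deviation by half the number of
variables — asserted in the tests.

The intercept is *not* distributed into category points; it is stored
in the model and used only for probability conversion
p = 1/(1+exp(−((s−A)/B + β₀))).  An option adds round(B·β₀) to every
total for cross-population base-risk comparisons.

## Evaluation

- Thresholds: predictions are positive iff score ≥ t; every integer t
  from min(score) to max(score)+1 is swept and the F_β-maximizing t is
  returned, ties resolved toward the *lowest* threshold (the F_β curve
  is flat-topped on the low side in rare-event data, and a lower
  threshold is the safer operating point).
- F_β uses β = 10 by default; the implied FN:FP cost ratio is β² = 100,
  verified in the tests through the gradient identity on 1/F_β.
- AUC is the Mann–Whitney rank statistic with midrank tie correction
  (scikit-learn's implementation), checked against an O(n²) pairwise
  oracle.
- Distribution overlap is computed on the discrete integer score grid,
  Σ_s min(f̂₁, f̂₀) — exactly reproducible, symmetric, translation
  invariant, and the discrete analogue of the density-overlap area.
- The allocation experiment draws the random-targeting recall from the
  exact hypergeometric distribution of event counts in a uniform
  without-replacement sample (equivalent in distribution to sampling
  patients, and O(1) per draw), 100 replications by default, with a
  single seed controlling all replications.  Risk-based targeting
  takes the top ⌈qn⌉ scores with stable tie-breaking.  The area
  between the curves uses the trapezoid rule on a 0.01-step fraction
  grid.

## Synthetic cohorts

The generator emulates the statistical shape of administrative-claims
feature tables: ordered age bands over an elderly population, a ~77%
female majority, binary comorbidity and utilization flags, and
zero-inflated lognormal 6-month cost variables (a point mass at zero
plus a heavy right tail).  Outcomes are Bernoulli draws from a known
logistic model; the intercept is calibrated by bisection so the
*expected* prevalence equals the target exactly (empirical prevalence
then fluctuates within binomial error, which is what the tests check).
Cost effects enter the logit as coef·log1p(cost)/ln 10, i.e. per
decade of spending, making a monotone ground-truth effect that the
binning stage should recover.

The ready-made cohorts fix the study conditions used throughout the
tests: `make_claims_like_cohort` (demo marginals, prevalence 0.007) and
`make_recovery_cohort` (3 strong effects — a binary flag at +1.1, an
ordered band at +0.35/level, a cost effect at −0.55/decade — among 30
variables, n = 100,000, prevalence 0.007).  Effect sizes were chosen
once as plausibly strong clinical signals and are not tuned.

What the generator does *not* emulate: repeated patient-months from
the same beneficiary (rows are independent), temporal rolling-window
structure, and real between-variable correlation.  Passing tests
therefore demonstrate correctness of the pipeline and recoverability
of known signals under realistic marginals and imbalance — not
real-data predictive performance.

Determinism: a single integer seed fully determines a cohort through
`numpy.random.default_rng`; the draw order is part of the generator
contract (versioned in `GENERATOR_VERSION`).

## Problem sizes

The default test suite runs cohorts of 5,000–200,000 rows and
completes in well under a minute; the acceptance checks use the full
n = 100,000, 30-variable recovery design, 50 random threshold
instances up to n = 10,000, O(n²) AUC oracles up to n = 2,000 and
exhaustive binning enumeration up to 8 pre-bins — sizes at which the
exhaustive oracles are still exact yet the asymptotic behaviour of the
estimators is visible.

## Known limitations

- The greedy merge is near-optimal but not provably optimal; optimal
  monotone binning (e.g. via integer programming) is out of scope.
- LASSO path granularity means the selected feature count can land
  below the budget rather than exactly on it.
- Scores are modelled as exchangeable rows; panel structure
  (patient-month repeats) would require clustered standard errors and
  is not implemented.
- The intercept calibration targets expected prevalence; at small n
  the realized prevalence can deviate noticeably (binomial noise).
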