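"""Synthetic claims-like cohorts with known ground truth.

Real administrative-claims tables for rare hospitalization outcomes are
not shareable, so every stage of the package is exercised on generated
cohorts that mimic their statistical shape: a rare binary outcome
(prevalence ~0.5-0.7% by default), zero-inflated right-skewed cost
variables, ordered demographic categories, and binary clinical-history
flags.  Outcomes are drawn from a known logistic model whose intercept
is calibrated by bisection so the expected prevalence hits the target,
which makes end-to-end parameter-recovery checks possible.

Rows are treated as independent observation units; the repeated
patient-month structure of real claims panels is not simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .data_model import BINARY, CATEGORICAL, CONTINUOUS, Dataset, VariableSpec

GENERATOR_VERSION = "1.0"  # bump if the draw order or templates change


# ---------------------------------------------------------------------
# variable templates


@dataclass(frozen=True)
class BinaryFlag:
    """Bernoulli clinical-history flag with marginal ``p``; contributes
    ``coef`` to the logit when the flag is 1."""

    name: str
    p: float
    coef: float = 0.0


@dataclass(frozen=True)
class OrderedCategory:
    """Ordered categorical (e.g. age bands) with stated level
    frequencies; level i contributes ``i * coef_per_level`` to the
    logit."""

    name: str
    levels: tuple
    probs: tuple
    coef_per_level: float = 0.0


@dataclass(frozen=True)
class ZeroInflatedCost:
    """Cost variable: 0 with probability ``zero_mass``, else
    LogNormal(log_mean, log_sd).  The logit contribution is
    ``coef * log1p(cost) / log_scale`` so the effect is monotone in
    cost and ``coef`` is per roughly one decade of spending."""

    name: str
    zero_mass: float
    log_mean: float
    log_sd: float
    coef: float = 0.0
    log_scale: float = np.log(10.0)


Template = BinaryFlag | OrderedCategory | ZeroInflatedCost


@dataclass
class GeneratorConfig:
    """Everything that determines a generated cohort.

    The seed fully determines the output; ``n_null_flags`` appends that
    many zero-coefficient binary noise variables (marginals cycling
    through 0.1..0.5).
    """

    n: int = 100_000
    prevalence_target: float = 0.007
    templates: list = field(default_factory=list)
    n_null_flags: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.prevalence_target < 1):
            raise ValueError("prevalence_target must be in (0, 1)")
        if self.n < 1:
            raise ValueError("n must be >= 1")


def _draw_column(t: Template, n: int, rng: np.random.Generator):
    """Returns (values for the table, logit contribution, VariableSpec)."""
    if isinstance(t, BinaryFlag):
        v = (rng.random(n) < t.p).astype(int)
        return v, t.coef * v, VariableSpec(t.name, BINARY)
    if isinstance(t, OrderedCategory):
        idx = rng.choice(len(t.levels), size=n, p=np.asarray(t.probs) / np.sum(t.probs))
        values = pd.Categorical.from_codes(idx, categories=list(t.levels), ordered=True)
        return values, t.coef_per_level * idx, VariableSpec(t.name, CATEGORICAL, ordered=True)
    if isinstance(t, ZeroInflatedCost):
        zero = rng.random(n) < t.zero_mass
        v = np.where(zero, 0.0, rng.lognormal(t.log_mean, t.log_sd, size=n))
        eta = t.coef * np.log1p(v) / t.log_scale
        return np.round(v, 2), eta, VariableSpec(t.name, CONTINUOUS)
    raise TypeError(f"unknown template type {type(t).__name__}")


def calibrate_intercept(eta: np.ndarray, target: float) -> float:
    """Intercept b0 with mean(expit(b0 + eta)) == target, by bisection."""
    f = lambda b0: float(np.mean(expit(b0 + eta))) - target
    lo, hi = -50.0, 50.0
    if f(lo) > 0 or f(hi) < 0:
        raise ValueError(
            f"target prevalence {target} not achievable by intercept shift"
        )
    return float(brentq(f, lo, hi, xtol=1e-12))


def generate(config: GeneratorConfig) -> tuple[Dataset, dict]:
    """Draw a cohort from the configured logistic model.

    Returns the Dataset and a ground-truth dict holding the calibrated
    intercept, the linear predictor eta (without intercept), and the
    per-variable coefficient map -- the material end-to-end recovery
    tests compare against.
    """
    rng = np.random.default_rng(config.seed)
    templates = list(config.templates)
    for i in range(config.n_null_flags):
        templates.append(BinaryFlag(f"null_flag_{i:02d}", p=0.1 + 0.1 * (i % 5), coef=0.0))
    if not templates:
        raise ValueError("no variable templates configured")

    cols, specs = {}, []
    eta = np.zeros(config.n)
    coef_map = {}
    for t in templates:
        v, contrib, spec = _draw_column(t, config.n, rng)
        cols[spec.name] = v
        specs.append(spec)
        eta = eta + contrib
        coef = t.coef_per_level if isinstance(t, OrderedCategory) else t.coef
        coef_map[spec.name] = coef

    b0 = calibrate_intercept(eta, config.prevalence_target)
    y = (rng.random(config.n) < expit(b0 + eta)).astype(int)
    frame = pd.DataFrame(cols)
    frame["outcome"] = y
    truth = {
        "intercept": b0,
        "eta": eta,
        "coefficients": coef_map,
        "true_variables": [k for k, c in coef_map.items() if c != 0],
        "generator_version": GENERATOR_VERSION,
    }
    return Dataset(frame, "outcome", variables=specs), truth


# ---------------------------------------------------------------------
# ready-made cohorts


#: age-band frequencies typical of an elderly fee-for-service population
AGE_BANDS = ("<65", "65-69", "70-74", "75-79", "80-84", ">84")
AGE_PROBS = (0.008, 0.113, 0.146, 0.173, 0.212, 0.348)


def claims_like_templates() -> list[Template]:
    """Claims-like template set: elderly demographics (77% female),
    common comorbidity flags, recent ICU/CCU utilization, and
    zero-inflated 6-month cost variables.  Lower recent spending and
    ICU admission raise risk, echoing the risk factors such cohorts
    exhibit."""
    return [
        OrderedCategory("age_band", AGE_BANDS, AGE_PROBS, coef_per_level=0.08),
        BinaryFlag("female", p=0.769, coef=0.10),
        BinaryFlag("diabetes", p=0.423, coef=0.15),
        BinaryFlag("cognitive_disorder", p=0.562, coef=0.45),
        BinaryFlag("heart_disease", p=0.936, coef=0.05),
        BinaryFlag("icu_last_3m", p=0.08, coef=0.80),
        BinaryFlag("ccu_last_3m", p=0.06, coef=0.55),
        BinaryFlag("uti_history_6m", p=0.30, coef=0.35),
        ZeroInflatedCost("inpatient_cost_6m", zero_mass=0.55, log_mean=8.5, log_sd=1.2, coef=-0.25),
        ZeroInflatedCost("carrier_cost_6m", zero_mass=0.10, log_mean=6.5, log_sd=1.1, coef=-0.15),
        ZeroInflatedCost("outpatient_cost_6m", zero_mass=0.30, log_mean=7.0, log_sd=1.3, coef=0.0),
    ]


def make_claims_like_cohort(seed: int, n: int = 50_000, prevalence: float = 0.007) -> Dataset:
    """Fixed-template demo cohort (claims-like marginals, rare outcome).

    Intended for demos and integration tests, not numerical
    reproduction of any real-data analysis.
    """
    cfg = GeneratorConfig(
        n=n, prevalence_target=prevalence, templates=claims_like_templates(), seed=seed
    )
    d, _ = generate(cfg)
    return d


def make_recovery_cohort(
    seed: int,
    n: int = 100_000,
    prevalence: float = 0.007,
    n_variables: int = 30,
) -> tuple[Dataset, dict]:
    """Benchmark cohort for parameter recovery: 3 strong true effects
    (a binary flag, an ordered demographic, a zero-inflated cost)
    hidden among ``n_variables - 3`` null variables of mixed types."""
    if n_variables < 3:
        raise ValueError("need at least the 3 true-effect variables")
    templates: list[Template] = [
        BinaryFlag("true_flag", p=0.25, coef=1.1),
        OrderedCategory("true_band", AGE_BANDS, AGE_PROBS, coef_per_level=0.35),
        ZeroInflatedCost("true_cost", zero_mass=0.45, log_mean=8.0, log_sd=1.2, coef=-0.55),
    ]
    n_null = n_variables - 3
    n_null_cat = n_null // 3
    n_null_cost = n_null // 3
    n_null_flags = n_null - n_null_cat - n_null_cost
    for i in range(n_null_cat):
        templates.append(
            OrderedCategory(f"null_band_{i:02d}", AGE_BANDS, AGE_PROBS, coef_per_level=0.0)
        )
    for i in range(n_null_cost):
        templates.append(
            ZeroInflatedCost(f"null_cost_{i:02d}", zero_mass=0.4, log_mean=7.0, log_sd=1.2, coef=0.0)
        )
    cfg = GeneratorConfig(
        n=n,
        prevalence_target=prevalence,
        templates=templates,
        n_null_flags=n_null_flags,
        seed=seed,
    )
    return generate(cfg)
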