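"""Credit-scorecard construction with points-to-double-the-odds scaling.

Each variable is binned with monotone WOE, its values are replaced by
the bin WOE, variables are shortlisted by information value and a
LASSO-constrained logistic regression is fit on the WOE-transformed
table.  The total score is an affine map of the log-odds,
``S = A + B log(odds)``, where ``B = pdo / ln 2`` so that adding
``pdo`` points exactly doubles the odds, and ``A`` shifts the scale
(0 by default).  The integer points of category j of variable k are

    s_kj = round(B * beta_k * WOE_kj).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .binning import BinningConfig, BinningScheme, apply_binning, fit_all_bins
from .data_model import Dataset
from .integerized import fit_sparse_logistic, round_half_away


def woe_transform(
    d: Dataset | pd.DataFrame, schemes: Mapping[str, BinningScheme]
) -> pd.DataFrame:
    """Replace each raw value by the WOE of its bin (one numeric column
    per scheme variable)."""
    frame = d.frame if isinstance(d, Dataset) else d
    out = {}
    for var, scheme in schemes.items():
        if var not in frame.columns:
            raise KeyError(f"variable {var!r} has a scheme but is absent from data")
        idx = apply_binning(scheme, frame[var])
        woes = np.array([b.woe for b in scheme.bins])
        out[var] = woes[idx]
    return pd.DataFrame(out, index=frame.index)


def select_by_iv(schemes: Mapping[str, BinningScheme], top_m: int) -> list[str]:
    """Names of the ``top_m`` variables by information value, descending;
    ties broken lexicographically for determinism."""
    if top_m < 1:
        raise ValueError("top_m must be >= 1")
    ranked = sorted(schemes, key=lambda k: (-schemes[k].iv, k))
    if len(ranked) < top_m:
        warnings.warn(
            f"only {len(ranked)} variables available (top_m={top_m}); returning all",
            stacklevel=2,
        )
        return ranked
    return ranked[:top_m]


def compute_offset_factor(s0: float, theta0: float, pdo: float) -> tuple[float, float]:
    """Solve ``S0 = A + B ln(theta0)`` and ``S0 + pdo = A + B ln(2 theta0)``.

    Returns ``(A, B)`` with ``B = pdo / ln 2`` and
    ``A = S0 - ln(theta0) * B``; A is 0 whenever ``S0 = ln(theta0) B``.
    """
    if pdo <= 0:
        raise ValueError("pdo must be positive")
    if theta0 <= 0:
        raise ValueError("theta0 must be positive")
    B = pdo / math.log(2.0)
    A = s0 - math.log(theta0) * B
    return A, B


@dataclass
class ScorecardModel:
    """Integer points per category of each selected variable."""

    schemes: dict[str, BinningScheme]  # selected variables only
    coefficients: dict[str, float]  # WOE-space slope per variable
    intercept: float
    offset_A: float
    factor_B: float
    pdo: float

    @property
    def variables(self) -> list[str]:
        return list(self.schemes.keys())

    def category_points_raw(self, var: str) -> np.ndarray:
        """Un-rounded per-bin scores ``B * beta_k * WOE_kj``."""
        beta = self.coefficients[var]
        return self.factor_B * beta * np.array([b.woe for b in self.schemes[var].bins])

    def category_points(self, var: str) -> np.ndarray:
        return round_half_away(self.category_points_raw(var))

    def score(self, x: Mapping | pd.Series, rounded: bool = True):
        """Total score of one raw observation: each variable contributes
        the points of the single bin containing its value."""
        frame = pd.DataFrame({k: [x[k]] for k in self.variables})
        return (self.score_frame(frame, rounded=rounded))[0]

    def score_frame(self, d: Dataset | pd.DataFrame, rounded: bool = True) -> np.ndarray:
        frame = d.frame if isinstance(d, Dataset) else d
        total = np.zeros(len(frame))
        for var in self.variables:
            if var not in frame.columns:
                raise KeyError(f"variable {var!r} missing from input")
            idx = apply_binning(self.schemes[var], frame[var])
            pts = self.category_points(var) if rounded else self.category_points_raw(var)
            total = total + pts[idx]
        return total.astype(int) if rounded else total

    def score_to_probability(self, s, rounded_intercept_shift: bool = False):
        """``p = 1 / (1 + exp(-((s - A)/B + beta_0)))``.

        With the default ``A = 0`` the score is used as-is; a non-zero
        offset is removed before the log-odds conversion.
        """
        s = np.asarray(s, dtype=float)
        p = 1.0 / (1.0 + np.exp(-((s - self.offset_A) / self.factor_B + self.intercept)))
        return float(p) if p.ndim == 0 else p

    def to_table(self) -> pd.DataFrame:
        """Long-format scorecard: (variable, category, lower, upper, woe, points)."""
        rows = []
        for var in self.variables:
            pts = self.category_points(var)
            for b, p in zip(self.schemes[var].bins, pts):
                rows.append(
                    {
                        "variable": var,
                        "category": b.label,
                        "lower": b.lower,
                        "upper": b.upper,
                        "woe": b.woe,
                        "points": int(p),
                    }
                )
        return pd.DataFrame(rows)

    def score_range(self) -> tuple[int, int]:
        """Column-wise (sum of per-variable min points, sum of max points)."""
        lo = sum(int(self.category_points(v).min()) for v in self.variables)
        hi = sum(int(self.category_points(v).max()) for v in self.variables)
        return lo, hi

    # -- serialization ----------------------------------------------
    def to_dict(self) -> dict:
        return {
            "kind": "scorecard",
            "schemes": {k: s.to_dict() for k, s in self.schemes.items()},
            "coefficients": self.coefficients,
            "intercept": self.intercept,
            "offset_A": self.offset_A,
            "factor_B": self.factor_B,
            "pdo": self.pdo,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScorecardModel":
        return cls(
            schemes={k: BinningScheme.from_dict(v) for k, v in d["schemes"].items()},
            coefficients={k: float(v) for k, v in d["coefficients"].items()},
            intercept=float(d["intercept"]),
            offset_A=float(d["offset_A"]),
            factor_B=float(d["factor_B"]),
            pdo=float(d["pdo"]),
        )


def assign_points(
    intercept: float,
    coefficients: Mapping[str, float],
    schemes: Mapping[str, BinningScheme],
    offset_A: float,
    factor_B: float,
    pdo: float,
) -> ScorecardModel:
    """Build the scorecard from a WOE-space logistic fit.

    Variables with a zero coefficient are excluded from the card; the
    intercept is kept for probability conversion but not distributed
    into category points.
    """
    kept = {k: float(b) for k, b in coefficients.items() if b != 0.0}
    return ScorecardModel(
        schemes={k: schemes[k] for k in kept},
        coefficients=kept,
        intercept=float(intercept),
        offset_A=float(offset_A),
        factor_B=float(factor_B),
        pdo=float(pdo),
    )


def fit_scorecard(
    d: Dataset,
    top_iv: int = 15,
    max_features: int = 10,
    pdo: float = 10.0,
    offset: float = 0.0,
    config: BinningConfig | None = None,
    refit: bool = True,
) -> ScorecardModel:
    """Full pipeline: monotone binning, IV shortlist of ``top_iv``
    variables, LASSO down to at most ``max_features``, then integer
    points via the (A, B) points-to-double-odds scaling."""
    schemes = fit_all_bins(d, config)
    shortlist = select_by_iv(schemes, top_iv)
    W = woe_transform(d, {k: schemes[k] for k in shortlist})
    intercept, betas = fit_sparse_logistic(W, d.outcome, max_features=max_features, refit=refit)
    B = pdo / math.log(2.0)
    return assign_points(intercept, betas, schemes, offset_A=offset, factor_B=B, pdo=pdo)


def save_model(model: ScorecardModel, path: str | Path, meta: dict | None = None) -> None:
    payload = model.to_dict()
    if meta:
        payload["meta"] = meta
    Path(path).write_text(json.dumps(payload, indent=1))
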