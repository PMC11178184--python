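"""Integer scoring tables from a sparse logistic regression.

The construction scales the logistic coefficients by ``c = |b0| * a``
and rounds them to integers, so a patient's risk score is a small
integer sum over binary features.  The positive constant ``a`` starts
at the power of ten matching the coefficient-to-intercept magnitude
ratio and is halved until the total-score range ``R = S_max - S_min``
reaches a requested minimum ``R*``, which lets the modeller trade
coarseness of the table against a desired score resolution.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression

from .binning import BinningConfig, BinningScheme, apply_binning, fit_all_bins
from .data_model import Dataset


def round_half_away(x) -> np.ndarray | int:
    """Round to nearest integer, ties away from zero (0.5 -> 1, -0.5 -> -1)."""
    arr = np.sign(x) * np.floor(np.abs(x) + 0.5)
    if np.isscalar(x):
        return int(arr)
    return arr.astype(int)


def fit_sparse_logistic(
    X: pd.DataFrame,
    y: np.ndarray,
    max_features: int = 10,
    refit: bool = True,
    c_grid: Sequence[float] | None = None,
) -> tuple[float, dict[str, float]]:
    """L1-constrained logistic fit keeping at most ``max_features`` slopes.

    The penalty strength is the weakest on a logarithmic path whose
    non-zero slope count is <= ``max_features``; by default the model is
    then refit without penalty on the selected features so the reported
    coefficients are not shrunken.

    Returns ``(intercept, {feature: coefficient})`` with only the
    non-zero slopes included.
    """
    y = np.asarray(y)
    if y.sum() == 0:
        raise ValueError("no events in training data")
    if max_features < 1:
        raise ValueError("max_features must be >= 1")
    if c_grid is None:
        c_grid = np.logspace(-4, 2, 25)
    Xv = X.to_numpy(dtype=float)
    cols = list(X.columns)

    # walk the path from the strongest penalty up; the non-zero count grows
    # along the way, so the last C satisfying the budget is the weakest
    # admissible penalty and the scan can stop at the first violation
    selected: list[int] = []
    coefs = None
    intercept = float(np.log(y.mean() / (1 - y.mean())))
    for C in c_grid:
        lasso = LogisticRegression(
            l1_ratio=1.0, C=float(C), solver="liblinear", max_iter=200, tol=1e-6
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            lasso.fit(Xv, y)
        nz = np.flatnonzero(np.abs(lasso.coef_[0]) > 1e-10)
        if len(nz) > max_features:
            break
        selected = list(nz)
        coefs = lasso.coef_[0]
        intercept = float(lasso.intercept_[0])
    if not selected and np.any(np.abs(lasso.coef_[0]) > 1e-10):
        # the non-zero count jumped past the budget in one path step
        # (e.g. collinear copies entering together): keep the largest
        # |coefficient| features of that fit
        selected = list(np.argsort(-np.abs(lasso.coef_[0]))[:max_features])
        coefs = lasso.coef_[0]
        intercept = float(lasso.intercept_[0])

    if not selected:
        p = y.mean()
        return float(np.log(p / (1 - p))), {}

    if refit:
        ml = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=2000, tol=1e-8)
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            ml.fit(Xv[:, selected], y)
        if any(issubclass(w.category, ConvergenceWarning) for w in caught) or np.max(
            np.abs(ml.coef_)
        ) > 30:
            warnings.warn(
                "possible separation or non-convergence in unpenalized refit; "
                "coefficients capped at the final iterate",
                stacklevel=2,
            )
        intercept = float(ml.intercept_[0])
        betas = {cols[j]: float(b) for j, b in zip(selected, ml.coef_[0])}
    else:
        betas = {cols[j]: float(coefs[j]) for j in selected}
    return intercept, betas


def init_scale(intercept: float, betas: Mapping[str, float]) -> float:
    """Initial ``a = 10^floor(log10(max_i |beta_i / beta_0|))``.

    ``a`` is the power of ten capturing the order-of-magnitude gap
    between the largest slope and the intercept, so only features with
    a sizeable contribution survive the rounding.
    """
    if intercept == 0:
        raise ValueError("intercept is zero; scaling factor undefined")
    nonzero = [abs(b) for b in betas.values() if b != 0]
    if not nonzero:
        raise ValueError("all slopes are zero; nothing to score")
    ratio = max(nonzero) / abs(intercept)
    return 10.0 ** math.floor(math.log10(ratio))


@dataclass
class IntegerizedModel:
    """Integer points per binary feature plus the scaling needed to map
    a total score back to a probability."""

    features: list[str]
    points: dict[str, int]
    intercept_points: int
    scale_c: float
    a: float
    intercept: float  # un-rounded beta_0, kept for optional exact conversion
    score_range: tuple[int, int]
    coefficients: dict[str, float] | None = None  # pre-rounding slopes
    range_warning: bool = False
    schemes: dict[str, BinningScheme] | None = None
    feature_bins: dict[str, tuple[str, int]] | None = None  # feature -> (variable, bin idx)

    def score(self, x: Mapping[str, int] | pd.Series) -> int:
        """Integer dot product of points with a 0/1 feature vector."""
        total = 0
        for f in self.features:
            if f not in x:
                raise KeyError(f"feature {f!r} missing from input")
            total += self.points[f] * int(x[f])
        return total

    def score_to_probability(self, s, rounded_intercept: bool = True):
        """``p = 1 / (1 + exp(-c (s + b0')))`` -- strictly increasing in s.

        With ``rounded_intercept=False`` the exact ``beta_0 / c`` is used
        in place of the integer intercept points.
        """
        b0 = self.intercept_points if rounded_intercept else self.intercept / self.scale_c
        s = np.asarray(s, dtype=float)
        p = 1.0 / (1.0 + np.exp(-self.scale_c * (s + b0)))
        return float(p) if p.ndim == 0 else p

    def encode(self, d: Dataset | pd.DataFrame) -> pd.DataFrame:
        """Dummy-encode raw observations into this model's features."""
        if self.schemes is None or self.feature_bins is None:
            raise ValueError("model carries no binning schemes; pass encoded features")
        frame = d.frame if isinstance(d, Dataset) else d
        out = {}
        for f in self.features:
            var, j = self.feature_bins[f]
            idx = apply_binning(self.schemes[var], frame[var])
            out[f] = (idx == j).astype(int)
        return pd.DataFrame(out, index=frame.index)

    def score_frame(self, d: Dataset | pd.DataFrame) -> np.ndarray:
        enc = self.encode(d)
        pts = np.array([self.points[f] for f in self.features])
        return enc.to_numpy() @ pts

    # -- serialization ----------------------------------------------
    def to_dict(self) -> dict:
        return {
            "kind": "integerized",
            "features": self.features,
            "points": self.points,
            "intercept_points": self.intercept_points,
            "scale_c": self.scale_c,
            "a": self.a,
            "intercept": self.intercept,
            "score_range": list(self.score_range),
            "coefficients": self.coefficients,
            "range_warning": self.range_warning,
            "schemes": None
            if self.schemes is None
            else {k: s.to_dict() for k, s in self.schemes.items()},
            "feature_bins": None
            if self.feature_bins is None
            else {k: list(v) for k, v in self.feature_bins.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "IntegerizedModel":
        return cls(
            features=list(d["features"]),
            points={k: int(v) for k, v in d["points"].items()},
            intercept_points=int(d["intercept_points"]),
            scale_c=float(d["scale_c"]),
            a=float(d["a"]),
            intercept=float(d["intercept"]),
            score_range=tuple(d["score_range"]),
            coefficients=None
            if d.get("coefficients") is None
            else {k: float(v) for k, v in d["coefficients"].items()},
            range_warning=bool(d.get("range_warning", False)),
            schemes=None
            if d.get("schemes") is None
            else {k: BinningScheme.from_dict(v) for k, v in d["schemes"].items()},
            feature_bins=None
            if d.get("feature_bins") is None
            else {k: (v[0], int(v[1])) for k, v in d["feature_bins"].items()},
        )

    def to_table(self) -> pd.DataFrame:
        """Two-column scoring table (feature, score)."""
        return pd.DataFrame(
            {"feature": self.features, "score": [self.points[f] for f in self.features]}
        )


def score_range_of(points: Mapping[str, int]) -> tuple[int, int]:
    """(S_min, S_max) over all 0/1 feature settings."""
    s_min = sum(min(0, p) for p in points.values())
    s_max = sum(max(0, p) for p in points.values())
    return int(s_min), int(s_max)


def integerize(
    intercept: float,
    betas: Mapping[str, float],
    r_star: int = 10,
    max_halvings: int = 20,
) -> IntegerizedModel:
    """Scale and round coefficients, halving ``a`` until the score range
    ``R = S_max - S_min`` is at least ``r_star``.

    Features whose points round to zero are dropped from the table
    (their contribution to every total is zero).
    """
    if r_star < 1:
        raise ValueError("r_star must be >= 1")
    a = init_scale(intercept, betas)
    halvings = 0
    warned = False
    while True:
        c = abs(intercept) * a
        pts = {k: round_half_away(b / c) for k, b in betas.items()}
        s_min, s_max = score_range_of(pts)
        if s_max - s_min >= r_star:
            break
        if halvings >= max_halvings:
            warnings.warn(
                f"max_halvings={max_halvings} exhausted with range "
                f"{s_max - s_min} < R*={r_star}",
                stacklevel=2,
            )
            warned = True
            break
        a /= 2.0
        halvings += 1
    pts = {k: v for k, v in pts.items() if v != 0}
    return IntegerizedModel(
        features=list(pts.keys()),
        points=pts,
        intercept_points=round_half_away(intercept / c),
        scale_c=c,
        a=a,
        intercept=intercept,
        score_range=score_range_of(pts),
        coefficients={k: float(betas[k]) for k in pts},
        range_warning=warned,
    )


def dummy_encode(
    d: Dataset, schemes: Mapping[str, BinningScheme]
) -> tuple[pd.DataFrame, dict[str, tuple[str, int]]]:
    """One 0/1 column per non-reference bin of every variable.

    The reference (dropped) category is the lowest-WOE bin, so points
    measure added risk relative to the safest group.
    """
    cols = {}
    feature_bins: dict[str, tuple[str, int]] = {}
    for var, scheme in schemes.items():
        idx = apply_binning(scheme, d.frame[var])
        if len(scheme.bins) < 2:
            continue
        ref = int(np.argmin([b.woe for b in scheme.bins]))
        for j, b in enumerate(scheme.bins):
            if j == ref:
                continue
            name = f"{var}={b.label}"
            cols[name] = (idx == j).astype(int)
            feature_bins[name] = (var, j)
    return pd.DataFrame(cols, index=d.frame.index), feature_bins


def fit_integerized(
    d: Dataset,
    max_features: int = 10,
    r_star: int = 10,
    max_halvings: int = 20,
    config: BinningConfig | None = None,
    refit: bool = True,
) -> IntegerizedModel:
    """Full pipeline: monotone binning, dummy encoding, sparse logistic
    fit, then coefficient integerization."""
    schemes = fit_all_bins(d, config)
    X, feature_bins = dummy_encode(d, schemes)
    intercept, betas = fit_sparse_logistic(X, d.outcome, max_features=max_features, refit=refit)
    model = integerize(intercept, betas, r_star=r_star, max_halvings=max_halvings)
    model.schemes = {var: schemes[var] for var, _ in (feature_bins[f] for f in model.features)}
    model.feature_bins = {f: feature_bins[f] for f in model.features}
    return model


def save_model(model: IntegerizedModel, path: str | Path, meta: dict | None = None) -> None:
    payload = model.to_dict()
    if meta:
        payload["meta"] = meta
    Path(path).write_text(json.dumps(payload, indent=1))
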