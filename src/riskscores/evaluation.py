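"""Threshold selection, classification metrics, score-distribution
overlap, and the intervention-allocation experiment.

All functions operate on integer score vectors and 0/1 outcome vectors;
predictions are positive when ``score >= threshold`` (higher score means
higher risk in both scoring constructions).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score


def f_beta(precision: float, recall: float, beta: float = 10.0) -> float:
    """Fbeta = (1 + b^2) P R / (b^2 P + R); 0 when P = R = 0.

    The implied cost ratio of false negatives to false positives is
    beta^2 (100 for the F10 default), appropriate when missing a rare
    event is far costlier than a spurious alert.
    """
    if beta <= 0:
        raise ValueError("beta must be positive")
    if not (0 <= precision <= 1 and 0 <= recall <= 1):
        raise ValueError("precision and recall must lie in [0, 1]")
    denom = beta**2 * precision + recall
    if denom == 0:
        return 0.0
    return (1 + beta**2) * precision * recall / denom


@dataclass
class EvaluationReport:
    """Confusion counts at a threshold plus the standard metric panel."""

    threshold: int
    tp: int
    fp: int
    tn: int
    fn: int
    auc: float
    recall: float
    precision: float
    f1: float
    f_beta: float
    beta: float
    overlap_ratio: float | None = None
    allocation_area: float | None = None

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def to_dict(self) -> dict:
        return asdict(self)

    def save(self, path: str | Path, meta: dict | None = None) -> None:
        payload = self.to_dict()
        if meta:
            payload["meta"] = meta
        Path(path).write_text(json.dumps(payload, indent=1))


def _confusion(scores: np.ndarray, outcome: np.ndarray, threshold: float):
    pred = scores >= threshold
    tp = int(np.sum(pred & (outcome == 1)))
    fp = int(np.sum(pred & (outcome == 0)))
    fn = int(np.sum(~pred & (outcome == 1)))
    tn = int(np.sum(~pred & (outcome == 0)))
    return tp, fp, tn, fn


def select_threshold(
    scores: Sequence[int], outcome: Sequence[int], beta: float = 10.0
) -> tuple[int, pd.DataFrame]:
    """Sweep every achievable integer threshold and return the one
    maximizing Fbeta (ties toward the lowest threshold) together with
    the full (threshold, precision, recall, f_beta) curve.

    A threshold at the minimum score predicts everyone positive
    (recall 1); one above the maximum predicts everyone negative.
    """
    scores = np.asarray(scores)
    outcome = np.asarray(outcome)
    if len(scores) != len(outcome):
        raise ValueError("scores and outcome must have the same length")
    if outcome.sum() == 0:
        raise ValueError("no events in outcome")
    lo, hi = int(scores.min()), int(scores.max())
    rows = []
    for t in range(lo, hi + 2):  # hi+1 = all-negative boundary
        tp, fp, tn, fn = _confusion(scores, outcome, t)
        p = tp / (tp + fp) if tp + fp else 0.0
        r = tp / (tp + fn)
        rows.append({"threshold": t, "precision": p, "recall": r, "f_beta": f_beta(p, r, beta)})
    curve = pd.DataFrame(rows)
    best = int(curve.loc[curve["f_beta"].idxmax(), "threshold"])  # idxmax -> first max
    return best, curve


def classification_report(
    scores: Sequence[int],
    outcome: Sequence[int],
    threshold: int,
    beta: float = 10.0,
) -> EvaluationReport:
    """Confusion counts at ``threshold`` plus AUC (Mann-Whitney rank
    statistic with midrank tie correction), recall, precision, F1 and
    Fbeta."""
    scores = np.asarray(scores)
    outcome = np.asarray(outcome)
    tp, fp, tn, fn = _confusion(scores, outcome, threshold)
    p = tp / (tp + fp) if tp + fp else 0.0
    r = tp / (tp + fn) if tp + fn else 0.0
    if outcome.min() == outcome.max():
        auc = float("nan")
    else:
        auc = float(roc_auc_score(outcome, scores))
    return EvaluationReport(
        threshold=int(threshold),
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        auc=auc,
        recall=r,
        precision=p,
        f1=f_beta(p, r, 1.0),
        f_beta=f_beta(p, r, beta),
        beta=beta,
    )


def overlap_ratio(scores_event: Sequence[int], scores_nonevent: Sequence[int]) -> float:
    """Overlap of the two per-group score distributions on the common
    integer grid: sum over scores of min(f1, f0) for the normalized
    frequencies.  1 for identical distributions, 0 for disjoint
    supports; symmetric and translation invariant."""
    a = np.asarray(scores_event)
    b = np.asarray(scores_nonevent)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    lo = int(min(a.min(), b.min()))
    hi = int(max(a.max(), b.max()))
    grid = np.arange(lo, hi + 1)
    fa = np.bincount(a - lo, minlength=len(grid)) / len(a)
    fb = np.bincount(b - lo, minlength=len(grid)) / len(b)
    return float(np.minimum(fa, fb).sum())


def allocation_benefit(
    scores: Sequence[int],
    outcome: Sequence[int],
    fractions: Sequence[float] | None = None,
    replications: int = 100,
    seed: int = 0,
) -> tuple[pd.DataFrame, float]:
    """Recall from treating a fraction q of the cohort, random vs
    risk-ranked.

    For each fraction q on the grid: (a) mean recall over
    ``replications`` uniform draws of ceil(q n) patients; (b) recall
    when the ceil(q n) highest-score patients are treated (ties broken
    by stable original order).  Returns the two curves plus the area
    between them by the trapezoid rule.
    """
    scores = np.asarray(scores)
    outcome = np.asarray(outcome)
    n = len(scores)
    n_events = int(outcome.sum())
    if n_events == 0:
        raise ValueError("no events in outcome")
    if replications < 1:
        raise ValueError("replications must be >= 1")
    if fractions is None:
        fractions = np.round(np.arange(0.0, 1.0 + 1e-9, 0.01), 10)
    fractions = np.asarray(fractions, dtype=float)
    rng = np.random.default_rng(seed)

    # stable descending rank: ties keep original order
    order = np.argsort(-scores, kind="stable")
    event_cum = np.concatenate([[0], np.cumsum(outcome[order])])

    random_recall = np.empty(len(fractions))
    risk_recall = np.empty(len(fractions))
    for i, q in enumerate(fractions):
        k = int(np.ceil(q * n))
        risk_recall[i] = event_cum[k] / n_events
        if k == 0:
            random_recall[i] = 0.0
        elif k == n:
            random_recall[i] = 1.0
        else:
            # events in a uniform without-replacement sample of size k
            # are exactly hypergeometric
            hits = rng.hypergeometric(n_events, n - n_events, k, size=replications)
            random_recall[i] = float(hits.mean()) / n_events
    curve = pd.DataFrame(
        {"fraction": fractions, "random_recall": random_recall, "risk_recall": risk_recall}
    )
    area = float(np.trapezoid(risk_recall - random_recall, fractions))
    return curve, area


def evaluate_scores(
    scores: Sequence[int],
    outcome: Sequence[int],
    beta: float = 10.0,
    threshold: int | None = None,
    allocation_seed: int = 0,
    allocation_replications: int = 100,
) -> EvaluationReport:
    """One-stop report: threshold by Fbeta maximization (unless given),
    metric panel, distribution overlap and allocation-curve area."""
    scores = np.asarray(scores)
    outcome = np.asarray(outcome)
    if threshold is None:
        threshold, _ = select_threshold(scores, outcome, beta)
    report = classification_report(scores, outcome, threshold, beta)
    report.overlap_ratio = overlap_ratio(scores[outcome == 1], scores[outcome == 0])
    _, report.allocation_area = allocation_benefit(
        scores, outcome, replications=allocation_replications, seed=allocation_seed
    )
    return report
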