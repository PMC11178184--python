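"""Monotone weight-of-evidence binning and information value.

Continuous variables are pre-split into quantile bins and adjacent bins
are merged greedily until the weight-of-evidence (WOE) sequence is
monotone; categorical levels are ordered (by their natural order, or by
event rate when unordered) and merged the same way.  WOE is oriented so
that a higher value means higher event risk:

    WOE_j = ln[ (e_j / E) / (n_j / N) ]

with e_j, n_j the bin's event / non-event counts and E, N the group
totals; an additive smoothing constant guards against empty cells in
rare-event data.  The information value of a variable is

    IV = sum_j (e_j/E - n_j/N) * WOE_j  >=  0.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
import numpy as np
import pandas as pd
from scipy import stats

from .data_model import BINARY, CATEGORICAL, CONTINUOUS, Dataset, VariableSpec

MISSING_LABEL = "missing"


@dataclass
class BinningConfig:
    """Knobs for :func:`fit_monotone_bins`.

    n_prebins : number of quantile pre-bins for continuous variables.
    min_bin_frac : minimum bin size as a fraction of n.
    min_events : minimum events per bin.
    smoothing : additive smoothing added to each cell count (both
        groups) when computing WOE; 0.5 by default so rare-event bins
        with zero cells stay finite.
    """

    n_prebins: int = 20
    min_bin_frac: float = 0.05
    min_events: int = 1
    smoothing: float = 0.5


@dataclass
class Bin:
    """One category of a binned variable.

    ``lower``/``upper`` are the half-open interval edges for continuous
    variables ([lower, upper), -inf/+inf at the extremes); ``levels``
    is the member-level tuple for categorical variables.
    """

    label: str
    event_count: int
    nonevent_count: int
    woe: float
    lower: float | None = None
    upper: float | None = None
    levels: tuple | None = None
    is_missing: bool = False

    @property
    def count(self) -> int:
        return self.event_count + self.nonevent_count


@dataclass
class BinningScheme:
    """Ordered bins for one variable, with per-bin WOE and total IV."""

    variable: VariableSpec
    bins: list[Bin]
    iv: float
    total_events: int
    total_nonevents: int
    smoothing: float
    direction: int = 1
    warning: str | None = None

    @property
    def ordered_bins(self) -> list[Bin]:
        """Bins participating in the monotone ordering (missing excluded)."""
        return [b for b in self.bins if not b.is_missing]

    def woe_values(self) -> np.ndarray:
        return np.array([b.woe for b in self.bins])

    def to_dict(self) -> dict:
        return {
            "variable": self.variable.name,
            "kind": self.variable.kind,
            "ordered": self.variable.ordered,
            "iv": self.iv,
            "total_events": self.total_events,
            "total_nonevents": self.total_nonevents,
            "smoothing": self.smoothing,
            "direction": self.direction,
            "bins": [
                {
                    "label": b.label,
                    "lower": None if b.lower is None else float(b.lower),
                    "upper": None if b.upper is None else float(b.upper),
                    "levels": None if b.levels is None else list(b.levels),
                    "event_count": b.event_count,
                    "nonevent_count": b.nonevent_count,
                    "woe": b.woe,
                    "is_missing": b.is_missing,
                }
                for b in self.bins
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BinningScheme":
        var = VariableSpec(d["variable"], d["kind"], ordered=d.get("ordered", False))
        bins = [
            Bin(
                label=b["label"],
                event_count=b["event_count"],
                nonevent_count=b["nonevent_count"],
                woe=b["woe"],
                lower=b["lower"] if b["lower"] is None else float(b["lower"]),
                upper=b["upper"] if b["upper"] is None else float(b["upper"]),
                levels=None if b["levels"] is None else tuple(b["levels"]),
                is_missing=b.get("is_missing", False),
            )
            for b in d["bins"]
        ]
        return cls(
            variable=var,
            bins=bins,
            iv=d["iv"],
            total_events=d["total_events"],
            total_nonevents=d["total_nonevents"],
            smoothing=d["smoothing"],
            direction=d.get("direction", 1),
        )

    def to_table(self) -> pd.DataFrame:
        """Human-readable long-format table (one row per category)."""
        return pd.DataFrame(
            {
                "variable": self.variable.name,
                "category": [b.label for b in self.bins],
                "lower": [b.lower for b in self.bins],
                "upper": [b.upper for b in self.bins],
                "events": [b.event_count for b in self.bins],
                "nonevents": [b.nonevent_count for b in self.bins],
                "woe": [b.woe for b in self.bins],
                "iv": self.iv,
            }
        )


def woe(
    event_count: int,
    nonevent_count: int,
    total_events: int,
    total_nonevents: int,
    smoothing: float = 0.0,
) -> float:
    """Weight of evidence of one bin, higher = higher event risk.

    ln[ (e+s)/(E+2s) / ((n+s)/(N+2s)) ] with smoothing s >= 0.  With
    s = 0 a zero cell is an error (the caller should smooth or merge).
    """
    if total_events < 1 or total_nonevents < 1:
        raise ValueError("both groups must contain at least one observation")
    if event_count > total_events or nonevent_count > total_nonevents:
        raise ValueError("bin counts exceed group totals")
    if smoothing < 0:
        raise ValueError("smoothing must be >= 0")
    if smoothing == 0 and (event_count == 0 or nonevent_count == 0):
        raise ValueError(
            "zero cell with smoothing=0: increase smoothing or merge the bin"
        )
    pe = (event_count + smoothing) / (total_events + 2 * smoothing)
    pn = (nonevent_count + smoothing) / (total_nonevents + 2 * smoothing)
    return math.log(pe / pn)


def information_value(scheme: BinningScheme) -> float:
    """IV = sum over bins of (event freq - non-event freq) x WOE; >= 0.

    Uses the same smoothed frequencies as :func:`woe`, so every summand
    has the form (a-b)ln(a/b) >= 0.
    """
    e = np.array([b.event_count for b in scheme.bins], dtype=float)
    n = np.array([b.nonevent_count for b in scheme.bins], dtype=float)
    s = scheme.smoothing
    pe = (e + s) / (scheme.total_events + 2 * s)
    pn = (n + s) / (scheme.total_nonevents + 2 * s)
    w = np.array([b.woe for b in scheme.bins])
    return float(np.sum((pe - pn) * w))


def _woe_from_counts(e, n, E, N, s) -> np.ndarray:
    e = np.asarray(e, dtype=float)
    n = np.asarray(n, dtype=float)
    if s == 0 and (np.any(e == 0) or np.any(n == 0)):
        raise ValueError(
            "zero cell with smoothing=0: increase smoothing or merge the bin"
        )
    return np.log(((e + s) / (E + 2 * s)) / ((n + s) / (N + 2 * s)))


def _iv_from_counts(e, n, E, N, s) -> float:
    e = np.asarray(e, dtype=float)
    n = np.asarray(n, dtype=float)
    w = _woe_from_counts(e, n, E, N, s)
    pe = (e + s) / (E + 2 * s)
    pn = (n + s) / (N + 2 * s)
    return float(np.sum((pe - pn) * w))


# ---------------------------------------------------------------------
# fitting


def fit_monotone_bins(
    d: Dataset, variable: VariableSpec | str, config: BinningConfig | None = None
) -> BinningScheme:
    """Bin one variable so that its WOE sequence is monotone.

    Continuous variables are pre-split into ``config.n_prebins``
    quantile bins; categorical levels are taken in their natural order
    (ordered) or sorted by event rate (unordered).  Adjacent bins are
    then merged greedily -- the violating pair with the smallest
    |delta WOE| first -- until the WOE sequence is monotone in the
    direction of the rank correlation between variable and outcome,
    and until every bin meets the minimum size and event count.
    Missing values, if any, get a dedicated bin outside the ordering.
    """
    config = config or BinningConfig()
    if isinstance(variable, str):
        variable = d.variable(variable)
    values = d.frame[variable.name]
    y = d.outcome
    E = d.n_events
    N = d.n_nonevents
    s = config.smoothing
    min_size = max(1, int(math.ceil(config.min_bin_frac * d.n)))

    miss_mask = values.isna().to_numpy()
    v_obs = values[~miss_mask]
    y_obs = y[~miss_mask]
    warning = None

    if v_obs.nunique() <= 1:
        warnings.warn(
            f"variable {variable.name!r} is constant; returning single-bin scheme",
            stacklevel=2,
        )
        bins = [
            Bin(
                label="all",
                event_count=int(y_obs.sum()),
                nonevent_count=int(len(y_obs) - y_obs.sum()),
                woe=woe(int(y_obs.sum()), int(len(y_obs) - y_obs.sum()), E, N, s)
                if len(y_obs)
                else 0.0,
                lower=-math.inf if variable.kind != CATEGORICAL else None,
                upper=math.inf if variable.kind != CATEGORICAL else None,
                levels=tuple(v_obs.unique()) if variable.kind == CATEGORICAL else None,
            )
        ]
        warning = "constant variable"
        return _finalize(variable, bins, miss_mask, y, E, N, s, 1, warning)

    if variable.kind == CONTINUOUS or variable.kind == BINARY:
        if variable.kind == BINARY:
            groups = v_obs.to_numpy(dtype=float).astype(int)
            edges = np.array([0.0, 0.5, 1.0])
        else:
            groups, edges = _continuous_prebins(v_obs.to_numpy(dtype=float), config.n_prebins)
        e_counts, n_counts = _group_counts(groups, y_obs, len(edges) - 1)
        keep = (e_counts + n_counts) > 0
        edges = _collapse_edges(edges, keep)
        e_counts, n_counts = e_counts[keep], n_counts[keep]
        level_sets = None
        rho = _rank_direction(v_obs.to_numpy(dtype=float), y_obs)
    else:
        levels = _level_order(v_obs, y_obs, variable.ordered)
        idx_of = {lv: i for i, lv in enumerate(levels)}
        groups = v_obs.map(idx_of).to_numpy(dtype=int)
        e_counts, n_counts = _group_counts(groups, y_obs, len(levels))
        level_sets = [(lv,) for lv in levels]
        edges = None
        rho = _rank_direction(groups.astype(float), y_obs)

    direction = 1 if rho >= 0 else -1

    parts = [
        {"e": int(e_counts[i]), "n": int(n_counts[i]), "i0": i, "i1": i}
        for i in range(len(e_counts))
    ]
    parts = _merge_to_monotone(parts, E, N, s, direction)
    parts, size_ok = _merge_small(parts, E, N, s, min_size, config.min_events)
    # size merges can re-break monotonicity at the seams
    parts = _merge_to_monotone(parts, E, N, s, direction)
    if not size_ok and len(parts) == 1:
        warnings.warn(
            f"variable {variable.name!r}: minimum bin sizes not satisfiable; "
            "returning single-bin scheme",
            stacklevel=2,
        )
        warning = "min sizes not satisfiable"

    bins = []
    for p in parts:
        w = woe(p["e"], p["n"], E, N, s)
        if edges is not None:
            lo = -math.inf if p["i0"] == 0 else float(edges[p["i0"]])
            hi = math.inf if p["i1"] + 1 == len(edges) - 1 else float(edges[p["i1"] + 1])
            if variable.kind == BINARY:
                label = "1" if p["i0"] >= 1 else ("0" if p["i1"] == 0 else "0-1")
            else:
                label = _interval_label(lo, hi)
            bins.append(Bin(label=label, event_count=p["e"], nonevent_count=p["n"], woe=w, lower=lo, upper=hi))
        else:
            members = tuple(lv for i in range(p["i0"], p["i1"] + 1) for lv in level_sets[i])
            label = ", ".join(str(m) for m in members)
            bins.append(Bin(label=label, event_count=p["e"], nonevent_count=p["n"], woe=w, levels=members))
    return _finalize(variable, bins, miss_mask, y, E, N, s, direction, warning)


def _finalize(variable, bins, miss_mask, y, E, N, s, direction, warning):
    if miss_mask.any():
        e_m = int(y[miss_mask].sum())
        n_m = int(miss_mask.sum() - e_m)
        bins = bins + [
            Bin(label=MISSING_LABEL, event_count=e_m, nonevent_count=n_m, woe=woe(e_m, n_m, E, N, s), is_missing=True)
        ]
    if len(bins) == 1:
        # the whole-population bin carries no evidence by definition;
        # smoothing would otherwise leave a spurious residue when E != N
        bins[0].woe = 0.0
    scheme = BinningScheme(
        variable=variable,
        bins=bins,
        iv=0.0,
        total_events=E,
        total_nonevents=N,
        smoothing=s,
        direction=direction,
        warning=warning,
    )
    scheme.iv = information_value(scheme)
    return scheme


def _continuous_prebins(v: np.ndarray, n_prebins: int):
    qs = np.quantile(v, np.linspace(0, 1, n_prebins + 1))
    edges = np.unique(qs)
    if len(edges) < 2:
        edges = np.array([v.min(), v.max() + 1.0])
    # interior edges define [lower, upper) intervals; values >= last
    # interior edge fall in the final bin
    interior = edges[1:-1]
    groups = np.searchsorted(interior, v, side="right")
    return groups, edges


def _group_counts(groups: np.ndarray, y: np.ndarray, k: int):
    e = np.bincount(groups, weights=y, minlength=k).astype(int)
    tot = np.bincount(groups, minlength=k).astype(int)
    return e, tot - e


def _collapse_edges(edges: np.ndarray, keep: np.ndarray) -> np.ndarray:
    # empty pre-bins are absorbed into the following kept interval; counts
    # are unaffected because the absorbed region contains no observations
    return np.concatenate([[edges[0]], edges[1:][keep]])


def _rank_direction(v: np.ndarray, y: np.ndarray) -> float:
    with np.errstate(invalid="ignore"):
        rho = stats.spearmanr(v, y).statistic
    if not np.isfinite(rho):
        return 1.0
    return float(rho)


def _level_order(v_obs: pd.Series, y_obs: np.ndarray, ordered: bool):
    if ordered and isinstance(v_obs.dtype, pd.CategoricalDtype):
        return [lv for lv in v_obs.cat.categories if lv in set(v_obs.unique())]
    levels = list(pd.unique(v_obs))
    if ordered:
        return sorted(levels)
    rate = pd.Series(y_obs, index=v_obs.index).groupby(v_obs, observed=True).mean()
    return sorted(levels, key=lambda lv: (rate[lv], str(lv)))


def _merge_to_monotone(parts, E, N, s, direction):
    parts = [dict(p) for p in parts]
    while len(parts) > 1:
        w = _woe_from_counts(
            [p["e"] for p in parts], [p["n"] for p in parts], E, N, s
        )
        viol = [
            (abs(w[i + 1] - w[i]), i)
            for i in range(len(parts) - 1)
            if (w[i + 1] - w[i]) * direction < -1e-12
        ]
        if not viol:
            break
        _, i = min(viol)
        parts[i : i + 2] = [_merge_pair(parts[i], parts[i + 1])]
    return parts


def _merge_small(parts, E, N, s, min_size, min_events):
    parts = [dict(p) for p in parts]
    while len(parts) > 1:
        sizes = [p["e"] + p["n"] for p in parts]
        bad = [
            i
            for i, p in enumerate(parts)
            if sizes[i] < min_size or p["e"] < min_events
        ]
        if not bad:
            return parts, True
        i = bad[0]
        w = _woe_from_counts([p["e"] for p in parts], [p["n"] for p in parts], E, N, s)
        if i == 0:
            j = 1
        elif i == len(parts) - 1:
            j = i - 1
        else:
            j = i - 1 if abs(w[i - 1] - w[i]) <= abs(w[i + 1] - w[i]) else i + 1
        lo, hi = min(i, j), max(i, j)
        parts[lo : hi + 1] = [_merge_pair(parts[lo], parts[hi])]
    p = parts[0]
    return parts, (p["e"] + p["n"] >= min_size and p["e"] >= min_events)


def _merge_pair(a, b):
    return {"e": a["e"] + b["e"], "n": a["n"] + b["n"], "i0": a["i0"], "i1": b["i1"]}


def _interval_label(lo: float, hi: float) -> str:
    fmt = lambda x: "-inf" if x == -math.inf else ("inf" if x == math.inf else f"{x:g}")
    return f"[{fmt(lo)}, {fmt(hi)})"


# ---------------------------------------------------------------------
# applying


def apply_binning(scheme: BinningScheme, values: pd.Series | np.ndarray) -> np.ndarray:
    """Map each value to the index of its bin in ``scheme.bins``.

    Continuous values outside the fitted range are clamped to the first
    or last ordered bin; unseen categorical levels go to the bin whose
    WOE is nearest 0 (logged); missing values go to the missing bin if
    one exists, otherwise to the nearest-zero-WOE bin.
    """
    values = pd.Series(values)
    ordered = scheme.ordered_bins
    bin_index = {id(b): i for i, b in enumerate(scheme.bins)}
    miss_idx = next(
        (i for i, b in enumerate(scheme.bins) if b.is_missing), None
    )
    neutral_idx = min(
        range(len(scheme.bins)),
        key=lambda i: (abs(scheme.bins[i].woe), i),
    )
    out = np.empty(len(values), dtype=int)
    isna = values.isna().to_numpy()
    out[isna] = miss_idx if miss_idx is not None else neutral_idx

    if len(ordered) == 1:
        out[~isna] = bin_index[id(ordered[0])]
        return out

    if ordered[0].levels is None:
        # continuous / binary: half-open [lower, upper), clamped
        uppers = np.array([b.upper for b in ordered[:-1]], dtype=float)
        v = pd.to_numeric(values[~isna]).to_numpy(dtype=float)
        pos = np.searchsorted(uppers, v, side="right")
        out[~isna] = np.array([bin_index[id(ordered[p])] for p in pos])
    else:
        lookup = {}
        for b in scheme.bins:
            if b.levels is not None:
                for lv in b.levels:
                    lookup[lv] = bin_index[id(b)]
        mapped = values[~isna].map(lambda lv: lookup.get(lv, -1)).to_numpy()
        unseen = mapped == -1
        if unseen.any():
            import logging

            logging.getLogger(__name__).info(
                "variable %r: %d unseen level(s) mapped to neutral bin",
                scheme.variable.name,
                int(unseen.sum()),
            )
            mapped[unseen] = neutral_idx
        out[~isna] = mapped
    return out


def fit_all_bins(
    d: Dataset, config: BinningConfig | None = None
) -> dict[str, BinningScheme]:
    """Fit monotone binning schemes for every predictor in the dataset."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return {v.name: fit_monotone_bins(d, v, config) for v in d.variables}


def save_schemes(schemes: dict[str, BinningScheme], path: str | Path) -> None:
    Path(path).write_text(
        json.dumps({k: s.to_dict() for k, s in schemes.items()}, indent=1)
    )


def load_schemes(path: str | Path) -> dict[str, BinningScheme]:
    raw = json.loads(Path(path).read_text())
    return {k: BinningScheme.from_dict(v) for k, v in raw.items()}
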