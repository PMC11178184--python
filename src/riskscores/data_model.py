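"""Tabular containers and delimited-file I/O shared by all modules.

A :class:`Dataset` is a thin wrapper around a :class:`pandas.DataFrame`
holding mixed binary / continuous / categorical predictors and a single
binary outcome column (1 = event).  Variable kinds are either supplied
explicitly as a list of :class:`VariableSpec` or inferred from the data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

BINARY = "binary"
CONTINUOUS = "continuous"
CATEGORICAL = "categorical"
KINDS = (BINARY, CONTINUOUS, CATEGORICAL)

# accepted string spellings for binary cells, case-insensitive
_TRUE = {"1", "true", "t", "yes"}
_FALSE = {"0", "false", "f", "no"}


@dataclass(frozen=True)
class VariableSpec:
    """Name and measurement kind of one predictor column.

    Parameters
    ----------
    name : str
        Column name; unique within a :class:`Dataset`.
    kind : str
        One of ``"binary"``, ``"continuous"``, ``"categorical"``.
    ordered : bool
        For categoricals with a natural order (e.g. age bands).  The
        level order is taken from the column's categorical dtype when
        present, otherwise from sorted unique values.
    """

    name: str
    kind: str
    ordered: bool = False

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown variable kind {self.kind!r}; expected one of {KINDS}")


class Dataset:
    """A flat observation table with a binary outcome.

    Rows are independent observation units (e.g. patient-months).  The
    outcome column must contain only 0/1 with no missing values;
    predictors may contain missing values (handled downstream by
    binning).
    """

    def __init__(
        self,
        frame: pd.DataFrame,
        outcome_name: str,
        variables: Sequence[VariableSpec] | None = None,
    ) -> None:
        if outcome_name not in frame.columns:
            raise KeyError(f"outcome column {outcome_name!r} not found in data")
        if len(frame) < 1:
            raise ValueError("dataset must contain at least one row")
        y = _coerce_binary(frame[outcome_name], outcome_name, allow_missing=False)
        self._frame = frame.copy()
        self._frame[outcome_name] = y
        self.outcome_name = outcome_name
        if variables is None:
            variables = infer_variable_specs(self._frame.drop(columns=[outcome_name]))
        names = [v.name for v in variables]
        if len(set(names)) != len(names):
            raise ValueError("duplicate variable names in spec")
        missing = [n for n in names if n not in frame.columns]
        if missing:
            raise KeyError(f"variables not present in data: {missing}")
        self.variables: list[VariableSpec] = list(variables)
        for v in self.variables:
            if v.kind == BINARY:
                self._frame[v.name] = _coerce_binary(self._frame[v.name], v.name, allow_missing=True)

    # -- accessors ---------------------------------------------------
    @property
    def n(self) -> int:
        return len(self._frame)

    @property
    def outcome(self) -> np.ndarray:
        return self._frame[self.outcome_name].to_numpy(dtype=np.int64)

    @property
    def frame(self) -> pd.DataFrame:
        return self._frame

    @property
    def predictors(self) -> pd.DataFrame:
        return self._frame[[v.name for v in self.variables]]

    def variable(self, name: str) -> VariableSpec:
        for v in self.variables:
            if v.name == name:
                return v
        raise KeyError(f"no variable named {name!r}")

    @property
    def n_events(self) -> int:
        return int(self.outcome.sum())

    @property
    def n_nonevents(self) -> int:
        return self.n - self.n_events

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"Dataset(n={self.n}, variables={len(self.variables)}, "
            f"events={self.n_events}, outcome={self.outcome_name!r})"
        )


def prevalence(d: Dataset) -> float:
    """Fraction of rows with the event; in [0, 1], 0 iff no events."""
    return d.n_events / d.n


def _coerce_binary(col: pd.Series, name: str, allow_missing: bool) -> pd.Series:
    """Coerce a column to {0,1} integers, accepting 0/1/true/false spellings."""
    isna = col.isna()
    if isna.any() and not allow_missing:
        raise ValueError(f"column {name!r} contains missing values")
    out = pd.Series(np.full(len(col), np.nan), index=col.index, dtype=float)
    vals = col[~isna]
    if pd.api.types.is_numeric_dtype(vals) or pd.api.types.is_bool_dtype(vals):
        numeric = pd.to_numeric(vals)
        bad = ~numeric.isin([0, 1])
    else:
        lowered = vals.astype(str).str.strip().str.lower()
        numeric = pd.Series(np.where(lowered.isin(_TRUE), 1.0, 0.0), index=vals.index)
        bad = ~(lowered.isin(_TRUE) | lowered.isin(_FALSE))
    if bad.any():
        offending = col[~isna][bad.to_numpy()].unique()[:5]
        raise ValueError(
            f"column {name!r} is not binary: offending value(s) {list(offending)!r}"
        )
    out[~isna] = numeric.astype(float)
    if allow_missing and isna.any():
        return out
    return out.astype(np.int64)


def infer_variable_specs(frame: pd.DataFrame) -> list[VariableSpec]:
    """Infer variable kinds from data.

    Rule: at most 2 distinct non-missing values, all spelled as 0/1
    (or true/false) -> binary; otherwise numeric dtype -> continuous;
    otherwise categorical (ordered when the dtype is an ordered pandas
    Categorical).  Every inference is logged.
    """
    specs = []
    for name in frame.columns:
        col = frame[name]
        nunique = col.dropna().nunique()
        kind = None
        if nunique <= 2:
            try:
                _coerce_binary(col, name, allow_missing=True)
                kind = BINARY
            except ValueError:
                kind = None
        if kind is None:
            if pd.api.types.is_numeric_dtype(col):
                kind = CONTINUOUS
            else:
                kind = CATEGORICAL
        ordered = bool(isinstance(col.dtype, pd.CategoricalDtype) and col.dtype.ordered)
        logger.info("inferred kind %s for variable %r (%d distinct values)", kind, name, nunique)
        specs.append(VariableSpec(name, kind, ordered=ordered))
    return specs


def read_dataset(
    path: str | Path,
    outcome_name: str,
    spec: Sequence[VariableSpec] | None = None,
    sep: str = ",",
) -> Dataset:
    """Read a delimited text file into a :class:`Dataset`.

    Parameters
    ----------
    path : str or Path
        CSV (RFC-4180 quoting) or, with ``sep="\\t"``, TSV.  UTF-8 with
        a header row.
    outcome_name : str
        Name of the binary outcome column (values coercible to {0,1}).
    spec : sequence of VariableSpec, optional
        Explicit variable metadata; inferred from data when absent.
    """
    path = Path(path)
    frame = pd.read_csv(path, sep=sep)
    if frame.empty:
        raise ValueError(f"{path} contains no rows")
    return Dataset(frame, outcome_name, variables=spec)


def write_dataset(d: Dataset, path: str | Path, sep: str = ",") -> None:
    """Write the dataset to delimited text; round-trips through
    :func:`read_dataset` with the same variable specs."""
    d.frame.to_csv(path, sep=sep, index=False)


def subset(d: Dataset, names: Iterable[str]) -> Dataset:
    """Dataset restricted to the given predictor columns (outcome kept)."""
    names = list(names)
    specs = [d.variable(n) for n in names]
    return Dataset(d.frame[names + [d.outcome_name]], d.outcome_name, variables=specs)
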