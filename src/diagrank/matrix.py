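"""Decision-matrix assembly and direction-aware min/max normalization.

The decision matrix holds one row per alternative (classifier) and one column
per criterion, together with direction metadata (beneficial = maximize,
non-beneficial = minimize). Normalization rescales every column into (0, 1]
so that the direction-appropriate optimum maps to 1:

* beneficial column:      x_ij / max_i(x_ij)
* non-beneficial column:  min_i(x_ij) / x_ij

After normalization every column is max-oriented, which is the form the
outranking and compromise rankers consume. Column extrema are taken over the
supplied alternatives only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .metrics import CRITERIA, DIRECTIONS, FoldSummary

_VALID_DIRECTIONS = ("beneficial", "non_beneficial")


@dataclass(frozen=True)
class CriterionSpec:
    name: str
    direction: str

    def __post_init__(self) -> None:
        if self.direction not in _VALID_DIRECTIONS:
            raise ValueError(
                f"direction for {self.name!r} must be one of {_VALID_DIRECTIONS}, "
                f"got {self.direction!r}"
            )


def default_criterion_specs() -> list[CriterionSpec]:
    """The ten standard criteria with their optimization directions."""
    return [CriterionSpec(c, DIRECTIONS[c]) for c in CRITERIA]


@dataclass(frozen=True)
class DecisionMatrix:
    """Alternatives x criteria grid with direction metadata.

    ``data`` rows are alternatives (index = ids), columns are criteria.
    ``directions`` maps every column to 'beneficial' or 'non_beneficial' so
    downstream methods never re-infer orientation. ``normalized`` marks a
    matrix whose columns are already max-oriented in (0, 1].
    """

    data: pd.DataFrame
    directions: dict[str, str]
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.data.shape[0] < 2:
            raise ValueError("a decision matrix needs at least 2 alternatives")
        if self.data.shape[1] < 1:
            raise ValueError("a decision matrix needs at least 1 criterion")
        if self.data.index.has_duplicates or self.data.columns.has_duplicates:
            raise ValueError("alternative ids and criterion names must be unique")
        missing = set(self.data.columns) - set(self.directions)
        if missing:
            raise ValueError(f"criteria without a direction: {sorted(missing)}")
        for name, d in self.directions.items():
            if d not in _VALID_DIRECTIONS:
                raise ValueError(f"invalid direction {d!r} for criterion {name!r}")
        if self.data.isna().any().any():
            raise ValueError("decision matrix has missing cells")
        bad = np.argwhere(self.data.to_numpy(dtype=float) <= 0)
        if bad.size:
            i, j = bad[0]
            raise ValueError(
                "decision matrix values must be > 0 (min/max normalization divides "
                f"by them); offending cell: ({self.data.index[i]!r}, "
                f"{self.data.columns[j]!r}) = {self.data.iat[i, j]}"
            )

    @property
    def alternatives(self) -> list[str]:
        return list(self.data.index)

    @property
    def criteria(self) -> list[str]:
        return list(self.data.columns)

    def specs(self) -> list[CriterionSpec]:
        return [CriterionSpec(c, self.directions[c]) for c in self.criteria]

    def to_csv(self, path) -> None:
        out = self.data.copy()
        if out.index.name is None:
            out.index.name = "alternative"
        out.to_csv(path)

    @classmethod
    def from_csv(
        cls, path, directions: Mapping[str, str], normalized: bool = False
    ) -> "DecisionMatrix":
        data = pd.read_csv(path, index_col=0)
        return cls(data=data, directions=dict(directions), normalized=normalized)


def build_decision_matrix(
    summaries: Mapping[str, FoldSummary],
    specs: Sequence[CriterionSpec] | None = None,
    percent: bool = True,
) -> DecisionMatrix:
    """Assemble the matrix from per-alternative fold summaries.

    Cell values are the fold means of each criterion (the parameter count is
    constant over folds, so its mean is the count itself). ``percent`` renders
    rate criteria and MCC on the percent scale, matching the usual report
    layout; normalization is scale-invariant per column either way.
    """
    if specs is None:
        specs = default_criterion_specs()
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise ValueError("criterion names must be unique")
    rows = {}
    for alt, summary in summaries.items():
        missing = [n for n in names if n not in summary.mean.index]
        if missing:
            raise ValueError(
                f"alternative {alt!r} is missing criteria: {missing}"
            )
        mean = summary.mean.copy()
        if percent:
            from .metrics import PERCENT_CRITERIA

            cols = [c for c in PERCENT_CRITERIA if c in mean.index]
            mean[cols] *= 100.0
        rows[alt] = mean[names]
    data = pd.DataFrame.from_dict(rows, orient="index")[names]
    return DecisionMatrix(data=data, directions={s.name: s.direction for s in specs})


class DirectionNormalizer(TransformerMixin, BaseEstimator):
    """Direction-aware min/max scaler producing max-oriented columns in (0, 1].

    Parameters
    ----------
    directions : mapping, sequence or None
        Per-column direction ('beneficial' / 'non_beneficial'). A mapping is
        keyed by column name (DataFrame input); a sequence is positional.
        None treats every column as beneficial.

    Attributes
    ----------
    maxima_, minima_ : ndarray of column extrema seen during fit.
    columns_ : column labels seen during fit (DataFrame input only).
    """

    def __init__(self, directions=None):
        self.directions = directions

    def _resolve_directions(self, columns, k: int) -> np.ndarray:
        d = self.directions
        if d is None:
            resolved = ["beneficial"] * k
        elif isinstance(d, Mapping):
            if columns is None:
                raise ValueError(
                    "directions given as a mapping require DataFrame input"
                )
            missing = [c for c in columns if c not in d]
            if missing:
                raise ValueError(f"no direction for columns: {missing}")
            resolved = [d[c] for c in columns]
        else:
            resolved = list(d)
            if len(resolved) != k:
                raise ValueError(
                    f"got {len(resolved)} directions for {k} columns"
                )
        for v in resolved:
            if v not in _VALID_DIRECTIONS:
                raise ValueError(f"invalid direction {v!r}")
        return np.asarray([v == "beneficial" for v in resolved])

    def fit(self, X, y=None):
        values, columns, _ = _as_matrix(X)
        self._validate_positive(values, columns, X)
        self.columns_ = columns
        self.beneficial_ = self._resolve_directions(columns, values.shape[1])
        self.maxima_ = values.max(axis=0)
        self.minima_ = values.min(axis=0)
        self.n_features_in_ = values.shape[1]
        return self

    def transform(self, X):
        values, columns, index = _as_matrix(X)
        if values.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {values.shape[1]} columns, expected {self.n_features_in_}"
            )
        self._validate_positive(values, columns, X)
        out = np.where(
            self.beneficial_, values / self.maxima_, self.minima_ / values
        )
        if columns is not None:
            return pd.DataFrame(out, index=index, columns=columns)
        return out

    def _validate_positive(self, values, columns, X) -> None:
        bad = np.argwhere(values <= 0)
        if bad.size:
            i, j = bad[0]
            row = X.index[i] if isinstance(X, pd.DataFrame) else i
            col = columns[j] if columns is not None else j
            raise ValueError(
                f"non-positive entry at ({row!r}, {col!r}): {values[i, j]}"
            )


def _as_matrix(X):
    """(values, columns-or-None, index-or-None) from DataFrame/array input."""
    if isinstance(X, DecisionMatrix):
        X = X.data
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.columns), X.index
    arr = np.asarray(X, dtype=float)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D matrix, got shape {arr.shape}")
    return arr, None, None


def normalize(dm: DecisionMatrix) -> DecisionMatrix:
    """Normalize a decision matrix (full floating precision; round at report
    time only)."""
    scaler = DirectionNormalizer(directions=dm.directions)
    data = scaler.fit_transform(dm.data)
    # every column is max-oriented after scaling
    directions = {c: "beneficial" for c in dm.criteria}
    return DecisionMatrix(data=data, directions=directions, normalized=True)
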