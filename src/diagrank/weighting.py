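"""Criterion weights: the entropy method and externally supplied vectors.

The entropy method weights each criterion by the contrast of its column in
the (normalized) decision matrix. With m alternatives:

    p_ij = x_ij / sum_i x_ij                 (column-share)
    e_j  = -(1/ln m) * sum_i p_ij ln p_ij    (entropy, in [0, 1])
    d_j  = 1 - e_j                           (contrast intensity)
    w_j  = d_j / sum_j d_j

A uniform column carries maximum entropy (e_j = 1) and receives weight 0; if
every column is uniform there is no discriminating criterion and weighting is
undefined. The p ln p term is taken as 0 at p = 0 (standard convention).

User-supplied weight vectors are stored verbatim, signs included; rankers can
consume either the signed values or their magnitudes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .matrix import DecisionMatrix, _as_matrix


@dataclass(frozen=True)
class WeightVector:
    """Per-criterion weights plus provenance.

    Entropy-derived weights are non-negative and sum to 1; user-supplied
    weights are kept verbatim (they may be signed or unnormalized) and a
    magnitude view is available via :attr:`magnitudes`.
    """

    values: pd.Series
    provenance: str  # 'entropy' | 'user_supplied'
    intermediates: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if self.provenance not in ("entropy", "user_supplied"):
            raise ValueError(f"unknown provenance {self.provenance!r}")
        v = self.values.to_numpy(dtype=float)
        if not np.all(np.isfinite(v)):
            raise ValueError("weights must be finite")
        if np.all(v == 0):
            raise ValueError("weights must not be all zero")

    @property
    def magnitudes(self) -> pd.Series:
        return self.values.abs()

    @property
    def criteria(self) -> list[str]:
        return list(self.values.index)


class EntropyWeighter(BaseEstimator):
    """Entropy criterion weighting as a scikit-learn style estimator.

    ``fit(X)`` consumes an alternatives x criteria matrix (all entries >= 0,
    m >= 2 rows) and exposes:

    Attributes
    ----------
    shares_ : column-share matrix p_ij (columns sum to 1)
    entropy_ : per-criterion entropy e_j in [0, 1]
    contrast_ : d_j = 1 - e_j
    weights_ : per-criterion weights, non-negative, summing to 1
    """

    def fit(self, X, y=None):
        values, columns, index = _as_matrix(X)
        m, k = values.shape
        if m < 2:
            raise ValueError("entropy weighting needs at least 2 alternatives")
        if np.any(values < 0):
            raise ValueError("entropy weighting requires non-negative entries")
        colsum = values.sum(axis=0)
        if np.any(colsum == 0):
            j = int(np.argmax(colsum == 0))
            name = columns[j] if columns is not None else j
            raise ValueError(f"criterion {name!r} is all zero")
        p = values / colsum
        with np.errstate(divide="ignore", invalid="ignore"):
            plogp = np.where(p > 0, p * np.log(p), 0.0)
        e = -plogp.sum(axis=0) / np.log(m)
        d = 1.0 - e
        # clip the tiny negative residue floating point can leave on uniform columns
        d = np.where(np.abs(d) < 1e-15, 0.0, d)
        if d.sum() == 0:
            raise ValueError(
                "no discriminating criterion: every column is uniform"
            )
        w = d / d.sum()
        if columns is not None:
            self.shares_ = pd.DataFrame(p, index=index, columns=columns)
            self.entropy_ = pd.Series(e, index=columns)
            self.contrast_ = pd.Series(d, index=columns)
            self.weights_ = pd.Series(w, index=columns)
        else:
            self.shares_, self.entropy_, self.contrast_, self.weights_ = p, e, d, w
        self.g_ = 1.0 / np.log(m)
        self.n_features_in_ = k
        return self


def entropy_weights(matrix) -> WeightVector:
    """Entropy weights of a (normalized) decision matrix."""
    est = EntropyWeighter().fit(matrix)
    w = est.weights_
    if not isinstance(w, pd.Series):
        w = pd.Series(w, index=range(len(w)))
    return WeightVector(
        values=w,
        provenance="entropy",
        intermediates={
            "shares": est.shares_,
            "entropy": est.entropy_,
            "contrast": est.contrast_,
            "g": est.g_,
        },
    )


def load_weights(
    values: Sequence[float] | Mapping[str, float] | pd.Series,
    criteria: Sequence[str] | None = None,
) -> WeightVector:
    """Wrap an externally supplied weight vector (stored verbatim, signed)."""
    if isinstance(values, Mapping):
        series = pd.Series(values, dtype=float)
        if criteria is not None:
            missing = [c for c in criteria if c not in series.index]
            if missing:
                raise ValueError(f"weights missing for criteria: {missing}")
            series = series[list(criteria)]
    else:
        arr = np.asarray(list(values), dtype=float)
        if criteria is not None:
            if len(arr) != len(criteria):
                raise ValueError(
                    f"got {len(arr)} weights for {len(criteria)} criteria"
                )
            series = pd.Series(arr, index=list(criteria))
        elif isinstance(values, pd.Series):
            series = values.astype(float)
        else:
            series = pd.Series(arr)
    return WeightVector(values=series, provenance="user_supplied")


def resolve_weights(
    weights, criteria: Sequence[str], weight_signs: str = "magnitude"
) -> np.ndarray:
    """Align a weight specification to a criterion list as a float array.

    Accepts a WeightVector, Series, mapping, sequence or None (equal weights
    1/k). ``weight_signs='magnitude'`` takes absolute values (the default for
    ranking); ``'signed'`` keeps signs for sensitivity analysis.
    """
    k = len(criteria)
    if weights is None:
        arr = np.full(k, 1.0 / k)
    elif isinstance(weights, WeightVector):
        arr = resolve_weights(weights.values, criteria, "signed")
    elif isinstance(weights, pd.Series) or isinstance(weights, Mapping):
        series = pd.Series(weights, dtype=float)
        missing = [c for c in criteria if c not in series.index]
        if missing:
            raise ValueError(f"weights missing for criteria: {missing}")
        arr = series[list(criteria)].to_numpy()
    else:
        arr = np.asarray(list(weights), dtype=float)
        if arr.shape != (k,):
            raise ValueError(f"got {arr.size} weights for {k} criteria")
    if weight_signs == "magnitude":
        arr = np.abs(arr)
    elif weight_signs != "signed":
        raise ValueError("weight_signs must be 'magnitude' or 'signed'")
    if not np.all(np.isfinite(arr)):
        raise ValueError("weights must be finite")
    return arr
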