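"""PROMETHEE I/II outranking on a max-oriented decision matrix.

For every ordered pair of alternatives (a, b) and criterion j the deviation
d_j(a, b) = x_aj - x_bj is mapped through a preference function to P_j(a, b)
in {0, 1}; the usual (threshold) criterion gives P = 1 iff d > 0. Ties at
d = 0 yield P = 0 on both sides, which is what makes pi(a, a) = 0 and net
flows conserve. The global preference index aggregates criteria:

    pi(a, b) = sum_j w_j P_j(a, b)

Flows come in two conventions, both first-class:

* averaged: phi+(a) = (1/(m-1)) sum_b pi(a, b)  (textbook form)
* summed:   phi+(a) = sum_b pi(a, b)            (no 1/(m-1) factor)

phi(a) = phi+(a) - phi-(a) in either convention; ranks descend in phi.
Negative user-supplied weights would break the flow interpretation, so the
index uses weight magnitudes by default; signed use stays available for
sensitivity analysis.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .matrix import _as_matrix
from .weighting import resolve_weights

_CONVENTIONS = ("averaged", "summed")


class PrometheeRanker(BaseEstimator):
    """PROMETHEE II complete ranking as a scikit-learn style estimator.

    Parameters
    ----------
    weights : WeightVector, Series, mapping, sequence or None
        Per-criterion weights; None means equal weights 1/k.
    preference : {'usual'}
        Preference function; only the usual 0/1 threshold criterion is
        implemented (P(d) = 1 iff d > 0).
    flow_convention : {'averaged', 'summed'}
        Whether flows divide by (m - 1).
    weight_signs : {'magnitude', 'signed'}
        How signed weight vectors enter the preference index.

    Attributes
    ----------
    preference_index_ : DataFrame, pi(a, b) over ordered pairs
    phi_plus_, phi_minus_, phi_ : Series of outranking flows
    rank_ : Series of ordinal ranks (1 = best, descending phi; ties broken
        by alternative id order)
    ranking_ : list of alternative ids, best first
    """

    def __init__(
        self,
        weights=None,
        preference: str = "usual",
        flow_convention: str = "averaged",
        weight_signs: str = "magnitude",
    ):
        self.weights = weights
        self.preference = preference
        self.flow_convention = flow_convention
        self.weight_signs = weight_signs

    def fit(self, X, y=None):
        if self.preference != "usual":
            raise ValueError(
                f"unsupported preference function {self.preference!r}"
            )
        if self.flow_convention not in _CONVENTIONS:
            raise ValueError(
                f"flow_convention must be one of {_CONVENTIONS}, "
                f"got {self.flow_convention!r}"
            )
        from .matrix import DecisionMatrix

        if isinstance(X, DecisionMatrix) and not X.normalized and any(
            d == "non_beneficial" for d in X.directions.values()
        ):
            raise ValueError(
                "PROMETHEE expects a max-oriented matrix; normalize() the "
                "decision matrix first"
            )
        values, columns, index = _as_matrix(X)
        m, k = values.shape
        if m < 2:
            raise ValueError("ranking needs at least 2 alternatives")
        criteria = columns if columns is not None else list(range(k))
        ids = list(index) if index is not None else list(range(m))
        w = resolve_weights(self.weights, criteria, self.weight_signs)

        # P[a, b, j] = 1 iff a strictly beats b on criterion j (usual criterion)
        pref = (values[:, None, :] > values[None, :, :]).astype(float)
        pi = pref @ w
        np.fill_diagonal(pi, 0.0)

        scale = 1.0 / (m - 1) if self.flow_convention == "averaged" else 1.0
        phi_plus = pi.sum(axis=1) * scale
        phi_minus = pi.sum(axis=0) * scale
        phi = phi_plus - phi_minus

        self.criteria_ = list(criteria)
        self.alternatives_ = ids
        self.weights_ = pd.Series(w, index=criteria)
        self.preference_index_ = pd.DataFrame(pi, index=ids, columns=ids)
        self.phi_plus_ = pd.Series(phi_plus, index=ids)
        self.phi_minus_ = pd.Series(phi_minus, index=ids)
        self.phi_ = pd.Series(phi, index=ids)
        self.rank_ = _ordinal_ranks(self.phi_, ascending=False)
        self.ranking_ = list(self.rank_.sort_values().index)
        self.n_features_in_ = k
        return self

    def report(self) -> pd.DataFrame:
        """Alternative, phi and rank, best first."""
        out = pd.DataFrame(
            {
                "phi_plus": self.phi_plus_,
                "phi_minus": self.phi_minus_,
                "phi": self.phi_,
                "rank": self.rank_,
            }
        )
        out.index.name = "alternative"
        return out.sort_values("rank")


def _ordinal_ranks(scores: pd.Series, ascending: bool) -> pd.Series:
    """1..m ordinal ranks; exact score ties broken by alternative id order."""
    order = sorted(
        scores.index, key=lambda a: ((1 if ascending else -1) * scores[a], str(a))
    )
    return pd.Series(
        {a: r for r, a in enumerate(order, start=1)}, index=scores.index, dtype=int
    )


def promethee_rank(
    matrix,
    weights=None,
    preference: str = "usual",
    flow_convention: str = "averaged",
    weight_signs: str = "magnitude",
) -> PrometheeRanker:
    """Fit a :class:`PrometheeRanker` on a max-oriented matrix."""
    return PrometheeRanker(
        weights=weights,
        preference=preference,
        flow_convention=flow_convention,
        weight_signs=weight_signs,
    ).fit(matrix)


def pairwise_preference_table(
    matrix, weights=None, preference: str = "usual", weight_signs: str = "magnitude"
) -> pd.DataFrame:
    """The global preference index pi(a, b) over all ordered pairs."""
    est = PrometheeRanker(
        weights=weights, preference=preference, weight_signs=weight_signs
    ).fit(matrix)
    return est.preference_index_
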