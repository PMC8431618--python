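"""VIKOR compromise ranking.

VIKOR scores each alternative by its distance to the per-criterion ideal:

    S_i = sum_j w_j (x_j* - x_ij) / (x_j* - x_j^-)   (group utility / weighted regret)
    R_i = max_j  w_j (x_j* - x_ij) / (x_j* - x_j^-)  (worst single regret)
    Q_i = v (S_i - S*) / (S^- - S*) + (1 - v) (R_i - R*) / (R^- - R*)

where x_j* / x_j^- are the best / worst column values (max / min for
beneficial criteria, min / max for non-beneficial ones), starred / minus
scalars are the extremes of S and R over alternatives, and v in [0, 1]
weighs "the majority of criteria" against the worst individual regret.
Alternatives are ranked by ascending Q; Q = 0 whenever an alternative attains
both the minimum S and minimum R, and 1 at the joint maximum.

The ranker accepts either an already max-oriented (normalized) matrix
(directions=None) or a raw matrix with explicit per-criterion directions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .matrix import _as_matrix
from .weighting import resolve_weights


class VikorRanker(BaseEstimator):
    """VIKOR compromise ranking as a scikit-learn style estimator.

    Parameters
    ----------
    weights : WeightVector, Series, mapping, sequence or None
        Per-criterion weights; None means equal weights.
    v : float in [0, 1]
        Weight of the group-utility term in Q (0.5 balances group utility
        and individual regret).
    directions : mapping / sequence / None
        None treats every column as max-oriented (normalized input); raw
        matrices supply 'beneficial' / 'non_beneficial' per column.
    weight_signs : {'magnitude', 'signed'}
    zero_range : {'raise', 'exclude'}
        A criterion whose best equals its worst value cannot be scaled; it is
        either reported as an error naming the criterion or silently dropped
        from S/R.

    Attributes
    ----------
    best_, worst_ : per-criterion x_j* and x_j^-
    S_, R_, Q_ : per-alternative scores
    rank_ : ordinal ranks (1 = best, ascending Q, ties broken by id)
    ranking_ : alternative ids, best first
    """

    def __init__(
        self,
        weights=None,
        v: float = 0.5,
        directions=None,
        weight_signs: str = "magnitude",
        zero_range: str = "raise",
    ):
        self.weights = weights
        self.v = v
        self.directions = directions
        self.weight_signs = weight_signs
        self.zero_range = zero_range

    def fit(self, X, y=None):
        if not 0.0 <= self.v <= 1.0:
            raise ValueError(f"v must lie in [0, 1], got {self.v}")
        if self.zero_range not in ("raise", "exclude"):
            raise ValueError("zero_range must be 'raise' or 'exclude'")
        from .matrix import DecisionMatrix, DirectionNormalizer

        directions = self.directions
        if (
            directions is None
            and isinstance(X, DecisionMatrix)
            and not X.normalized
        ):
            # raw matrices carry their own orientation metadata
            directions = X.directions
        values, columns, index = _as_matrix(X)
        m, k = values.shape
        if m < 2:
            raise ValueError("ranking needs at least 2 alternatives")
        criteria = columns if columns is not None else list(range(k))
        ids = list(index) if index is not None else list(range(m))
        w = resolve_weights(self.weights, criteria, self.weight_signs)

        beneficial = DirectionNormalizer(directions)._resolve_directions(
            columns, k
        )
        best = np.where(beneficial, values.max(axis=0), values.min(axis=0))
        worst = np.where(beneficial, values.min(axis=0), values.max(axis=0))

        span = best - worst
        degenerate = span == 0
        if degenerate.any():
            names = [criteria[j] for j in np.flatnonzero(degenerate)]
            if self.zero_range == "raise":
                raise ValueError(
                    f"zero-range criteria (best equals worst): {names}; "
                    "drop them or pass zero_range='exclude'"
                )
            keep = ~degenerate
            if not keep.any():
                raise ValueError("every criterion has zero range")
            values, best, worst, span, w = (
                values[:, keep], best[keep], worst[keep], span[keep], w[keep],
            )
            criteria = [c for c, k_ in zip(criteria, keep) if k_]

        regret = w * (best - values) / span  # one term per alternative x criterion
        S = regret.sum(axis=1)
        R = regret.max(axis=1)

        s_star, s_minus = S.min(), S.max()
        r_star, r_minus = R.min(), R.max()
        if s_minus == s_star and r_minus == r_star:
            raise ValueError(
                "degenerate input: S and R are both constant over alternatives"
            )
        # a constant S (or R) carries no discrimination; its Q term is 0
        q_s = (S - s_star) / (s_minus - s_star) if s_minus > s_star else np.zeros(m)
        q_r = (R - r_star) / (r_minus - r_star) if r_minus > r_star else np.zeros(m)
        Q = self.v * q_s + (1.0 - self.v) * q_r

        from .outranking import _ordinal_ranks

        self.criteria_ = list(criteria)
        self.alternatives_ = ids
        self.weights_ = pd.Series(w, index=criteria)
        self.best_ = pd.Series(best, index=criteria)
        self.worst_ = pd.Series(worst, index=criteria)
        self.S_ = pd.Series(S, index=ids)
        self.R_ = pd.Series(R, index=ids)
        self.Q_ = pd.Series(Q, index=ids)
        self.S_star_, self.S_minus_ = float(s_star), float(s_minus)
        self.R_star_, self.R_minus_ = float(r_star), float(r_minus)
        self.rank_ = _ordinal_ranks(self.Q_, ascending=True)
        self.ranking_ = list(self.rank_.sort_values().index)
        self.n_features_in_ = k
        return self

    def report(self) -> pd.DataFrame:
        """Alternative, S, R, Q and rank, best first."""
        out = pd.DataFrame(
            {"S": self.S_, "R": self.R_, "Q": self.Q_, "rank": self.rank_}
        )
        out.index.name = "alternative"
        return out.sort_values("rank")


def vikor_rank(
    matrix,
    weights=None,
    v: float = 0.5,
    directions=None,
    weight_signs: str = "magnitude",
    zero_range: str = "raise",
) -> VikorRanker:
    """Fit a :class:`VikorRanker`; see the class for parameter semantics."""
    return VikorRanker(
        weights=weights,
        v=v,
        directions=directions,
        weight_signs=weight_signs,
        zero_range=zero_range,
    ).fit(matrix)
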