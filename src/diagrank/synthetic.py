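"""Synthetic classifier predictions and planted-structure decision matrices.

The generator emulates the structure of a cross-validated diagnostic study:
a pool of n_pos positive and n_neg negative cases is partitioned into
stratified folds, and each simulated classifier predicts every test case
independently — a positive case is called positive with probability equal to
the classifier's planted sensitivity, a negative case is called negative with
probability equal to its specificity. Draws are independent Bernoulli per
case and per classifier; correlation induced by classifiers sharing the same
test images is deliberately not modelled.

Defaults mirror the melanoma case study the package ships fixtures for:
491 positive and 500 negative cases over 5 folds, which yields per-cycle
training sets of 393/400 for the four equal-size folds (one fold carries the
remainder case, so one cycle trains on 392 positives).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import DecisionMatrix

POSITIVE_LABEL = "positive"
NEGATIVE_LABEL = "negative"


@dataclass(frozen=True)
class SyntheticModelSpec:
    """Planted per-class correctness probabilities for one classifier."""

    model_id: str
    sensitivity: float
    specificity: float
    n_params: float  # millions

    def __post_init__(self) -> None:
        for name in ("sensitivity", "specificity"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {p}")


@dataclass(frozen=True)
class FoldPlan:
    """Stratified test-fold sizes and the seed driving the simulation."""

    n_pos: int
    n_neg: int
    n_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("need at least 2 folds")
        if self.n_pos < self.n_folds or self.n_neg < self.n_folds:
            raise ValueError("each class needs at least one case per fold")


def stratified_fold_sizes(n_pos: int, n_neg: int, n_folds: int) -> pd.DataFrame:
    """Per-fold stratified test sizes and the complementary train sizes.

    Within each class the fold sizes differ by at most one; the folds carrying
    the remainder come first (deterministic). Returns one row per fold with
    columns ``test_pos``, ``test_neg``, ``train_pos``, ``train_neg``.
    """
    if n_folds < 2:
        raise ValueError("need at least 2 folds")
    if n_pos < n_folds or n_neg < n_folds:
        raise ValueError(
            f"class counts ({n_pos}, {n_neg}) must each be >= n_folds ({n_folds})"
        )

    def sizes(n: int) -> np.ndarray:
        base, rem = divmod(n, n_folds)
        return np.array([base + 1] * rem + [base] * (n_folds - rem))

    tp, tn = sizes(n_pos), sizes(n_neg)
    out = pd.DataFrame(
        {
            "fold": np.arange(1, n_folds + 1),
            "test_pos": tp,
            "test_neg": tn,
            "train_pos": n_pos - tp,
            "train_neg": n_neg - tn,
        }
    )
    return out


def simulate_predictions(
    specs: list[SyntheticModelSpec], plan: FoldPlan
) -> pd.DataFrame:
    """Simulate hard predictions for every classifier over stratified folds.

    Output is a long table with columns ``alternative``, ``fold``, ``y_true``,
    ``y_pred``; identical plans (seed included) give bit-identical tables.
    """
    if not specs:
        raise ValueError("no model specs supplied")
    folds = stratified_fold_sizes(plan.n_pos, plan.n_neg, plan.n_folds)
    rng = np.random.default_rng(plan.seed)
    frames = []
    for spec in specs:
        for _, row in folds.iterrows():
            npos, nneg = int(row.test_pos), int(row.test_neg)
            hit_pos = rng.random(npos) < spec.sensitivity
            hit_neg = rng.random(nneg) < spec.specificity
            frames.append(
                pd.DataFrame(
                    {
                        "alternative": spec.model_id,
                        "fold": int(row.fold),
                        "y_true": [POSITIVE_LABEL] * npos + [NEGATIVE_LABEL] * nneg,
                        "y_pred": np.concatenate(
                            [
                                np.where(hit_pos, POSITIVE_LABEL, NEGATIVE_LABEL),
                                np.where(hit_neg, NEGATIVE_LABEL, POSITIVE_LABEL),
                            ]
                        ),
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


def planted_dominance_matrix(
    m: int,
    k: int,
    seed: int = 0,
    directions: list[str] | None = None,
    winner: str | None = None,
) -> DecisionMatrix:
    """Random positive decision matrix with one strictly dominant alternative.

    The designated winner (first alternative by default) is strictly best on
    every criterion, direction-aware: strictly largest on beneficial columns,
    strictly smallest on non-beneficial ones. Remaining cells are uniform
    random positives.
    """
    if m < 2 or k < 1:
        raise ValueError("need m >= 2 alternatives and k >= 1 criteria")
    if directions is None:
        directions = ["beneficial"] * k
    if len(directions) != k:
        raise ValueError(f"got {len(directions)} directions for {k} criteria")
    rng = np.random.default_rng(seed)
    values = rng.uniform(1.0, 10.0, size=(m, k))
    for j, d in enumerate(directions):
        col = values[1:, j]
        if d == "beneficial":
            values[0, j] = col.max() * 1.25
        else:
            values[0, j] = col.min() * 0.75
    ids = [winner or "winner"] + [f"alt{i}" for i in range(1, m)]
    crits = [f"c{j}" for j in range(k)]
    return DecisionMatrix(
        data=pd.DataFrame(values, index=ids, columns=crits),
        directions=dict(zip(crits, directions)),
    )
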