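"""Confusion-matrix criteria for binary diagnostic classifiers.

Ten criteria are computed per cross-validation fold from hard (non-probabilistic)
predictions: accuracy, classification error, precision, sensitivity (recall),
F1-score, specificity, false-positive rate, false-negative rate, the Matthews
correlation coefficient, and model complexity (parameter count in millions).
Fold-level vectors are aggregated to mean +/- sample standard deviation, which
is the per-classifier summary the decision matrix is built from.

All rate-like criteria are stored as fractions in [0, 1] (MCC in [-1, 1]);
reports render them on the percent scale.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Canonical criterion order used throughout the package (matrix columns,
#: weight vectors, reports).
CRITERIA: tuple[str, ...] = (
    "acc", "sen", "spe", "f1", "fnr", "fpr", "pre", "mcc", "err", "n_params",
)

#: Optimization direction per criterion: beneficial = larger is better.
DIRECTIONS: dict[str, str] = {
    "acc": "beneficial",
    "sen": "beneficial",
    "spe": "beneficial",
    "f1": "beneficial",
    "pre": "beneficial",
    "mcc": "beneficial",
    "err": "non_beneficial",
    "fnr": "non_beneficial",
    "fpr": "non_beneficial",
    "n_params": "non_beneficial",
}

#: Criteria rendered as percentages in reports (everything but the raw
#: parameter count; MCC is also reported on the percent scale).
PERCENT_CRITERIA: tuple[str, ...] = (
    "acc", "sen", "spe", "f1", "fnr", "fpr", "pre", "mcc", "err",
)


@dataclass(frozen=True)
class ConfusionCounts:
    """The four cells of a binary contingency table."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if v < 0:
                raise ValueError(f"confusion count {f.name} must be >= 0, got {v}")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class CriterionVector:
    """One classifier's values on the ten criteria (fractions, not percent)."""

    acc: float
    err: float
    pre: float
    sen: float
    f1: float
    spe: float
    fpr: float
    fnr: float
    mcc: float
    n_params: float

    def as_series(self, percent: bool = False) -> pd.Series:
        s = pd.Series({c: getattr(self, c) for c in CRITERIA}, dtype=float)
        if percent:
            s[list(PERCENT_CRITERIA)] *= 100.0
        return s


@dataclass(frozen=True)
class FoldSummary:
    """Per-criterion mean and sample standard deviation over CV folds."""

    mean: pd.Series
    std: pd.Series
    n_folds: int


def confusion_counts(
    y_true: Sequence, y_pred: Sequence, positive_label
) -> ConfusionCounts:
    """Count tp/tn/fp/fn for a two-class label alphabet.

    The positive label is caller-supplied semantics (e.g. the disease class),
    never inferred from sort order.
    """
    yt = np.asarray(y_true)
    yp = np.asarray(y_pred)
    if yt.size == 0:
        raise ValueError("empty label sequences")
    if yt.shape != yp.shape:
        raise ValueError(
            f"length mismatch: {yt.shape[0]} true vs {yp.shape[0]} predicted labels"
        )
    alphabet = set(np.unique(yt)) | set(np.unique(yp))
    if positive_label not in alphabet:
        raise ValueError(f"positive_label {positive_label!r} not present in labels")
    if len(alphabet) > 2:
        raise ValueError(f"expected a two-value label alphabet, got {sorted(map(str, alphabet))}")
    tpos = yt == positive_label
    ppos = yp == positive_label
    return ConfusionCounts(
        tp=int(np.sum(tpos & ppos)),
        tn=int(np.sum(~tpos & ~ppos)),
        fp=int(np.sum(~tpos & ppos)),
        fn=int(np.sum(tpos & ~ppos)),
    )


def criterion_vector(counts: ConfusionCounts, n_params: float) -> CriterionVector:
    """Evaluate the ten criteria from confusion counts.

    Degenerate denominators follow the common conventions: precision is 0 when
    no positive predictions exist, F1 is 0 when precision + sensitivity is 0,
    and MCC is 0 when any contingency-table marginal is 0 (random-prediction
    value). These conventions are documented in docs/methods.md.
    """
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    n = counts.total
    if n == 0:
        raise ValueError("all-zero confusion counts")

    acc = (tp + tn) / n
    pre = tp / (tp + fp) if tp + fp > 0 else 0.0
    sen = tp / (tp + fn) if tp + fn > 0 else 0.0
    f1 = 2 * pre * sen / (pre + sen) if pre + sen > 0 else 0.0
    spe = tn / (tn + fp) if tn + fp > 0 else 0.0

    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / np.sqrt(denom) if denom > 0 else 0.0

    return CriterionVector(
        acc=acc,
        err=1.0 - acc,
        pre=pre,
        sen=sen,
        f1=f1,
        spe=spe,
        fpr=1.0 - spe,
        fnr=1.0 - sen,
        mcc=float(mcc),
        n_params=float(n_params),
    )


def aggregate_folds(per_fold: Iterable[CriterionVector | pd.Series]) -> FoldSummary:
    """Aggregate fold-level criterion vectors to mean +/- sample std.

    The standard deviation uses the n-1 (sample) denominator; with a single
    fold the std is 0 for every criterion.
    """
    rows = [
        v.as_series() if isinstance(v, CriterionVector) else pd.Series(v, dtype=float)
        for v in per_fold
    ]
    if not rows:
        raise ValueError("aggregate_folds requires at least one fold")
    frame = pd.DataFrame(rows)
    if frame.isna().any().any():
        raise ValueError("criterion sets differ across folds")
    n = len(frame)
    std = frame.std(ddof=1) if n > 1 else pd.Series(0.0, index=frame.columns)
    return FoldSummary(mean=frame.mean(), std=std, n_folds=n)


def fold_criteria(
    predictions: pd.DataFrame,
    n_params: Mapping[str, float],
    positive_label,
) -> pd.DataFrame:
    """Per-(alternative, fold) criterion table from a long predictions frame.

    `predictions` needs columns ``alternative``, ``fold``, ``y_true``,
    ``y_pred`` (arbitrary string labels). Returns one row per alternative and
    fold with the ten criteria as columns (fraction scale).
    """
    required = {"alternative", "fold", "y_true", "y_pred"}
    missing = required - set(predictions.columns)
    if missing:
        raise ValueError(f"predictions table missing columns: {sorted(missing)}")
    records = []
    for (alt, fold), grp in predictions.groupby(["alternative", "fold"], sort=True):
        if alt not in n_params:
            raise ValueError(f"no parameter count supplied for alternative {alt!r}")
        counts = confusion_counts(grp["y_true"], grp["y_pred"], positive_label)
        vec = criterion_vector(counts, n_params[alt]).as_series()
        vec["alternative"] = alt
        vec["fold"] = fold
        records.append(vec)
    out = pd.DataFrame(records)
    return out[["alternative", "fold", *CRITERIA]]


def summarize_predictions(
    predictions: pd.DataFrame,
    n_params: Mapping[str, float],
    positive_label,
) -> dict[str, FoldSummary]:
    """Fold-aggregated summary per alternative (the Table-2-style view)."""
    table = fold_criteria(predictions, n_params, positive_label)
    return {
        str(alt): aggregate_folds(
            [row for _, row in grp[list(CRITERIA)].iterrows()]
        )
        for alt, grp in table.groupby("alternative", sort=True)
    }


def summary_frame(
    summaries: Mapping[str, FoldSummary], percent: bool = True
) -> pd.DataFrame:
    """Render summaries as a mean/std column-pair table (report layout)."""
    rows = {}
    for alt, s in summaries.items():
        mean, std = s.mean.copy(), s.std.copy()
        if percent:
            cols = [c for c in PERCENT_CRITERIA if c in mean.index]
            mean[cols] *= 100.0
            std[cols] *= 100.0
        row = {}
        for c in mean.index:
            row[f"mean_{c}"] = mean[c]
            row[f"std_{c}"] = std[c]
        rows[alt] = row
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "alternative"
    return out
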