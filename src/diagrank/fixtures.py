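"""Bundled case-study data: 19 CNN melanoma classifiers, ten criteria.

The package ships a small set of CSV fixtures transcribing a published
benchmark of nineteen convolutional neural networks evaluated for binary
melanoma diagnosis over five stratified folds:

* ``complexity.csv`` — parameter count per network (millions)
* ``criterion_summary.csv`` — fold mean and sample std of the nine
  confusion-matrix criteria, percent scale
* ``fold_accuracies.csv`` — per-fold test accuracies (percent)
* ``normalized_matrix.csv`` — the 19 x 10 normalized decision matrix as
  published (4 decimal places)
* ``published_weights.csv`` — the ten criterion weights the source analysis
  used, stored verbatim with their signs
* ``reference_rankings.csv`` — published net flows (phi), VIKOR Q values and
  both ranking columns

One cell of the fold-accuracy table is internally inconsistent in the
source: the DenseNet201 row as printed averages to 94.04 with sample std
4.91, while the summary table reports 93.94 +/- 4.97. A fold-2 accuracy of
91.44 (vs the printed 91.94) reproduces both the published mean and std
exactly, so the printed value is a typographical error; the loader applies
this erratum by default and keeps the verbatim value available.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .matrix import CriterionSpec, DecisionMatrix, default_criterion_specs, normalize
from .metrics import CRITERIA, DIRECTIONS
from .weighting import WeightVector, load_weights

#: (network, fold-column) cells whose printed value contradicts the published
#: mean/std pair; mapped to the value consistent with both.
FOLD_ACCURACY_ERRATA: dict[tuple[str, str], float] = {
    ("DenseNet201", "fold2"): 91.44,  # printed 91.94; 91.44 gives 93.94 +/- 4.97
}


def _read(name: str) -> pd.DataFrame:
    ref = resources.files("diagrank").joinpath("data", name)
    with resources.as_file(ref) as path:
        return pd.read_csv(path)


def load_complexity() -> pd.Series:
    """Parameter counts in millions, indexed by network."""
    df = _read("complexity.csv")
    return df.set_index("network")["n_params"]


def load_criterion_means() -> pd.DataFrame:
    """Fold means of the nine confusion-matrix criteria (percent scale)."""
    df = _read("criterion_summary.csv").set_index("network")
    means = df[[c for c in df.columns if c.startswith("mean_")]].copy()
    means.columns = [c.removeprefix("mean_") for c in means.columns]
    return means


def load_criterion_stds() -> pd.DataFrame:
    """Fold sample standard deviations matching :func:`load_criterion_means`."""
    df = _read("criterion_summary.csv").set_index("network")
    stds = df[[c for c in df.columns if c.startswith("std_")]].copy()
    stds.columns = [c.removeprefix("std_") for c in stds.columns]
    return stds


def load_fold_accuracies(corrected: bool = True) -> pd.DataFrame:
    """Per-fold test accuracies (percent), one row per network.

    ``corrected=True`` applies :data:`FOLD_ACCURACY_ERRATA`;
    ``corrected=False`` returns the table verbatim as printed.
    """
    df = _read("fold_accuracies.csv").set_index("network")
    if corrected:
        df = df.copy()
        for (network, fold), value in FOLD_ACCURACY_ERRATA.items():
            df.loc[network, fold] = value
    return df


def load_normalized_matrix() -> DecisionMatrix:
    """The published 19 x 10 normalized decision matrix (4-dp values)."""
    data = _read("normalized_matrix.csv").set_index("network")[list(CRITERIA)]
    return DecisionMatrix(
        data=data,
        directions={c: "beneficial" for c in CRITERIA},
        normalized=True,
    )


def load_published_weights() -> WeightVector:
    """The ten published criterion weights, verbatim with signs."""
    df = _read("published_weights.csv")
    return load_weights(df.set_index("criterion")["weight"], criteria=list(CRITERIA))


def load_reference_rankings() -> pd.DataFrame:
    """Published phi, Q and both ranking columns, indexed by network."""
    return _read("reference_rankings.csv").set_index("network")


def case_study_specs() -> list[CriterionSpec]:
    return default_criterion_specs()


def build_case_study_matrix() -> DecisionMatrix:
    """Raw decision matrix: nine criterion means plus the complexity column."""
    means = load_criterion_means()
    params = load_complexity()
    data = means.copy()
    data["n_params"] = params
    data = data[list(CRITERIA)]
    return DecisionMatrix(data=data, directions=dict(DIRECTIONS))


def validate_fixtures(atol_mean: float = 0.01, atol_norm: float = 5e-5) -> None:
    """Internal-consistency checks across the bundled tables.

    * fold accuracies average (and n-1 std) to the summary accuracy column —
      at one printed ULP, since the folds are themselves 2-dp rounded;
    * the summary table satisfies the complement identities
      err = 100 - acc, fnr = 100 - sen, fpr = 100 - spe at printed precision;
    * normalizing the raw matrix reproduces the published normalized matrix
      at its 4-dp precision.

    Raises AssertionError on the first violated check.
    """
    folds = load_fold_accuracies()
    means = load_criterion_means()
    stds = load_criterion_stds()

    fold_mean = folds.mean(axis=1)
    fold_std = folds.std(axis=1, ddof=1)
    assert np.allclose(fold_mean, means["acc"], atol=atol_mean), (
        "fold accuracies do not average to the summary accuracy column"
    )
    assert np.allclose(fold_std, stds["acc"], atol=atol_mean), (
        "fold accuracy stds do not match the summary column"
    )

    for derived, base in (("err", "acc"), ("fnr", "sen"), ("fpr", "spe")):
        assert np.allclose(means[derived], 100.0 - means[base], atol=0.005 + 1e-9), (
            f"complement identity violated: {derived} != 100 - {base}"
        )

    recomputed = normalize(build_case_study_matrix()).data
    published = load_normalized_matrix().data
    assert np.allclose(
        recomputed.round(4), published, atol=atol_norm
    ), "normalizing the raw matrix does not reproduce the published matrix"
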