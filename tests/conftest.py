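import numpy as np
import pandas as pd
import pytest

from diagrank import fixtures
from diagrank.matrix import DecisionMatrix


@pytest.fixture(scope="session")
def case_matrix() -> DecisionMatrix:
    """Raw case-study decision matrix (19 networks x 10 criteria)."""
    return fixtures.build_case_study_matrix()


@pytest.fixture(scope="session")
def published_normalized() -> pd.DataFrame:
    return fixtures.load_normalized_matrix().data


@pytest.fixture(scope="session")
def published_weights():
    return fixtures.load_published_weights()


@pytest.fixture(scope="session")
def reference_rankings() -> pd.DataFrame:
    return fixtures.load_reference_rankings()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


def random_positive_matrix(rng, m, k, as_frame=True):
    values = rng.uniform(0.1, 10.0, size=(m, k))
    if not as_frame:
        return values
    return pd.DataFrame(
        values,
        index=[f"a{i}" for i in range(m)],
        columns=[f"c{j}" for j in range(k)],
    )
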