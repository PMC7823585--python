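import numpy as np
import pandas as pd
import pytest

from panclass.classify import CentroidProfile
from panclass.preprocess import ExpressionMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20260904)


@pytest.fixture
def count_matrix(rng):
    """Small random count matrix (20 genes x 5 samples)."""
    X = rng.integers(1, 2000, size=(20, 5))
    return ExpressionMatrix(
        pd.DataFrame(X, index=[f"g{i}" for i in range(20)],
                     columns=[f"s{j}" for j in range(5)]),
        cohort="toy",
        unit="counts",
    )


@pytest.fixture
def toy_centroids():
    """Two orthogonal-ish toy centroids over 4 genes."""
    vals = pd.DataFrame(
        {"LumA": [2.0, 1.0, -1.0, -2.0], "Basal": [-2.0, -1.0, 1.0, 2.0]},
        index=[f"g{i}" for i in range(4)],
    )
    return CentroidProfile(vals)


def make_expression(rng, p=30, n=10, cohort="c0", unit="logCPM"):
    X = rng.normal(size=(p, n))
    return ExpressionMatrix(
        pd.DataFrame(X, index=[f"g{i}" for i in range(p)],
                     columns=[f"{cohort}_s{j}" for j in range(n)]),
        cohort=cohort,
        unit=unit,
    )
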