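import numpy as np
import pandas as pd
import pytest

from plaqomics.omics_io import CytokinePanel, ExpressionMatrix
from plaqomics.synthetic_cohort import CohortConfig, simulate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_counts():
    """3 features x 4 samples, two groups."""
    values = pd.DataFrame(
        [[9, 9, 12, 30], [10, 3, 0, 5], [0, 0, 0, 0]],
        index=["g1", "g2", "g3"],
        columns=["s1", "s2", "s3", "s4"],
    )
    groups = pd.Series({"s1": "HIV", "s2": "HIV", "s3": "HIV_AS", "s4": "HIV_AS"})
    return ExpressionMatrix(values, groups, "counts")


@pytest.fixture
def normalized_matrix(rng):
    values = pd.DataFrame(
        rng.uniform(2, 10, size=(8, 6)),
        index=[f"g{i}" for i in range(8)],
        columns=[f"s{j}" for j in range(6)],
    )
    groups = pd.Series({f"s{j}": ("A" if j < 3 else "B") for j in range(6)})
    return ExpressionMatrix(values, groups, "normalized")


@pytest.fixture
def duplicate_panel():
    values = pd.DataFrame(
        {"IL6": [4.0, 9.0, 2.0, 8.0], "TNF": [5.0, 5.0, 7.0, 7.0]},
        index=["a/1", "a/2", "b/1", "b/2"],
    )
    rep = pd.Series(["a", "a", "b", "b"], index=values.index)
    return CytokinePanel(values, replicate_of=rep)


@pytest.fixture(scope="session")
def default_bundle():
    return simulate_cohort(CohortConfig(seed=7))
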