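import numpy as np
import pandas as pd
import pytest

from xspecies_nash.io_formats import ExpressionMatrix
from xspecies_nash.study import biomarker_fixture, build_study


@pytest.fixture(scope="session")
def study():
    """Full six-cohort synthetic study at the default design, seed 1."""
    return build_study(seed=1)


@pytest.fixture(scope="session")
def bm_fixture():
    """Planted-truth biomarker cascade fixture, seed 1."""
    return biomarker_fixture(seed=1)


@pytest.fixture
def small_counts():
    """3-gene, 4-sample count matrix with hand-checkable values."""
    values = pd.DataFrame(
        {
            "s1": [10, 100, 0],
            "s2": [12, 110, 1],
            "s3": [40, 95, 2],
            "s4": [44, 105, 0],
        },
        index=["gA", "gB", "gC"],
    )
    return ExpressionMatrix(values, "count")


@pytest.fixture
def groups_2v2():
    return pd.Series(
        ["control", "control", "case", "case"], index=["s1", "s2", "s3", "s4"], name="group"
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
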