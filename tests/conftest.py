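import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from _util import make_numeric_table

from hcmfs import generate_cohort, planted_spec, table1_spec
from hcmfs.preprocess import standardize


@pytest.fixture(scope="session")
def table1_cohort():
    """One generated instance of the published-cohort spec (no missingness)."""
    return generate_cohort(table1_spec(missing_rate=0.0), seed=0)


@pytest.fixture(scope="session")
def table1_cohort_std(table1_cohort):
    return standardize(table1_cohort)


@pytest.fixture(scope="session")
def planted_table():
    """Planted-signal cohort: 6 informative + 14 noise features."""
    return generate_cohort(planted_spec(), seed=42)


@pytest.fixture
def small_separable_table():
    """Tiny linearly separable table: f0 carries the labels, f1 is noise."""
    rng = np.random.default_rng(7)
    y = np.repeat([0, 1], 20)
    X = np.column_stack([y + 0.01 * rng.standard_normal(40), rng.standard_normal(40)])
    return make_numeric_table(X, y)
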