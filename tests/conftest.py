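import numpy as np
import pandas as pd
import pytest

from dietmort import generate_cohort

#: generator overrides that shrink the internal calibration reference for
#: fast unit-test cohorts (the quantities tested here do not depend on it)
FAST = {"hazards": {"calibration_n": 20000}}


@pytest.fixture(scope="session")
def small_cohort() -> pd.DataFrame:
    """A 4000-subject default-configuration cohort."""
    return generate_cohort(n_subjects=4000, seed=11, **FAST)


@pytest.fixture(scope="session")
def survival_cohort() -> pd.DataFrame:
    """A survival-only cohort (no diet simulation) with two countries."""
    return generate_cohort(
        n_subjects=8000, seed=12, simulate_diet=False,
        countries={"Denmark": 2, "Spain": 2},
        hazards={"calibration_n": 20000})


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
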