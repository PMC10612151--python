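import numpy as np
import pandas as pd
import pytest

from fusiform import CohortSimConfig, simulate_cohort


@pytest.fixture
def five_case_cohort() -> pd.DataFrame:
    """Tiny corrected-mode cohort with hand-checkable summary statistics."""
    return pd.DataFrame(
        {
            "case_id": [f"c{i}" for i in range(1, 6)],
            "age": [30, 41, 52, 25, 60],
            "sex": ["female", "male", "female", "female", "male"],
            "location": ["head", "head", "neck", "abdomen", "head"],
            "corrected_width": [0.4, 0.5, 0.6, 0.7, 0.8],
            "corrected_length": [1.0, 1.2, 1.5, 1.4, 2.0],
            "designed_arc": [1.2, 1.4, 1.7, 1.7, 2.3],
            "post_incision": [1.1, 1.3, 1.8, 1.6, 2.2],
        }
    )


@pytest.fixture
def default_cohort() -> pd.DataFrame:
    """One seeded draw under the study's default generator conditions."""
    return simulate_cohort(CohortSimConfig(seed=20260924))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260924)
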