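import logging

import numpy as np
import pandas as pd
import pytest

from envage.synthetic_cohort import GeneratorConfig, generate_cohort

logging.getLogger("envage").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_cohort() -> pd.DataFrame:
    """A 2000-participant archetype-mode cohort shared across tests."""
    return generate_cohort(GeneratorConfig(n=2000, seed=42))


@pytest.fixture(scope="session")
def reference_panel() -> dict:
    """A mid-range biomarker panel used as a fixed fixture."""
    return {
        "albumin": 46.0, "creatinine": 70.0, "glucose": 5.0, "crp": 1.3,
        "lymphocyte_pct": 30.0, "mcv": 91.0, "rdw": 13.5, "alp": 80.0,
        "wbc": 6.8, "age": 55.0,
    }


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
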