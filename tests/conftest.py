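import numpy as np
import pandas as pd
import pytest

from geoaccess import StudyArea, SyntheticConfig, gen_enrollees, gen_facilities


@pytest.fixture
def unit_square() -> StudyArea:
    return StudyArea.square(1.0)


@pytest.fixture
def small_facilities() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "id": ["F1", "F2", "F3"],
            "name": ["Alpha Clinic", "Beta Hospital", "Gamma Centre"],
            "level": ["primary", "secondary", "tertiary"],
            "nhis_accredited": [False, True, True],
            "lga": ["North", "North", "South"],
            "x": [100.0, 2000.0, 350.5],
            "y": [200.0, 900.0, 4100.25],
        }
    )


@pytest.fixture
def small_enrollees() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "id": ["E1", "E2"],
            "x": [150.0, 1000.0],
            "y": [250.0, 1000.0],
            "used_facility_id": ["F2", "F3"],
        }
    )


@pytest.fixture
def sim_pair():
    """A moderately sized synthetic study shared across tests."""
    cfg = SyntheticConfig(seed=11, n_facilities=150, n_enrollees=120)
    fac = gen_facilities(cfg)
    enr = gen_enrollees(cfg, fac)
    return cfg, fac, enr


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
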