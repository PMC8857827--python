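import numpy as np
import pandas as pd
import pytest

from growthdx.customized import PregnancyRecord, Sex
from growthdx.population import build_demo_table
from growthdx.simulate import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def demo_table():
    return build_demo_table()


@pytest.fixture
def record():
    return PregnancyRecord(
        maternal_age=32.6,
        maternal_height=162.02,
        pregestational_weight=78.5,
        sex=Sex.MALE,
        ga_scan=36.0,
        efw=2600.0,
        ga_birth=37.5,
        birthweight=2900.0,
        birth_length=48.0,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """Deterministic 300-record synthetic cohort used across tests."""
    return simulate_cohort(SimulationConfig(n=300, seed=42, hdp_shift=-0.8, rho=0.6))


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def toy_classifications():
    return pd.DataFrame(
        {
            "size_class": ["SGA", "SGA", "AGA", "AGA"],
            "nutrition": ["undernourished", "normal", "undernourished", "normal"],
        }
    )
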