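import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cottonlai import datasets

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rlai_table():
    """Reference relative-LAI grid (six treatments, eight GDD points)."""
    return datasets.rlai_table()


@pytest.fixture(scope="session")
def mean_curve(rlai_table):
    """(gdd, mean_rlai) arrays of the reference table's printed mean column."""
    return rlai_table["gdd"].to_numpy(), rlai_table["mean_rlai"].to_numpy()


@pytest.fixture(scope="session")
def biomass_table():
    return datasets.biomass_table()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
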