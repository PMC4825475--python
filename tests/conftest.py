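import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from carequity.tables import load_utilization_table

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def survey_table():
    """The packaged 72-cell five-way utilization table."""
    return load_utilization_table()


@pytest.fixture(scope="session")
def gp_view(survey_table):
    """Four-way view for the GP model (specialist axis collapsed)."""
    return survey_table.collapse(["location", "age", "ses", "vis_gp"])


@pytest.fixture(scope="session")
def sd_view(survey_table):
    """Four-way view for the specialist model (GP axis collapsed)."""
    return survey_table.collapse(["location", "age", "ses", "vis_sd"])


@pytest.fixture()
def rng():
    return np.random.default_rng(20260101)
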