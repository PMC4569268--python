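import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from codmedia import doe, published

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def paper_design():
    """The bundled 36-run COD production design with observed responses."""
    return doe.load_paper_fixture()


@pytest.fixture(scope="session")
def published_model():
    """The published 21-coefficient quadratic for COD activity."""
    return published.published_quadratic()


@pytest.fixture(scope="session")
def center_composition():
    return np.array([0.75, 0.75, 0.75, 0.025, 0.15])
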