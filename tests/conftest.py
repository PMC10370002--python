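import numpy as np
import pytest
from hypothesis import settings

from pollendrive import drive_scenario

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def scenario():
    """Drive cross with the effective linked unit at 0 cM, 6.02% baseline."""
    return drive_scenario()


@pytest.fixture(scope="session")
def scenario_mapped():
    """Drive cross with the linked antidote at its mapped 18.7 cM distance."""
    return drive_scenario(antidote_cm=18.7)
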