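import numpy as np
import pytest

from wfhmm import FrequencyGrid, PopulationParams


@pytest.fixture(scope="session")
def grid129() -> FrequencyGrid:
    return FrequencyGrid.uniform(129)


@pytest.fixture
def neutral100() -> PopulationParams:
    return PopulationParams(Ne=100, s=0.0, h=0.5)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
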