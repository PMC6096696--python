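import numpy as np
import pytest
from hypothesis import settings

from pointillism.colour import DisplayCalibration
from pointillism.observer import GroundTruth, make_observers, simulate_session

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def cal() -> DisplayCalibration:
    return DisplayCalibration()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def session_table():
    """One default synthetic session: 5 observers, 4 conditions, 15 pairs,
    4 replicates, linear N_t/N_v ground truth."""
    rng = np.random.default_rng(20260928)
    observers = make_observers(5, rng)
    return simulate_session(observers, GroundTruth(), rng)
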