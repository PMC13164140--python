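import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from lipoxkin import (
    ReactorConditions,
    simulate,
    tomato_pomace_mechanism,
)

H = 3600.0
T12 = 43_200.0
T4 = 14_400.0


@pytest.fixture(scope="session")
def mech():
    return tomato_pomace_mechanism()


def _traj(mech, celsius):
    return simulate(mech, ReactorConditions.from_celsius(celsius, t_end=T12))


@pytest.fixture(scope="session")
def traj50(mech):
    return _traj(mech, 50.0)


@pytest.fixture(scope="session")
def traj70(mech):
    return _traj(mech, 70.0)


@pytest.fixture(scope="session")
def traj90(mech):
    return _traj(mech, 90.0)


@pytest.fixture(scope="session")
def all_trajs(traj50, traj70, traj90):
    return {50.0: traj50, 70.0: traj70, 90.0: traj90}


def rel_err(value, reference):
    return abs(value - reference) / abs(reference)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260920)
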