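import numpy as np
import pytest

from thermoperf.synthetic import make_default_profiles
from thermoperf.tpc import ToleranceSummary


@pytest.fixture(scope="session")
def profiles():
    return {p.species: p for p in make_default_profiles()}


@pytest.fixture(scope="session")
def rattlesnake(profiles):
    return profiles["Crotalus polystictus"]


@pytest.fixture(scope="session")
def fossorial(profiles):
    return profiles["Conopsis lineata"]


@pytest.fixture(scope="session")
def gartersnake(profiles):
    return profiles["Thamnophis melanogaster"]


@pytest.fixture
def wide_anchors():
    """A tolerance interval generously wider than the test curves."""
    return ToleranceSummary(species="test", ct_min_mean=5.0, ct_max_mean=45.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20240719)
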