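import numpy as np
import pytest

from abstractmyo import (
    BlockPlan,
    TaskSpaceConfig,
    VirtualUserProfile,
    simulate_session,
)


@pytest.fixture
def cfg():
    return TaskSpaceConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def simulated_bucket():
    """One full 16-block pick-and-place session with ground truth, shared
    across tests that only read it."""
    profile = VirtualUserProfile()
    return simulate_session(profile, BlockPlan.default(16), rng=20220725)
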