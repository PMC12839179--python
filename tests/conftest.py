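import numpy as np
import pytest

from exosweep import ExoGeometry, default_muscle_set, generate_trial


@pytest.fixture(scope="session")
def clean_trial():
    """Noise-free default-subject trial (the pre-computed kinematics the
    device fitting uses)."""
    return generate_trial(noise_sd=0.0, seed=0)


@pytest.fixture(scope="session")
def geometry():
    return ExoGeometry()


@pytest.fixture(scope="session")
def muscles():
    return default_muscle_set(87.6, 1.86)


@pytest.fixture(scope="session")
def left_muscles(muscles):
    return [m for m in muscles if m.side == "left"]


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
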