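import numpy as np
import pytest

from platelab.synthgen import PatternSpec, SICMSimParams, generate_pattern


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture(scope="session")
def default_pattern():
    """4-um lines at 15-um period on a 25.6-um field, 0.1 um/px."""
    return generate_pattern(PatternSpec())


@pytest.fixture(scope="session")
def quiet_sim():
    """Noise-free, untilted simulator constants for analytic checks."""
    return SICMSimParams(noise_sigma=0.0, tilt=(0.0, 0.0))
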