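import numpy as np
import pytest

from momchannel import OpticsParams, simulate_stack


@pytest.fixture(scope="session")
def default_stack_and_truth():
    """One rendered 10-generation stack with defaults, shared across tests."""
    return simulate_stack(n_generations=10, seed=42)


@pytest.fixture(scope="session")
def clean_stack_and_truth():
    """Low-blur, noise-free stack for tight geometric assertions."""
    optics = OpticsParams(psf_sigma_px=0.5, read_noise_sd=0.0, shot_noise=False)
    return simulate_stack(optics=optics, n_generations=10, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
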