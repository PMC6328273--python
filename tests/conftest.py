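import numpy as np
import pytest

from cpgph import BursterParams, generate_burster_trace


@pytest.fixture(scope="session")
def clean_burster():
    """Noiseless reference burster: 1 Hz, duty 0.30, 5 spikes/burst."""
    params = BursterParams(noise_sd=0.0)
    trace = generate_burster_trace(params, 60.0, 10_000.0, seed=0)
    return params, trace


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
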