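import numpy as np
import pytest

from nucleotopo import synthetic_nuclei as syn


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture(scope="session")
def control_population():
    """Small rendered control population (noise sigma=8), shared by
    recovery tests."""
    spec = syn.condition_spec("control", n_nuclei=40, noise_sigma=8.0, seed=101)
    return spec, syn.generate_population(spec)


@pytest.fixture(scope="session")
def noiseless_population():
    spec = syn.condition_spec("control", n_nuclei=25, noise_sigma=0.0, seed=202)
    return spec, syn.generate_population(spec)
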