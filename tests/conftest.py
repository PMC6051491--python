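import numpy as np
import pytest

from halopol.synthetic_data import TraceSimParams, simulate_traces


@pytest.fixture(scope="session")
def br3_sim():
    """One BR3-condition flow-stretching experiment, shared across tests."""
    return simulate_traces(seed=0)


@pytest.fixture(scope="session")
def clean_sim():
    """Noise- and drift-free BR3-condition experiment (exact boundaries)."""
    params = TraceSimParams(noise_sd=0.0, drift_amplitude=0.0, n_reaction_traces=5, seed=7)
    return simulate_traces(params)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
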