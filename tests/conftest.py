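import numpy as np
import pytest

from isodeg.simulate import simulate_experiment


@pytest.fixture(scope="session")
def tiny_experiment():
    """A small but complete simulated experiment shared across tests."""
    return simulate_experiment(n_genes=25, depth=30_000, n_reps=2, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
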