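import numpy as np
import pytest

from fullforce import NetworkParams, TrainingConfig, init_random_weights


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_params():
    return NetworkParams(n_units=8)


@pytest.fixture
def small_weights(small_params):
    return init_random_weights(small_params, seed=7)


@pytest.fixture(scope="session")
def quick_oscillation_model():
    """A small full-FORCE oscillation network trained just enough to be
    clearly better than chance; shared across tests to save time."""
    from fullforce import train_full_force

    params = NetworkParams(n_units=250)
    config = TrainingConfig(
        algorithm="full-force", task="oscillation", n_batches=2,
        periods_per_batch=100, seed=11,
    )
    return train_full_force(params, config)
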