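import numpy as np
import pytest

from votcortex.synth import SyntheticConfig, make_hg_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_config():
    """A scaled-down study: 2 participants, 12 trials per VOT."""
    return SyntheticConfig(
        seed=7, n_participants=2, n_behavior_participants=2, trials_per_vot=12
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return make_hg_dataset(small_config)
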