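import numpy as np
import pytest

import valuecode as vc
from valuecode.task import TaskConfig


@pytest.fixture(scope="session")
def small_config() -> TaskConfig:
    """A short blocked session: 6 blocks x 12 trials, both odor sets."""
    return TaskConfig(trials_per_block=12, n_blocks=6, seed=11)


@pytest.fixture(scope="session")
def small_session(small_config):
    """72-trial session with two neurons of each generative class."""
    truth = vc.make_population(n_value=2, n_untuned=2, n_lick=2, n_reward=2,
                               n_none=2, seed=12)
    return vc.simulate_session(small_config, truth)


@pytest.fixture(scope="session")
def small_prepared(small_session):
    return vc.prepare_session(small_session)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
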