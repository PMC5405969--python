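import numpy as np
import pandas as pd
import pytest

from horizontask.agents import simulate_study
from horizontask.task_design import SessionConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_config():
    """12 games: 4 per horizon, 2 per (horizon, information) stratum."""
    return SessionConfig(n_games=12, seed=99)


@pytest.fixture(scope="session")
def small_study(small_config):
    """Two-subject crossover study on the 12-game design."""
    return simulate_study(config=small_config, n_subjects=2, seed=7)


@pytest.fixture(scope="session")
def small_observations(small_study):
    return small_study.observations()
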