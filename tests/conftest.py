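import numpy as np
import pandas as pd
import pytest

from memorize.memory import ItemParams
from memorize.schedulers import UniformScheduler
from memorize.simulate import PopulationConfig, SimulationWindow, simulate_population


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def small_uniform_log() -> pd.DataFrame:
    """A small canonical log: 8 learners x 8 items, uniform reviewing."""
    config = PopulationConfig(
        n_learners=8,
        n_items=8,
        scheduler=UniformScheduler(mu=0.3),
        window=SimulationWindow(0.0, 30.0),
        n0_median=0.15,
        master_seed=42,
    )
    return simulate_population(config)


@pytest.fixture
def toy_log() -> pd.DataFrame:
    """Hand-built 2-learner log with known session grades."""
    rows = [
        ("u1", "a", 1.0, 1, 1),
        ("u1", "a", 3.0, 1, 0),
        ("u1", "a", 6.5, 1, 1),
        ("u1", "b", 0.5, 4, 3),
        ("u1", "b", 2.0, 4, 4),
        ("u2", "a", 2.0, 1, 1),
        ("u2", "a", 4.0, 1, 1),
    ]
    return pd.DataFrame(
        rows,
        columns=["learner_id", "item_id", "t_days", "session_seen", "session_correct"],
    )
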