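import numpy as np
import pytest

from gametransfer import games as G
from gametransfer.agents import Population
from gametransfer.engine import SimulationConfig, run_training


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def random_game_pool():
    """A pool of unconstrained random generic 2x2 games (payoffs iid
    uniform) for oracle comparisons, plus draws from every class."""
    rng = np.random.default_rng(777)
    rows = rng.uniform(-1, 1, (6000, 2, 2))
    cols = rng.uniform(-1, 1, (6000, 2, 2))
    for c in G.GAME_CLASSES:
        r, k = G.generate_games(c, 600, rng)
        rows = np.concatenate([rows, r])
        cols = np.concatenate([cols, k])
    return rows, cols


@pytest.fixture(scope="session")
def pd_trained():
    """A small-but-converged PD-trained population (dominance learning is
    fast; 4,000 games saturate the defect response)."""
    cfg = SimulationConfig(
        training_class="PD", n_training_games=4000, n_test_games=200, master_seed=11
    )
    return run_training(cfg)


@pytest.fixture
def tiny_population(rng):
    return Population.initialize(4, rng)
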