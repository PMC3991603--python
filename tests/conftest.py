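import numpy as np
import pandas as pd
import pytest

from rpslearn import RelphParams, run_game
from rpslearn.environment import outcome, reward_of, stationary_bias_schedule

LOG_COLUMNS = ["trial", "phase", "player_choice", "opponent_choice", "outcome", "reward"]


def playlog_from_choices(players, opponents, phase=1) -> pd.DataFrame:
    """Build an internally consistent play log from two choice sequences."""
    rows = []
    for i, (p, o) in enumerate(zip(players, opponents)):
        res = outcome(p, o)
        rows.append((i + 1, phase, p, o, res, reward_of(res)))
    return pd.DataFrame(rows, columns=LOG_COLUMNS)


@pytest.fixture(scope="session")
def short_relph_log() -> pd.DataFrame:
    """120-trial soft-max RELPH log against a stationary 80%-paper opponent."""
    return run_game(
        "relph",
        RelphParams(n=2, h_thr=2.0, alpha=0.25),
        schedule=stationary_bias_schedule(length=120),
        seed=1,
    )


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
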