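"""Running agents against scheduled opponents and summarising their play.

The unit of analysis is the *play log*: one row per trial with the player's
choice, the opponent's choice, the outcome and the reward.  Win rates are
summarised, as in the behavioural task, over the final 200 trials split into
twenty blocks of 10.  Cohorts of simulated participants are drawn from group
presets whose parameter distributions follow the fitted group statistics:
healthy-control-like (soft-max), left-brain-damage-like (greedy soft-max
"lesion", all else as HC) and right-brain-damage-like (lower pruning
threshold, higher learning rate).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .elph import ELPHAgent, ElphParams
from .environment import (
    OpponentSchedule,
    default_schedule,
    generate_opponent_sequence,
    outcome,
    reward_of,
)
from .core import RPS_ALPHABET
from .relph import RELPHAgent, RelphParams

LOG_COLUMNS = ["trial", "phase", "player_choice", "opponent_choice", "outcome", "reward"]

MODELS = ("elph", "relph", "relph-greedy")


def make_agent(
    model: str,
    params: ElphParams | RelphParams,
    seed: int | np.random.SeedSequence | None = None,
    value_seed: int | None = None,
):
    """Instantiate an agent; 'relph-greedy' forces argmax choice."""
    if model == "elph":
        if not isinstance(params, ElphParams):
            raise TypeError("elph expects ElphParams")
        return ELPHAgent(params, seed=seed)
    if model in ("relph", "relph-greedy"):
        if not isinstance(params, RelphParams):
            raise TypeError("relph expects RelphParams")
        if model == "relph-greedy" and not params.greedy:
            params = replace(params, greedy=True)
        return RELPHAgent(params, seed=seed, value_seed=value_seed)
    raise ValueError(f"unknown model {model!r}; expected one of {MODELS}")


def run_game(
    model: str,
    params: ElphParams | RelphParams,
    schedule: OpponentSchedule | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Play a full scheduled game; returns the per-trial play log.

    The master seed deterministically spawns independent streams for the
    opponent sequence and the agent, so a fixed seed reproduces the log
    byte-for-byte.
    """
    if schedule is None:
        schedule = default_schedule()
    for phase in schedule.phases:
        for sym, p in phase.distribution:
            if p > 0 and sym not in RPS_ALPHABET:
                raise ValueError(f"schedule symbol {sym!r} outside the RPS alphabet")
    ss = np.random.SeedSequence(seed)
    opp_ss, agent_ss = ss.spawn(2)
    opp_seq = generate_opponent_sequence(schedule, rng=np.random.default_rng(opp_ss))
    agent = make_agent(model, params, seed=agent_ss)
    phases = schedule.phase_indices()
    rows = []
    for i, opp in enumerate(opp_seq):
        played, result, r = agent.step(opp)
        rows.append((i + 1, int(phases[i]), played, opp, result, r))
    return pd.DataFrame(rows, columns=LOG_COLUMNS)


def write_playlog(log: pd.DataFrame, path) -> None:
    log.to_csv(path, index=False)


def read_playlog(path, validate: bool = True) -> pd.DataFrame:
    """Read a play-log CSV, checking per-row internal consistency."""
    log = pd.read_csv(path)
    missing = [c for c in LOG_COLUMNS if c not in log.columns]
    if missing:
        raise ValueError(f"play log missing columns: {missing}")
    if len(log) == 0:
        raise ValueError("play log is empty")
    if validate:
        for i, row in log.iterrows():
            expected = outcome(row["player_choice"], row["opponent_choice"])
            if row["outcome"] != expected or int(row["reward"]) != reward_of(expected):
                raise ValueError(f"inconsistent play-log row {i + 1}")
        if list(log["trial"]) != list(range(1, len(log) + 1)):
            raise ValueError("trial numbers must run consecutively from 1")
    return log


def block_win_rates(
    log: pd.DataFrame, window: int = 200, block_size: int = 10
) -> pd.DataFrame:
    """Win/tie/loss rates per block over the final ``window`` trials."""
    if len(log) < window:
        raise ValueError(f"play log has {len(log)} trials; need >= {window}")
    if window % block_size:
        raise ValueError("window must be a whole number of blocks")
    tail = log.iloc[-window:].reset_index(drop=True)
    rows = []
    for b in range(window // block_size):
        chunk = tail.iloc[b * block_size : (b + 1) * block_size]
        rows.append(
            (
                b + 1,
                (chunk["outcome"] == "win").mean(),
                (chunk["outcome"] == "tie").mean(),
                (chunk["outcome"] == "loss").mean(),
            )
        )
    return pd.DataFrame(rows, columns=["block", "win_rate", "tie_rate", "loss_rate"])


@dataclass
class GroupSpec:
    """Parameter population for a simulated participant group.

    ``n_freqs`` gives relative frequencies for the STM length; ``h_thr`` and
    ``alpha`` are drawn from normals with the given means/SDs and clipped to
    their valid ranges ([0, 3] and [0, 1]).
    """

    name: str
    model: str = "relph"
    size: int = 12
    n_freqs: Mapping[int, float] = field(default_factory=lambda: {1: 2, 2: 7, 3: 3})
    h_thr_mean: float = 2.28
    h_thr_sd: float = 0.82
    alpha_mean: float = 0.27
    alpha_sd: float = 0.22
    tau: float = 1.0

    def __post_init__(self) -> None:
        if self.size < 1:
            raise ValueError("group size must be >= 1")
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}")


def hc_like(size: int = 12) -> GroupSpec:
    """Healthy-control-like soft-max RELPH group."""
    return GroupSpec(name="hc_like", model="relph", size=size)


def lbd_like(size: int = 10) -> GroupSpec:
    """LBD-like group: greedy choice, all other parameters as HC."""
    return GroupSpec(name="lbd_like", model="relph-greedy", size=size)


def rbd_like(size: int = 14) -> GroupSpec:
    """RBD-like group: lower pruning threshold, higher learning rate."""
    return GroupSpec(
        name="rbd_like",
        model="relph",
        size=size,
        n_freqs={1: 3, 2: 8, 3: 3},
        h_thr_mean=1.35,
        h_thr_sd=1.01,
        alpha_mean=0.42,
        alpha_sd=0.20,
    )


def sample_group_params(
    spec: GroupSpec, rng: np.random.Generator
) -> list[ElphParams | RelphParams]:
    """Draw per-agent parameters for a group."""
    ns = sorted(spec.n_freqs)
    w = np.array([spec.n_freqs[k] for k in ns], dtype=float)
    w /= w.sum()
    out: list[ElphParams | RelphParams] = []
    for _ in range(spec.size):
        n = int(rng.choice(ns, p=w))
        h = float(np.clip(rng.normal(spec.h_thr_mean, spec.h_thr_sd), 0.0, 3.0))
        if spec.model == "elph":
            out.append(ElphParams(n=n, h_thr=h))
        else:
            a = float(np.clip(rng.normal(spec.alpha_mean, spec.alpha_sd), 0.0, 1.0))
            out.append(
                RelphParams(
                    n=n,
                    h_thr=h,
                    alpha=a,
                    tau=spec.tau,
                    greedy=(spec.model == "relph-greedy"),
                )
            )
    return out


@dataclass
class CohortResult:
    """Per-agent logs and summaries, plus the group mean/SEM per block."""

    spec: GroupSpec
    params: list
    logs: list[pd.DataFrame]
    blocks: pd.DataFrame  # per-agent block summaries, 'agent' column
    group: pd.DataFrame  # block, mean_win_rate, sem_win_rate


def summarize_cohort_blocks(blocks: pd.DataFrame) -> pd.DataFrame:
    """Group mean and SEM of the block win rates (SEM = SD / sqrt(size))."""
    g = blocks.groupby("block")["win_rate"]
    size = blocks["agent"].nunique()
    out = pd.DataFrame(
        {
            "block": sorted(blocks["block"].unique()),
            "mean_win_rate": g.mean().values,
            "sem_win_rate": (g.std(ddof=1) / np.sqrt(size)).values
            if size > 1
            else np.zeros(blocks["block"].nunique()),
        }
    )
    return out


def simulate_cohort(
    spec: GroupSpec,
    schedule: OpponentSchedule | None = None,
    seed: int = 0,
    window: int = 200,
) -> CohortResult:
    """Simulate a full participant group against the scheduled opponent."""
    if schedule is None:
        schedule = default_schedule()
    ss = np.random.SeedSequence(seed)
    param_rng = np.random.default_rng(ss.spawn(1)[0])
    params = sample_group_params(spec, param_rng)
    game_seeds = ss.generate_state(spec.size)
    logs, block_frames = [], []
    for i, (p, gs) in enumerate(zip(params, game_seeds)):
        log = run_game(spec.model, p, schedule=schedule, seed=int(gs))
        logs.append(log)
        b = block_win_rates(log, window=min(window, len(log)))
        b.insert(0, "agent", i)
        block_frames.append(b)
    blocks = pd.concat(block_frames, ignore_index=True)
    return CohortResult(
        spec=spec, params=params, logs=logs, blocks=blocks,
        group=summarize_cohort_blocks(blocks),
    )
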