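"""Rock-Paper-Scissors game rules and the scheduled non-stationary opponent.

The opponent emulated here is the computer player of the behavioural task the
models were built for: 600 trials in three 200-trial phases -- uniform play,
a light bias (rock half the time), then a heavy bias (paper 80% of the time).
Residual probability mass in the biased phases is split evenly over the
remaining symbols.  Draws are i.i.d. within a phase; the opponent never
reacts to the player.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .core import RPS_ALPHABET

# key beats value
BEATS: dict[str, str] = {"rock": "scissors", "scissors": "paper", "paper": "rock"}
# counter_of[x] is the symbol that beats x
COUNTER: dict[str, str] = {beaten: beater for beater, beaten in BEATS.items()}

WIN, TIE, LOSS = "win", "tie", "loss"
OUTCOMES: tuple[str, ...] = (WIN, TIE, LOSS)
REWARD_OF_OUTCOME: dict[str, int] = {WIN: 1, TIE: 0, LOSS: -1}
OUTCOME_OF_REWARD: dict[int, str] = {1: WIN, 0: TIE, -1: LOSS}


def _check_symbol(symbol: str) -> None:
    if symbol not in RPS_ALPHABET:
        raise ValueError(f"{symbol!r} is not a Rock-Paper-Scissors symbol")


def counter_of(symbol: str) -> str:
    """The unique symbol that beats ``symbol``."""
    _check_symbol(symbol)
    return COUNTER[symbol]


def outcome(player: str, opponent: str) -> str:
    """RPS dominance from the player's perspective: 'win', 'tie' or 'loss'."""
    _check_symbol(player)
    _check_symbol(opponent)
    if player == opponent:
        return TIE
    return WIN if BEATS[player] == opponent else LOSS


def reward_of(result: str) -> int:
    """Reward mapping: win -> +1, tie -> 0, loss -> -1."""
    if result not in REWARD_OF_OUTCOME:
        raise ValueError(f"{result!r} is not an outcome")
    return REWARD_OF_OUTCOME[result]


@dataclass(frozen=True)
class PhaseSpec:
    """One stationary stretch of opponent play."""

    length: int
    distribution: tuple[tuple[str, float], ...]

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("phase length must be >= 1")
        probs = dict(self.distribution)
        if any(p < 0 for p in probs.values()):
            raise ValueError("phase probabilities must be non-negative")
        if abs(sum(probs.values()) - 1.0) > 1e-9:
            raise ValueError("phase probabilities must sum to 1")

    @classmethod
    def from_mapping(cls, length: int, dist: Mapping[str, float]) -> "PhaseSpec":
        return cls(length=length, distribution=tuple(sorted(dist.items())))

    def prob(self, symbol: str) -> float:
        return dict(self.distribution).get(symbol, 0.0)


@dataclass(frozen=True)
class OpponentSchedule:
    """Ordered phases concatenated into one opponent strategy."""

    phases: tuple[PhaseSpec, ...]

    def __post_init__(self) -> None:
        if not self.phases:
            raise ValueError("schedule needs at least one phase")

    @property
    def total_trials(self) -> int:
        return sum(p.length for p in self.phases)

    def phase_of(self, trial: int) -> int:
        """1-based phase index of a 1-based trial number."""
        if not 1 <= trial <= self.total_trials:
            raise ValueError(f"trial {trial} outside schedule")
        upto = 0
        for i, p in enumerate(self.phases, start=1):
            upto += p.length
            if trial <= upto:
                return i
        raise AssertionError("unreachable")

    def phase_indices(self) -> np.ndarray:
        """Per-trial 1-based phase index, length ``total_trials``."""
        return np.repeat(
            np.arange(1, len(self.phases) + 1),
            [p.length for p in self.phases],
        )


def default_schedule() -> OpponentSchedule:
    """The three-phase, 600-trial task schedule.

    200 uniform trials, then 200 with rock at probability one half, then 200
    with paper at probability 0.8; leftover mass split evenly.
    """
    return OpponentSchedule(
        phases=(
            PhaseSpec.from_mapping(200, {"rock": 1 / 3, "paper": 1 / 3, "scissors": 1 / 3}),
            PhaseSpec.from_mapping(200, {"rock": 0.5, "paper": 0.25, "scissors": 0.25}),
            PhaseSpec.from_mapping(200, {"rock": 0.1, "paper": 0.8, "scissors": 0.1}),
        )
    )


def stationary_bias_schedule(
    length: int = 200, symbol: str = "paper", bias: float = 0.8
) -> OpponentSchedule:
    """A single stationary phase with ``symbol`` at probability ``bias``."""
    _check_symbol(symbol)
    rest = (1.0 - bias) / (len(RPS_ALPHABET) - 1)
    dist = {s: (bias if s == symbol else rest) for s in RPS_ALPHABET}
    return OpponentSchedule(phases=(PhaseSpec.from_mapping(length, dist),))


def generate_opponent_sequence(
    schedule: OpponentSchedule,
    seed: int | np.random.SeedSequence | None = None,
    rng: np.random.Generator | None = None,
) -> list[str]:
    """Draw the full opponent symbol sequence, i.i.d. within each phase."""
    if rng is None:
        rng = np.random.default_rng(seed)
    out: list[str] = []
    for phase in schedule.phases:
        symbols = [s for s, _ in phase.distribution]
        probs = np.array([p for _, p in phase.distribution], dtype=float)
        draws = rng.choice(len(symbols), size=phase.length, p=probs / probs.sum())
        out.extend(symbols[i] for i in draws)
    return out
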