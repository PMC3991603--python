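"""RELPH: the reinforcement-learning variant of the hypothesis-space learner.

RELPH shares ELPH's memory architecture -- the STM context and the lattice of
subset hypotheses -- but its prediction-sets store the *cumulative reward* of
the agent's own plays in that context rather than counts of opponent symbols,
and each hypothesis carries a delta-rule value V estimating its expected
reward.  Choice is a two-stage soft-max: first over hypothesis values, then
over the per-action reward totals within the chosen hypothesis (actions never
tried in a context count as total 0, so exploration can reach them).  Setting
``greedy=True`` "turns off" the soft-max and takes strict argmaxes, the
probability-maximising regime used to account for left-brain-damaged play.

Pruning mirrors ELPH but scores the *outcome* entropy -- the regularised
entropy of the hypothesis's win/tie/loss tallies -- so hypotheses with
inconsistent payoffs are discarded.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Callable, Iterable

import numpy as np

from .core import (
    RPS_ALPHABET,
    ContextPattern,
    HypothesisRecord,
    HypothesisSpace,
    STMBuffer,
    generate_candidates,
)
from .elph import modified_entropy
from .environment import OUTCOME_OF_REWARD, outcome, reward_of

VALUE_INIT_SCALE = 0.01  # half-width of the random initial hypothesis value


@dataclass
class RelphParams:
    """STM capacity, outcome-entropy threshold, learning rate, temperature."""

    n: int = 2
    h_thr: float = 2.28
    alpha: float = 0.27
    tau: float = 1.0
    greedy: bool = False

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("STM capacity n must be >= 1")
        if self.h_thr < 0:
            raise ValueError("entropy threshold must be >= 0")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("learning rate alpha must lie in [0, 1]")
        if not self.greedy and self.tau <= 0:
            raise ValueError("soft-max temperature must be positive")


def delta_update(v: float, r: float, alpha: float) -> float:
    """Delta (Rescorla-Wagner) rule: V <- V + alpha * (r - V)."""
    return v + alpha * (r - v)


def init_value(pattern: ContextPattern, seed: int) -> float:
    """Random initial hypothesis value, uniform on [-0.01, +0.01].

    The draw is a deterministic function of (pattern, seed), so initial
    values do not depend on the order in which hypotheses are first created.
    """
    key = f"{seed}|" + ";".join(f"{o}:{s}" for o, s in pattern.bindings)
    h = hashlib.blake2b(key.encode(), digest_size=8).digest()
    u = int.from_bytes(h, "big") / 2.0**64
    return (2.0 * u - 1.0) * VALUE_INIT_SCALE


def outcome_entropy(record: HypothesisRecord) -> float:
    """Regularised entropy of the win/tie/loss tallies, in bits."""
    counts = {k: v for k, v in record.outcome_counts.items() if v > 0}
    if not counts:
        raise ValueError("outcome entropy undefined for all-zero counts")
    return modified_entropy(counts)


def relph_update(
    hs: HypothesisSpace,
    stm: STMBuffer,
    played: str,
    reward: float,
    alpha: float,
    init_value_fn: Callable[[ContextPattern], float] | None = None,
) -> None:
    """Credit the (play, reward) pair to every candidate pattern of the STM."""
    for pattern in generate_candidates(stm):
        fresh = pattern not in hs
        rec = hs.lookup_or_insert(pattern)
        if fresh and init_value_fn is not None:
            rec.value = init_value_fn(pattern)
        rec.pset[played] = rec.pset.get(played, 0.0) + reward
        label = OUTCOME_OF_REWARD[int(reward)]
        rec.outcome_counts[label] = rec.outcome_counts.get(label, 0) + 1
        rec.value = delta_update(rec.value, reward, alpha)


def relph_prune(hs: HypothesisSpace, h_thr: float) -> int:
    """Delete every record whose outcome entropy exceeds ``h_thr``."""
    return hs.prune(lambda rec: outcome_entropy(rec) <= h_thr)


def _prune_patterns(
    hs: HypothesisSpace, h_thr: float, patterns: Iterable[ContextPattern]
) -> None:
    for p in patterns:
        if p in hs and outcome_entropy(hs[p]) > h_thr:
            hs.remove(p)


def softmax_weights(x: np.ndarray, tau: float) -> np.ndarray:
    """Soft-max with temperature; numerically stable."""
    z = np.asarray(x, dtype=float) / tau
    z = z - z.max()
    w = np.exp(z)
    return w / w.sum()


def greedy_weights(x: np.ndarray) -> np.ndarray:
    """Uniform over the exact argmax set (ties split evenly)."""
    x = np.asarray(x, dtype=float)
    w = (x == x.max()).astype(float)
    return w / w.sum()


def relph_choice_distribution(
    hs: HypothesisSpace,
    stm: STMBuffer,
    params: RelphParams,
    alphabet: tuple[str, ...] = RPS_ALPHABET,
) -> np.ndarray:
    """Probability of each own play under the two-stage (soft-)max rule."""
    cands = sorted(generate_candidates(stm), key=lambda q: q.bindings)
    recs = [hs[p] for p in cands if p in hs]
    m = len(alphabet)
    if not recs:
        return np.full(m, 1.0 / m)
    values = np.array([r.value for r in recs])
    if params.greedy:
        w = greedy_weights(values)
    else:
        w = softmax_weights(values, params.tau)
    dist = np.zeros(m)
    for wi, rec in zip(w, recs):
        totals = np.array([rec.pset.get(s, 0.0) for s in alphabet])
        if params.greedy:
            inner = greedy_weights(totals)
        else:
            inner = softmax_weights(totals, params.tau)
        dist += wi * inner
    return dist


def relph_choose(
    hs: HypothesisSpace,
    stm: STMBuffer,
    params: RelphParams,
    rng: np.random.Generator,
    alphabet: tuple[str, ...] = RPS_ALPHABET,
) -> str:
    """Sample the next play."""
    dist = relph_choice_distribution(hs, stm, params, alphabet)
    return alphabet[int(rng.choice(len(alphabet), p=dist))]


class RELPHAgent:
    """One simulated RELPH player.

    Per trial: choose a play from the current HS/STM, observe the opponent,
    convert the outcome to a reward, update prediction-sets / outcome tallies
    / values, prune by outcome entropy, then shift the opponent's symbol into
    the STM (the context is the same "situation" ELPH sees; only the
    prediction target differs).
    """

    def __init__(
        self,
        params: RelphParams,
        alphabet: tuple[str, ...] = RPS_ALPHABET,
        seed: int | np.random.SeedSequence | None = None,
        value_seed: int | None = None,
    ) -> None:
        self.params = params
        self.alphabet = tuple(alphabet)
        ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
        self.rng = np.random.default_rng(ss)
        self._value_seed = (
            int(ss.generate_state(1)[0]) if value_seed is None else int(value_seed)
        )
        self.hs = HypothesisSpace()
        self.stm = STMBuffer(params.n)

    def _init_value_fn(self, pattern: ContextPattern) -> float:
        return init_value(pattern, self._value_seed)

    def choice_distribution(self) -> np.ndarray:
        return relph_choice_distribution(self.hs, self.stm, self.params, self.alphabet)

    def observe(self, played: str, opponent_symbol: str) -> tuple[str, int]:
        """Teacher-forcible transition given a (possibly recorded) play."""
        result = outcome(played, opponent_symbol)
        r = reward_of(result)
        cands = generate_candidates(self.stm)
        for pattern in cands:
            fresh = pattern not in self.hs
            rec = self.hs.lookup_or_insert(pattern)
            if fresh:
                rec.value = self._init_value_fn(pattern)
            rec.pset[played] = rec.pset.get(played, 0.0) + float(r)
            label = OUTCOME_OF_REWARD[r]
            rec.outcome_counts[label] = rec.outcome_counts.get(label, 0) + 1
            rec.value = delta_update(rec.value, float(r), self.params.alpha)
        _prune_patterns(self.hs, self.params.h_thr, cands)
        self.stm.push(opponent_symbol)
        return result, r

    def step(self, opponent_symbol: str) -> tuple[str, str, int]:
        """Play one trial; returns (played, outcome, reward)."""
        dist = self.choice_distribution()
        played = self.alphabet[int(self.rng.choice(len(self.alphabet), p=dist))]
        result, r = self.observe(played, opponent_symbol)
        return played, result, r
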