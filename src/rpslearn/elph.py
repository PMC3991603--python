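"""ELPH: the statistical sequence learner.

ELPH predicts the opponent's next symbol.  Each hypothesis keeps a
prediction-set of observation counts; its trustworthiness is scored by a
pseudo-count-regularised ("reliable") entropy, which penalises hypotheses
with little evidence.  Prediction is a two-stage sample -- first a hypothesis
(low entropy preferred, weight proportional to exp(-H)), then a symbol within
it (probability proportional to its count).  Hypotheses whose entropy exceeds
the threshold ``H_thr`` are deleted at the end of every trial, which is what
lets the learner shed stale structure when the opponent's strategy shifts.

As a game player, ELPH converts the predicted opponent symbol into the unique
counter-symbol that beats it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

from .core import (
    RPS_ALPHABET,
    ContextPattern,
    HypothesisRecord,
    HypothesisSpace,
    STMBuffer,
    generate_candidates,
)
from .environment import BEATS, outcome, reward_of


@dataclass
class ElphParams:
    """STM capacity ``n`` and pruning threshold ``h_thr`` in bits."""

    n: int = 2
    h_thr: float = 1.0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("STM capacity n must be >= 1")
        if self.h_thr < 0:
            raise ValueError("entropy threshold must be >= 0")


def modified_entropy(counts: Mapping[str, float] | Iterable[float]) -> float:
    """Reliable (pseudo-count-regularised) Shannon entropy, in bits.

    One phantom count of 1 is appended to the multiset of counts and the
    augmented distribution is normalised by N + 1, where N is the raw total.
    The phantom mass keeps low-evidence hypotheses from looking spuriously
    certain: a single observation scores a full bit, and the entropy of a
    pure set {c} decays to 0 only as c grows.
    """
    if isinstance(counts, Mapping):
        vals = [float(v) for v in counts.values()]
    else:
        vals = [float(v) for v in counts]
    if not vals:
        raise ValueError("entropy of an empty prediction-set is undefined")
    if any(v <= 0 for v in vals):
        raise ValueError("prediction-set counts must be positive")
    vals.append(1.0)
    total = sum(vals)
    return -sum(c / total * math.log2(c / total) for c in vals)


def elph_update(hs: HypothesisSpace, stm: STMBuffer, observed: str) -> None:
    """Credit ``observed`` to every candidate pattern of the current STM."""
    for pattern in generate_candidates(stm):
        rec = hs.lookup_or_insert(pattern)
        rec.pset[observed] = rec.pset.get(observed, 0.0) + 1.0


def elph_prune(hs: HypothesisSpace, h_thr: float) -> int:
    """Delete every record whose prediction-set entropy exceeds ``h_thr``."""
    return hs.prune(lambda rec: modified_entropy(rec.pset) <= h_thr)


def _prune_patterns(
    hs: HypothesisSpace, h_thr: float, patterns: Iterable[ContextPattern]
) -> None:
    # Only hypotheses updated this trial can have changed entropy, so the
    # per-trial pass is restricted to them; equivalent to a full scan.
    for p in patterns:
        if p in hs and modified_entropy(hs[p].pset) > h_thr:
            hs.remove(p)


def _matching_records(
    hs: HypothesisSpace, stm: STMBuffer
) -> list[HypothesisRecord]:
    return [hs[p] for p in sorted(generate_candidates(stm), key=lambda q: q.bindings) if p in hs]


def elph_predict_distribution(
    hs: HypothesisSpace,
    stm: STMBuffer,
    alphabet: tuple[str, ...] = RPS_ALPHABET,
) -> np.ndarray:
    """Probability of each alphabet symbol being the opponent's next play.

    Mixture over the candidate hypotheses present in HS: hypothesis weights
    proportional to exp(-H), symbol probabilities within a hypothesis
    proportional to its counts.  With no matching hypothesis the fallback is
    uniform.
    """
    recs = _matching_records(hs, stm)
    m = len(alphabet)
    if not recs:
        return np.full(m, 1.0 / m)
    ent = np.array([modified_entropy(r.pset) for r in recs])
    w = np.exp(-(ent - ent.min()))
    w /= w.sum()
    idx = {s: i for i, s in enumerate(alphabet)}
    dist = np.zeros(m)
    for wi, rec in zip(w, recs):
        total = sum(rec.pset.values())
        for sym, c in rec.pset.items():
            dist[idx[sym]] += wi * c / total
    return dist


def elph_predict(
    hs: HypothesisSpace,
    stm: STMBuffer,
    rng: np.random.Generator,
    alphabet: tuple[str, ...] = RPS_ALPHABET,
) -> str:
    """Sample a prediction of the opponent's next symbol."""
    dist = elph_predict_distribution(hs, stm, alphabet)
    return alphabet[int(rng.choice(len(alphabet), p=dist))]


class ELPHAgent:
    """One simulated ELPH player.

    Per trial: predict the opponent's symbol from the current HS/STM, play
    the counter-symbol, observe the opponent's actual play, update all
    candidate hypotheses with it, prune, then shift the STM.
    """

    def __init__(
        self,
        params: ElphParams,
        alphabet: tuple[str, ...] = RPS_ALPHABET,
        seed: int | np.random.SeedSequence | None = None,
    ) -> None:
        self.params = params
        self.alphabet = tuple(alphabet)
        self.rng = np.random.default_rng(seed)
        self.hs = HypothesisSpace()
        self.stm = STMBuffer(params.n)
        self._idx = {s: i for i, s in enumerate(self.alphabet)}

    def predict_distribution(self) -> np.ndarray:
        return elph_predict_distribution(self.hs, self.stm, self.alphabet)

    def choice_distribution(self) -> np.ndarray:
        """Probability of each own play: the counter of the prediction."""
        pred = self.predict_distribution()
        out = np.empty_like(pred)
        for i, sym in enumerate(self.alphabet):
            # play `sym` exactly when predicting the symbol `sym` beats
            out[i] = pred[self._idx[BEATS[sym]]]
        return out

    def observe(self, opponent_symbol: str) -> None:
        """Teacher-forcible state transition: update, prune, shift STM."""
        cands = generate_candidates(self.stm)
        for pattern in cands:
            rec = self.hs.lookup_or_insert(pattern)
            rec.pset[opponent_symbol] = rec.pset.get(opponent_symbol, 0.0) + 1.0
        _prune_patterns(self.hs, self.params.h_thr, cands)
        self.stm.push(opponent_symbol)

    def step(self, opponent_symbol: str) -> tuple[str, str, int]:
        """Play one trial; returns (played, outcome, reward)."""
        dist = self.choice_distribution()
        played = self.alphabet[int(self.rng.choice(len(self.alphabet), p=dist))]
        result = outcome(played, opponent_symbol)
        self.observe(opponent_symbol)
        return played, result, reward_of(result)
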