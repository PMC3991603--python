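"""Shared memory architecture for entropy-pruned hypothesis-space learners.

Both learners in this package (the statistical learner ELPH and its
reinforcement variant RELPH) share one memory layout: a short-term memory
(STM) holding the ``n`` most recent symbols, and a hypothesis space (HS)
mapping *context patterns* -- partial bindings of STM slots to concrete
symbols -- to bookkeeping records.  A context pattern is the identity of a
hypothesis: "whenever the recent history matched this binding, here is what
followed" (ELPH) or "here is how my own plays paid off" (RELPH).

The containers are alphabet-generic; Rock-Paper-Scissors is simply the
default three-symbol alphabet.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Iterator, Mapping

RPS_ALPHABET: tuple[str, ...] = ("rock", "paper", "scissors")


@dataclass(frozen=True)
class ContextPattern:
    """A partial binding of STM slots to concrete symbols.

    ``bindings`` is a tuple of ``(offset, symbol)`` pairs sorted by offset.
    Offsets count backwards from the upcoming trial: offset 1 is the most
    recent observation (t-1), offset 2 the one before (t-2), and so on.
    Offsets absent from the binding are wildcards.  Patterns compare and hash
    by content, so two patterns are equal iff they bind the same slots to the
    same symbols.
    """

    bindings: tuple[tuple[int, str], ...]

    def __post_init__(self) -> None:
        if not self.bindings:
            raise ValueError("a context pattern must bind at least one slot")
        offsets = [o for o, _ in self.bindings]
        if any(o < 1 for o in offsets):
            raise ValueError("STM offsets are 1-based (1 = most recent)")
        if sorted(set(offsets)) != offsets:
            raise ValueError("bindings must be sorted by offset, no duplicates")

    @classmethod
    def from_mapping(cls, slots: Mapping[int, str]) -> "ContextPattern":
        return cls(tuple(sorted(slots.items())))

    @property
    def offsets(self) -> tuple[int, ...]:
        return tuple(o for o, _ in self.bindings)

    def symbol_at(self, offset: int) -> str | None:
        for o, s in self.bindings:
            if o == offset:
                return s
        return None

    def order(self) -> int:
        """Number of concretely bound slots."""
        return len(self.bindings)

    def __str__(self) -> str:  # pragma: no cover - debugging aid
        return "(" + ", ".join(f"{s}@t-{o}" for o, s in self.bindings) + ")"


class STMBuffer:
    """Sliding window over the most recent observed symbols.

    Holds at most ``capacity`` symbols; pushing a new one evicts the oldest
    once full.  Offset 1 addresses the most recent symbol.
    """

    def __init__(self, capacity: int, contents: Iterable[str] = ()) -> None:
        if capacity < 1:
            raise ValueError("STM capacity must be >= 1")
        self.capacity = int(capacity)
        self._items: list[str] = list(contents)[-self.capacity:]

    def push(self, symbol: str) -> None:
        self._items.append(symbol)
        if len(self._items) > self.capacity:
            del self._items[0]

    def __len__(self) -> int:
        return len(self._items)

    @property
    def contents(self) -> tuple[str, ...]:
        """Symbols in temporal order, oldest first."""
        return tuple(self._items)

    def symbol_at(self, offset: int) -> str:
        """Symbol at backward offset (1 = most recent)."""
        if not 1 <= offset <= len(self._items):
            raise IndexError(f"offset {offset} outside occupied STM slots")
        return self._items[-offset]


def generate_candidates(stm: STMBuffer) -> set[ContextPattern]:
    """All ``2**k - 1`` non-empty subset patterns of the current STM.

    Every subset of the occupied STM slots is a candidate predictor of the
    next observation; each candidate binds its slots to the symbols currently
    sitting there.  An empty STM yields no candidates (the caller falls back
    to uniform play).
    """
    k = len(stm)
    out: set[ContextPattern] = set()
    for r in range(1, k + 1):
        for offs in combinations(range(1, k + 1), r):
            out.add(ContextPattern(tuple((o, stm.symbol_at(o)) for o in offs)))
    return out


@dataclass
class HypothesisRecord:
    """Per-hypothesis bookkeeping.

    ``pset`` is the prediction-set: symbol -> observation count (ELPH) or
    symbol -> cumulative reward (RELPH).  ``value`` and ``outcome_counts``
    are used by RELPH only: the delta-rule estimate of the hypothesis's
    expected reward, and win/tie/loss tallies for outcome-entropy pruning.
    """

    pattern: ContextPattern
    pset: dict[str, float] = field(default_factory=dict)
    value: float = 0.0
    outcome_counts: dict[str, int] = field(default_factory=dict)


class HypothesisSpace:
    """Map from context pattern to its record, with no duplicate patterns."""

    def __init__(self) -> None:
        self._records: dict[ContextPattern, HypothesisRecord] = {}

    def __len__(self) -> int:
        return len(self._records)

    def __contains__(self, pattern: ContextPattern) -> bool:
        return pattern in self._records

    def __getitem__(self, pattern: ContextPattern) -> HypothesisRecord:
        return self._records[pattern]

    def __iter__(self) -> Iterator[ContextPattern]:
        return iter(self._records)

    def records(self) -> list[HypothesisRecord]:
        return list(self._records.values())

    def lookup_or_insert(
        self, pattern: ContextPattern, init_value: float = 0.0
    ) -> HypothesisRecord:
        """Return the existing record, or insert and return a fresh one."""
        rec = self._records.get(pattern)
        if rec is None:
            rec = HypothesisRecord(pattern=pattern, value=init_value)
            self._records[pattern] = rec
        return rec

    def remove(self, pattern: ContextPattern) -> None:
        del self._records[pattern]

    def prune(self, keep) -> int:
        """Drop records for which ``keep(record)`` is false; return count."""
        doomed = [p for p, r in self._records.items() if not keep(r)]
        for p in doomed:
            del self._records[p]
        return len(doomed)
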