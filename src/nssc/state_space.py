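"""Lineage-configuration state spaces of the structured coalescent.

The ancestral history of ``k`` sampled lineages in an ``n``-deme structured
population is a continuous-time Markov chain on occupancy vectors
``alpha = (alpha_1, ..., alpha_n)``, where ``alpha_i`` counts the
un-coalesced ancestral lineages currently in deme ``i``, together with an
absorbing state ``c`` marking the first coalescence (for a pair, the MRCA).
This module enumerates those states in a fixed canonical order and provides
the index map used to address rate-matrix entries.

Ordering convention: states are grouped by descending total lineage count
``|alpha|`` and sorted inverse-lexicographically within each group, with the
absorbing state strictly last.  For ``k = 2, n = 3`` this gives::

    (2,0,0) < (1,1,0) < (1,0,1) < (0,2,0) < (0,1,1) < (0,0,2) < c
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

from .errors import ConfigError

__all__ = [
    "LineageConfiguration",
    "StateSpace",
    "enumerate_states",
    "ordered_pair_state_count",
]

COALESCED = "c"


@dataclass(frozen=True)
class LineageConfiguration:
    """One state of the ancestral lineage process.

    Either an occupancy vector over the ``n`` demes, or the absorbing
    coalesced marker (which carries no counts).
    """

    counts: tuple[int, ...] | None
    is_coalesced: bool = False

    def __post_init__(self) -> None:
        if self.is_coalesced:
            if self.counts is not None:
                raise ConfigError("coalesced state carries no occupancy counts")
        else:
            if self.counts is None:
                raise ConfigError("non-coalesced state needs occupancy counts")
            if any(a < 0 for a in self.counts):
                raise ConfigError(f"negative occupancy in {self.counts}")
            if self.total <= 1:
                raise ConfigError(
                    f"{self.counts}: fewer than two lineages is the absorbed state"
                )

    @classmethod
    def coalesced(cls) -> "LineageConfiguration":
        return cls(counts=None, is_coalesced=True)

    @classmethod
    def from_counts(cls, counts: Sequence[int]) -> "LineageConfiguration":
        return cls(counts=tuple(int(a) for a in counts))

    @classmethod
    def same_deme(cls, n: int, deme: int = 0, k: int = 2) -> "LineageConfiguration":
        """All ``k`` lineages sampled in one deme (0-based index)."""
        counts = [0] * n
        counts[deme] = k
        return cls.from_counts(counts)

    @classmethod
    def different_demes(cls, n: int, demes: Sequence[int] = (0, 1)) -> "LineageConfiguration":
        """One lineage in each listed deme (0-based indices, repeats allowed)."""
        counts = [0] * n
        for d in demes:
            counts[d] += 1
        return cls.from_counts(counts)

    @property
    def total(self) -> int:
        """Number of un-coalesced lineages ``|alpha|``."""
        return 0 if self.is_coalesced else sum(self.counts)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return COALESCED if self.is_coalesced else str(self.counts)


def _compositions(total: int, parts: int) -> Iterator[tuple[int, ...]]:
    """All vectors of `parts` non-negative ints summing to `total`."""
    if parts == 1:
        yield (total,)
        return
    for first in range(total, -1, -1):
        for rest in _compositions(total - first, parts - 1):
            yield (first,) + rest


@dataclass
class StateSpace:
    """Ordered state set ``E_{k,n}`` with its 1-based index map ``phi``."""

    k: int
    n: int
    states: list[LineageConfiguration]
    _index0: dict[LineageConfiguration, int] = field(repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        if not self._index0:
            self._index0 = {s: i for i, s in enumerate(self.states)}

    def __len__(self) -> int:
        return len(self.states)

    def __iter__(self) -> Iterator[LineageConfiguration]:
        return iter(self.states)

    @property
    def n_c(self) -> int:
        """1-based position of the absorbing state (always last)."""
        return len(self.states)

    def index_of(self, state: LineageConfiguration) -> int:
        """1-based position ``phi(state)`` in the canonical order."""
        return self.index0(state) + 1

    def index0(self, state: LineageConfiguration) -> int:
        """0-based position, for array addressing."""
        state = self._coerce(state)
        try:
            return self._index0[state]
        except KeyError:
            raise ConfigError(f"state {state!r} not in E_{{{self.k},{self.n}}}") from None

    def _coerce(self, state) -> LineageConfiguration:
        if isinstance(state, LineageConfiguration):
            return state
        if state == COALESCED:
            return LineageConfiguration.coalesced()
        return LineageConfiguration.from_counts(state)


def enumerate_states(k: int, n: int) -> StateSpace:
    """Enumerate ``E_{k,n}``: every occupancy vector with ``1 < |alpha| <= k``
    plus the absorbing coalesced state, in the canonical order.

    Parameters
    ----------
    k : int
        Sample size (number of lineages at time zero), ``k >= 2``.
    n : int
        Number of demes, ``n >= 1``.
    """
    if not isinstance(k, (int,)) or isinstance(k, bool) or k < 2:
        raise ConfigError(f"sample size k must be an integer >= 2, got {k!r}")
    if not isinstance(n, (int,)) or isinstance(n, bool) or n < 1:
        raise ConfigError(f"deme count n must be an integer >= 1, got {n!r}")

    states: list[LineageConfiguration] = []
    for total in range(k, 1, -1):  # descending |alpha| blocks
        block = sorted(_compositions(total, n), reverse=True)  # inverse lex
        states.extend(LineageConfiguration.from_counts(a) for a in block)
    states.append(LineageConfiguration.coalesced())
    return StateSpace(k=k, n=n, states=states)


def ordered_pair_state_count(n: int) -> int:
    """Size ``n**2 + 1`` of the k=2 chain in the ordered-pair convention.

    Diagnostic only: computation here uses the (smaller) occupancy-vector
    convention, whose k=2 chain has ``n(n+1)/2 + 1`` states.  Both
    conventions yield identical coalescence-time distributions because the
    transition rates depend only on occupancy counts.
    """
    if not isinstance(n, int) or isinstance(n, bool) or n < 1:
        raise ConfigError(f"deme count n must be an integer >= 1, got {n!r}")
    return n * n + 1
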