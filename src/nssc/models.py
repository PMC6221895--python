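"""Structured demographic models and piecewise-constant scenarios.

A stationary model (one "epoch") is a vector of relative deme sizes
``c_i`` (haploid deme size ``2 c_i N``) and a matrix of scaled backward
migration rates ``M_ij`` (each lineage in deme i jumps to deme j at rate
``M_ij / 2``, time in units of ``2N`` generations).  A non-stationary
scenario is an ordered list of epochs with strictly increasing change
times, the deme count ``n`` held fixed so that the state space — and hence
the size of every transition rate matrix — never changes.

Canonical builders are provided for the n-island, 2D stepping-stone
(bounded or torus) and continent-island models, together with the
hand-reduced symmetry-lumped rate matrices for the n-island (3 states:
same deme / different demes / coalesced) and continent-island (5 states)
chains, and the packaged human/Neanderthal scenario pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError
from .kernel import RateMatrix

__all__ = [
    "ModelEpoch",
    "PiecewiseScenario",
    "TimeScaling",
    "n_island",
    "stepping_stone_2d",
    "continent_island",
    "conservation_residual",
    "reduced_n_island",
    "reduced_continent_island",
    "make_scenario",
    "human_neanderthal_fixture",
    "scale_time",
]


@dataclass
class ModelEpoch:
    """One stationary structured model: deme sizes and migration matrix.

    ``migration[i, j] = M_ij`` (scaled); the per-lineage jump rate i→j is
    ``M_ij / 2``.  The diagonal is ignored and stored as zero.  Deme sizes
    are positive reals (the continuous-time chain is well defined for any
    positive size, not just integers).
    """

    deme_sizes: np.ndarray
    migration: np.ndarray

    def __post_init__(self) -> None:
        self.deme_sizes = np.asarray(self.deme_sizes, dtype=float)
        self.migration = np.array(self.migration, dtype=float)
        n = self.deme_sizes.shape[0]
        if self.deme_sizes.ndim != 1 or n < 1:
            raise ConfigError("deme_sizes must be a non-empty 1-d vector")
        if np.any(self.deme_sizes <= 0):
            raise ConfigError("all deme sizes must be strictly positive")
        if self.migration.shape != (n, n):
            raise ConfigError(
                f"migration matrix must be {n}x{n}, got {self.migration.shape}"
            )
        np.fill_diagonal(self.migration, 0.0)
        if np.any(self.migration < 0):
            raise ConfigError("migration rates must be non-negative")
        if not np.all(np.isfinite(self.migration)):
            raise ConfigError("migration rates must be finite")

    @property
    def n(self) -> int:
        return self.deme_sizes.shape[0]

    def total_emigration(self) -> np.ndarray:
        """Row sums ``M_i = sum_{j != i} M_ij``."""
        return self.migration.sum(axis=1)


@dataclass
class PiecewiseScenario:
    """Ordered epochs with change times: the non-stationary model object.

    Epoch ``e`` applies on ``[T_e, T_{e+1})`` with ``T_0 = 0``; the last
    epoch extends to infinity.  Times are in coalescent units of ``2N``
    generations.  A single-epoch scenario (no change times) is the
    stationary structured coalescent.
    """

    epochs: list[ModelEpoch]
    change_times: list[float] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.epochs:
            raise ConfigError("a scenario needs at least one epoch")
        n = self.epochs[0].n
        if any(e.n != n for e in self.epochs):
            raise ConfigError("all epochs must share the same deme count n")
        if len(self.change_times) != len(self.epochs) - 1:
            raise ConfigError(
                f"{len(self.epochs)} epochs need {len(self.epochs) - 1} "
                f"change times, got {len(self.change_times)}"
            )
        ts = [float(t) for t in self.change_times]
        if any(t <= 0 for t in ts):
            raise ConfigError("change times must be strictly positive")
        if any(b <= a for a, b in zip(ts, ts[1:])):
            raise ConfigError("change times must be strictly increasing")
        self.change_times = ts

    @property
    def n(self) -> int:
        return self.epochs[0].n

    def epoch_index_at(self, t: float) -> int:
        """Index of the epoch active at time t (right-continuous)."""
        i = 0
        for T in self.change_times:
            if t < T:
                break
            i += 1
        return i


@dataclass(frozen=True)
class TimeScaling:
    """Conversion between coalescent units and calendar years.

    One coalescent time unit is ``2 * N_ref`` generations of
    ``generation_time`` years each.  ``mutation_rate`` (per generation per
    site) is carried for downstream sequence-scale conversions.
    """

    N_ref: float
    generation_time: float
    mutation_rate: float = 1.25e-8

    def __post_init__(self) -> None:
        if min(self.N_ref, self.generation_time, self.mutation_rate) <= 0:
            raise ConfigError("all time-scaling parameters must be positive")


def scale_time(t: float, scaling: TimeScaling, direction: str) -> float:
    """Convert times between coalescent units and years.

    direction = "to_years": ``t * 2 * N_ref * generation_time``;
    "to_coalescent" is the inverse.
    """
    if t < 0:
        raise ConfigError("time must be non-negative")
    factor = 2.0 * scaling.N_ref * scaling.generation_time
    if direction == "to_years":
        return t * factor
    if direction == "to_coalescent":
        return t / factor
    raise ConfigError(f"unknown direction {direction!r}")


# ---------------------------------------------------------------------------
# Canonical builders
# ---------------------------------------------------------------------------

def n_island(n: int, M: float) -> ModelEpoch:
    """Symmetric island model: unit demes, ``M_ij = M/(n-1)`` for all pairs.

    ``M`` is the total scaled emigration rate of a deme (``M_i = M``), so
    each lineage leaves its deme at rate ``M/2``.
    """
    if not isinstance(n, int) or isinstance(n, bool) or n < 2:
        raise ConfigError(f"n-island model needs integer n >= 2, got {n!r}")
    if M <= 0:
        raise ConfigError("migration rate M must be positive")
    mig = np.full((n, n), M / (n - 1))
    np.fill_diagonal(mig, 0.0)
    return ModelEpoch(deme_sizes=np.ones(n), migration=mig)


def stepping_stone_2d(rows: int, cols: int, M: float, torus: bool = False) -> ModelEpoch:
    """2D stepping-stone lattice: unit demes, ``M/4`` per neighbouring edge.

    Demes are indexed row-major.  With ``torus=True`` both dimensions wrap,
    so every deme has four neighbours; in the bounded model corner demes
    have two neighbours, edge demes three and interior demes four, so
    border demes have a smaller total emigration rate.  Note the rate is
    M/4 per edge regardless of degree, so the 1x2 lattice coincides with
    ``n_island(2, M/4)`` — a 2-island model with a quarter of the nominal
    rate, not M itself.
    """
    if rows < 1 or cols < 1 or rows * cols < 2:
        raise ConfigError("stepping stone lattice needs at least 2 demes")
    if M <= 0:
        raise ConfigError("migration rate M must be positive")
    n = rows * cols
    mig = np.zeros((n, n))

    def idx(r: int, c: int) -> int:
        return r * cols + c

    for r in range(rows):
        for c in range(cols):
            neighbours = set()
            for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                rr, cc = r + dr, c + dc
                if torus:
                    rr, cc = rr % rows, cc % cols
                elif not (0 <= rr < rows and 0 <= cc < cols):
                    continue
                if (rr, cc) != (r, c):
                    neighbours.add((rr, cc))
            for rr, cc in neighbours:
                mig[idx(r, c), idx(rr, cc)] = M / 4.0
    return ModelEpoch(deme_sizes=np.ones(n), migration=mig)


def continent_island(n: int, c: float, M: float) -> ModelEpoch:
    """Continent-island model: deme 1 is the continent (size 1), demes
    2..n are islands of relative size ``c`` connected only to the continent.

    ``M`` is the scaled island→continent rate (``M_j1 = M``); the
    continent→island rate is then ``M_1j = c M`` to each island, which is
    exactly the migrant-conservation constraint ``c_1/c_2 = M_2/M_1``.
    """
    if not isinstance(n, int) or isinstance(n, bool) or n < 2:
        raise ConfigError(f"continent-island model needs integer n >= 2, got {n!r}")
    if c <= 0 or M <= 0:
        raise ConfigError("c and M must be positive")
    sizes = np.full(n, float(c))
    sizes[0] = 1.0
    mig = np.zeros((n, n))
    mig[0, 1:] = c * M
    mig[1:, 0] = M
    return ModelEpoch(deme_sizes=sizes, migration=mig)


def conservation_residual(model: ModelEpoch) -> np.ndarray:
    """Migrant-conservation residual, one component per deme.

    Component ``i`` is ``c_i * sum_j M_ij - sum_j c_j * M_ji``: the scaled
    excess of outward over inward migrant lineages.  A zero vector means
    the model keeps every deme's size constant under migration.  Intended
    as an optional validation warning — the structured coalescent limit
    holds without it.
    """
    c = model.deme_sizes
    M = model.migration
    return c * M.sum(axis=1) - M.T @ c


# ---------------------------------------------------------------------------
# Hand-reduced symmetry-lumped chains
# ---------------------------------------------------------------------------

def reduced_n_island(n: int, M: float) -> RateMatrix:
    """Lumped 3-state chain of the n-island model for a pair of lineages.

    States: both lineages in the same deme (``s``), in different demes
    (``d``), coalesced.  Full symmetry makes the pair process lumpable
    onto these three states.
    """
    if not isinstance(n, int) or isinstance(n, bool) or n < 2:
        raise ConfigError(f"n-island model needs integer n >= 2, got {n!r}")
    if M <= 0:
        raise ConfigError("migration rate M must be positive")
    g = M / (n - 1)
    Q = np.array([
        [-1.0 - M, M, 1.0],
        [g, -g, 0.0],
        [0.0, 0.0, 0.0],
    ])
    return RateMatrix(entries=Q, state_labels=("s", "d", "c"))


def reduced_continent_island(n: int, c: float, M: float) -> RateMatrix:
    """Lumped 5-state chain of the continent-island model for a pair.

    States: both lineages in the continent; one in the continent and one
    in an island; two different islands; same island; coalesced.
    Requires ``n >= 3`` (at least two islands, otherwise the
    two-different-islands state is empty).
    """
    if not isinstance(n, int) or isinstance(n, bool) or n < 3:
        raise ConfigError("the 5-state reduction needs n >= 3 (two islands)")
    if c <= 0 or M <= 0:
        raise ConfigError("c and M must be positive")
    Q = np.array([
        [-1.0 - c * M * (n - 1), c * M * (n - 1), 0.0, 0.0, 1.0],
        [M / 2.0, -M * (c * n - c + 1) / 2.0, (n - 2) * c * M / 2.0, c * M / 2.0, 0.0],
        [0.0, M, -M, 0.0, 0.0],
        [0.0, M, 0.0, -M - 1.0 / c, 1.0 / c],
        [0.0, 0.0, 0.0, 0.0, 0.0],
    ])
    return RateMatrix(
        entries=Q,
        state_labels=("cc", "ci", "ii_diff", "ii_same", "c"),
    )


def make_scenario(epochs: list[ModelEpoch], change_times: list[float],
                  metadata: dict | None = None) -> PiecewiseScenario:
    """Validate and assemble a piecewise-constant scenario."""
    return PiecewiseScenario(
        epochs=list(epochs),
        change_times=list(change_times),
        metadata=metadata or {},
    )


# ---------------------------------------------------------------------------
# Packaged human / Neanderthal scenario pair
# ---------------------------------------------------------------------------

#: Human deme size used as the reference N; the Neanderthal deme size 200
#: gives the ~0.16 relative size of the Neanderthal demes.
HUMAN_DEME_SIZE = 1276.0
NEANDERTHAL_RELATIVE_DEME_SIZE = 0.16
#: Assumed years per generation (an assumption of this package's fixture,
#: taken as a conventional value for Homo; it is a free parameter).
DEFAULT_GENERATION_TIME = 25.0
MUTATION_RATE = 1.25e-8

_CHANGE_YEARS = (0.192e6, 0.287e6, 0.51e6, 1.1e6, 3.0e6)
_HUMAN_M = (0.55, 1.0, 4.0, 0.55, 0.85)          # recent -> ancient
_NEANDERTHAL_BLOCK_M = (5.0, 1.0, 0.5)           # recent -> ancient, pre-merge
_ANCESTRAL_M = (4.0, 0.55, 0.85)                 # shared ancestry, recent -> ancient
_N_DEMES = 10
_N_NEANDERTHAL_DEMES = 7


def default_scaling() -> TimeScaling:
    return TimeScaling(
        N_ref=HUMAN_DEME_SIZE,
        generation_time=DEFAULT_GENERATION_TIME,
        mutation_rate=MUTATION_RATE,
    )


def _block_island_epoch(n_total: int, block: int, c_block: float, M: float) -> ModelEpoch:
    """n-island connectivity restricted to the first `block` demes; the
    remaining demes are unit-size and disconnected (unreachable from the
    sampled block — an exact encoding of a post-split population)."""
    sizes = np.ones(n_total)
    sizes[:block] = c_block
    mig = np.zeros((n_total, n_total))
    mig[:block, :block] = M / (block - 1)
    np.fill_diagonal(mig, 0.0)
    return ModelEpoch(deme_sizes=sizes, migration=mig)


def human_neanderthal_fixture(
    scaling: TimeScaling | None = None,
) -> tuple[PiecewiseScenario, PiecewiseScenario]:
    """The packaged two-species scenario pair on a fixed 10-deme space.

    Both species descend from a structured ancestral population of ten
    interconnected demes.  The human-sampled scenario is a 10-deme island
    model throughout, with gene flow (recent → ancient)
    M = 0.55, 1, 4, 0.55, 0.85, changing at 0.192, 0.287, 1.1 and 3 MYA.
    The Neanderthal-sampled scenario keeps the same 10-deme state space:
    after the split (more recent than 0.51 MYA) only a 7-deme block of
    demes at 16% of the human deme size is connected (M = 5, 1, 0.5
    recent → ancient, changes at 0.192 and 0.287 MYA) and the other three
    demes are unreachable; from 0.51 MYA backwards all ten demes are
    unit-size and connected with the ancestral gene-flow values.

    Sampling: both lineages in deme 1 (a human deme, resp. a Neanderthal
    block deme); recorded in each scenario's metadata.
    """
    scaling = scaling or default_scaling()

    def to_coal(years: float) -> float:
        return scale_time(years, scaling, "to_coalescent")

    # Human: plain n-island with piecewise M.
    human_times = [to_coal(y) for y in _CHANGE_YEARS if y != 0.51e6]
    human = make_scenario(
        [n_island(_N_DEMES, M) for M in _HUMAN_M],
        human_times,
        metadata={
            "name": "human",
            "sampling_deme": 1,
            "scaling": scaling,
            "M_sequence": list(_HUMAN_M),
        },
    )

    # Neanderthal: 7-deme block at relative size 0.16 until the 0.51 MYA
    # merge, then the ancestral 10-deme island model.
    nea_epochs = [
        _block_island_epoch(_N_DEMES, _N_NEANDERTHAL_DEMES,
                            NEANDERTHAL_RELATIVE_DEME_SIZE, M)
        for M in _NEANDERTHAL_BLOCK_M
    ] + [n_island(_N_DEMES, M) for M in _ANCESTRAL_M]
    nea_times = [to_coal(y) for y in _CHANGE_YEARS]
    neanderthal = make_scenario(
        nea_epochs,
        nea_times,
        metadata={
            "name": "neanderthal",
            "sampling_deme": 1,
            "scaling": scaling,
            "M_sequence": list(_NEANDERTHAL_BLOCK_M) + list(_ANCESTRAL_M),
            "connected_block": _N_NEANDERTHAL_DEMES,
            "relative_deme_size": NEANDERTHAL_RELATIVE_DEME_SIZE,
        },
    )
    return human, neanderthal


def _scenario_change_years() -> tuple[float, ...]:
    """Change times of the packaged scenarios, in years (for serialisers)."""
    return _CHANGE_YEARS
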