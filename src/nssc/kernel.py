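"""Transition rate matrices, propagators, coalescence-time distributions
and the IICR.

The ancestral lineage process of a structured population is a finite
continuous-time Markov chain whose generator Q has, for occupancy vector
``alpha``:

* migration: rate ``alpha_i * M_ij / 2`` to ``alpha - e_i + e_j``;
* coalescence: rate ``alpha_i (alpha_i - 1) / (2 c_i)`` to ``alpha - e_i``;
* diagonal: minus the total outflow.

The propagator ``P_t = exp(t Q)`` gives the coalescence-time cdf of a pair
sampled in configuration alpha as the absorbing-column entry
``F(t) = P_t(n_alpha, n_c)``, the pdf as ``f(t) = (P_t Q)(n_alpha, n_c)``,
and the inverse instantaneous coalescence rate as
``IICR(t) = (1 - F(t)) / f(t)``.  Piecewise-constant demography composes
per-epoch exponentials via the semigroup property:
``P~_t = exp(T_1 Q_0) ... exp((t - T_e) Q_e)``.

Numerics
--------
Each epoch generator is eigendecomposed once (falling back to
scaling-and-squaring ``expm`` when the eigenvector matrix is
ill-conditioned), so evaluating a curve on a dense grid costs one small
matrix-vector product per point.  The survival ``1 - F`` and density are
evaluated directly from the spectral expansion with the analytically-zero
stationary coefficients removed, which keeps the IICR accurate far into
the plateau where ``1 - F`` underflows the naive subtraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Sequence

import numpy as np
import scipy.linalg

from .errors import (
    ConfigError,
    StateSpaceTooLargeError,
    UnreachableAbsorptionError,
)
from .state_space import COALESCED, LineageConfiguration, StateSpace, enumerate_states

if TYPE_CHECKING:  # pragma: no cover
    from .models import ModelEpoch, PiecewiseScenario

__all__ = [
    "NumericalSettings",
    "SETTINGS",
    "RateMatrix",
    "Propagator",
    "CoalescenceDistribution",
    "IICRCurve",
    "NIslandConstants",
    "build_rate_matrix",
    "propagator",
    "scenario_propagator",
    "coalescence_cdf",
    "coalescence_pdf",
    "iicr",
    "log_time_grid",
    "n_island_constants",
    "n_island_iicr_closed_form",
    "mean_first_coalescence",
    "general_k_first_coalescence",
    "absorption_reachable",
]


@dataclass
class NumericalSettings:
    """Tunable tolerances and caps, shared by default across the package."""

    row_sum_tol: float = 1e-12       # generator rows must sum to 0 within this
    stochastic_tol: float = 1e-10    # propagator rows must sum to 1 within this
    eig_condition_cap: float = 1e8   # use the spectral path below this cond(V)
    pdf_floor: float = 1e-300        # below this density the IICR is +inf
    zero_eigenvalue_tol: float = 1e-12
    noise_coefficient_tol: float = 1e-10
    points_per_decade: int = 64      # default log-grid resolution
    state_count_cap: int = 5000      # general-k enumeration guard


SETTINGS = NumericalSettings()


# ---------------------------------------------------------------------------
# Rate matrices
# ---------------------------------------------------------------------------

@dataclass
class RateMatrix:
    """A CTMC generator with its state bookkeeping.

    Built either on a full :class:`StateSpace` (``state_space`` set) or as a
    hand-reduced symmetry-lumped chain (``state_labels`` set).  The
    absorbing (coalesced) state is always last and its row is identically
    zero.
    """

    entries: np.ndarray
    state_space: StateSpace | None = None
    state_labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.entries = np.asarray(self.entries, dtype=float)
        m = self.entries.shape[0]
        if self.entries.shape != (m, m):
            raise ConfigError("rate matrix must be square")
        off = self.entries.copy()
        np.fill_diagonal(off, 0.0)
        if np.any(off < 0):
            raise ConfigError("off-diagonal rates must be non-negative")
        scale = max(1.0, float(np.abs(self.entries).max()))
        if np.abs(self.entries.sum(axis=1)).max() > SETTINGS.row_sum_tol * scale:
            raise ConfigError("generator rows must sum to zero")
        if self.state_space is not None and len(self.state_space) != m:
            raise ConfigError("state space size does not match matrix dimension")

    @property
    def size(self) -> int:
        return self.entries.shape[0]

    @property
    def absorbing_index(self) -> int:
        """0-based index of the coalesced state (last)."""
        return self.size - 1

    def row_index(self, alpha) -> int:
        """0-based row of a configuration.

        Accepts a :class:`LineageConfiguration`, an occupancy tuple, a
        symbolic label for reduced chains (e.g. ``"s"``/``"d"``), or a
        1-based integer position (the index map phi).
        """
        if isinstance(alpha, (int, np.integer)) and not isinstance(alpha, bool):
            if not 1 <= alpha <= self.size:
                raise ConfigError(f"1-based state index {alpha} out of range")
            return int(alpha) - 1
        if isinstance(alpha, str):
            if self.state_labels and alpha in self.state_labels:
                return self.state_labels.index(alpha)
            if alpha == COALESCED and self.state_space is not None:
                return self.absorbing_index
            raise ConfigError(f"unknown state label {alpha!r}")
        if self.state_space is None:
            raise ConfigError("this reduced chain is addressed by label only")
        return self.state_space.index0(alpha)


def build_rate_matrix(model: "ModelEpoch", space: StateSpace) -> RateMatrix:
    """Construct the generator of the ancestral lineage process on `space`."""
    if space.n != model.n:
        raise ConfigError(
            f"state space is over {space.n} demes but the model has {model.n}"
        )
    m = len(space)
    n = space.n
    c = model.deme_sizes
    M = model.migration
    Q = np.zeros((m, m))
    for a, state in enumerate(space.states):
        if state.is_coalesced:
            continue
        counts = state.counts
        total = 0.0
        for i in range(n):
            ai = counts[i]
            if ai == 0:
                continue
            for j in range(n):
                if j == i or M[i, j] == 0.0:
                    continue
                rate = ai * M[i, j] / 2.0
                beta = list(counts)
                beta[i] -= 1
                beta[j] += 1
                Q[a, space.index0(tuple(beta))] += rate
                total += rate
            if ai >= 2:
                rate = ai * (ai - 1) / (2.0 * c[i])
                if state.total == 2:
                    b = space.n_c - 1
                else:
                    beta = list(counts)
                    beta[i] -= 1
                    b = space.index0(tuple(beta))
                Q[a, b] += rate
                total += rate
        Q[a, a] = -total
    return RateMatrix(entries=Q, state_space=space)


def absorption_reachable(Q: np.ndarray, start: int,
                         absorbing: int | None = None) -> bool:
    """Whether the absorbing state is reachable from `start` in the
    directed graph of non-zero off-diagonal rates of `Q`."""
    m = Q.shape[0]
    absorbing = m - 1 if absorbing is None else absorbing
    return absorbing in _reachable_set(Q, start)


def _reachable_set(Q: np.ndarray, start: int) -> set[int]:
    m = Q.shape[0]
    seen = {start}
    stack = [start]
    while stack:
        i = stack.pop()
        for j in range(m):
            if j != i and Q[i, j] > 0 and j not in seen:
                seen.add(j)
                stack.append(j)
    return seen


# ---------------------------------------------------------------------------
# Propagators: per-epoch spectral operators and the piecewise chain
# ---------------------------------------------------------------------------

class _EpochOperator:
    """``exp(t Q)`` for one epoch: spectral form when the eigenvector
    matrix is well-conditioned, scaling-and-squaring otherwise."""

    def __init__(self, Q: np.ndarray):
        self.Q = Q
        self.norm = float(np.abs(Q).sum(axis=1).max()) or 1.0
        self.spectral = False
        try:
            w, V = np.linalg.eig(Q)
            cond = np.linalg.cond(V)
            if np.isfinite(cond) and cond < SETTINGS.eig_condition_cap:
                self.w = w
                self.V = V
                self.Vinv = np.linalg.inv(V)
                self.spectral = True
        except np.linalg.LinAlgError:  # pragma: no cover - defensive
            pass

    def expm(self, t: float) -> np.ndarray:
        if self.spectral:
            P = (self.V * np.exp(self.w * t)) @ self.Vinv
            return P.real
        return scipy.linalg.expm(self.Q * t)

    def transfer(self, v: np.ndarray, target: np.ndarray, ts: np.ndarray,
                 derivative: bool = False, drop_stationary: bool = False) -> np.ndarray:
        """Evaluate ``v . exp(s Q) . target`` (or its s-derivative) for an
        array of elapsed times ``s``.

        With ``drop_stationary`` the coefficients attached to (numerically)
        zero eigenvalues are removed when they are themselves at rounding
        level — they are analytically zero for survival probabilities of
        chains that absorb almost surely, and dropping them keeps the tail
        accurate long after ``1 - F(t)`` would underflow.
        """
        ts = np.asarray(ts, dtype=float)
        out = np.empty(ts.shape)
        # Short elapsed times: truncated Taylor series of exp(sQ) acting on
        # the target vector.  The spectral form loses relative accuracy for
        # densities that vanish like t^m at the origin (cancellation among
        # O(1) eigen-coefficients); the series keeps every term exact.
        small = ts * self.norm <= 0.5
        if small.any():
            x0 = self.Q @ target if derivative else target
            for idx in zip(*np.nonzero(small)):
                out[idx] = v @ _expm_action_series(self.Q, float(ts[idx]), x0)
        if not small.all():
            big = ~small
            if self.spectral:
                coef = (v @ self.V) * (self.Vinv @ target)
                if derivative:
                    coef = coef * self.w
                elif drop_stationary:
                    near_zero = np.abs(self.w) < SETTINGS.zero_eigenvalue_tol
                    noise = np.abs(coef) < SETTINGS.noise_coefficient_tol
                    coef = np.where(near_zero & noise, 0.0, coef)
                out[big] = (np.exp(np.multiply.outer(ts[big], self.w)) @ coef).real
            else:
                for idx in zip(*np.nonzero(big)):
                    P = self.expm(float(ts[idx]))
                    row = v @ P
                    out[idx] = (row @ self.Q @ target) if derivative else row @ target
        return out


def _expm_action_series(Q: np.ndarray, s: float, x: np.ndarray) -> np.ndarray:
    """``exp(s Q) @ x`` by Taylor series; accurate for ``s * ||Q|| <= 0.5``."""
    acc = x.astype(float).copy()
    term = x.astype(float).copy()
    for m in range(1, 40):
        term = (s / m) * (Q @ term)
        acc += term
        if np.abs(term).max() < 1e-20 * max(1.0, np.abs(acc).max()):
            break
    return acc


class _Chain:
    """A (piecewise) chain ready for evaluation: per-epoch operators and
    the running products of boundary propagators."""

    def __init__(self, Qs: Sequence[np.ndarray], change_times: Sequence[float]):
        if len(Qs) != len(change_times) + 1:
            raise ConfigError("epoch/change-time count mismatch")
        self.Qs = [np.asarray(Q, dtype=float) for Q in Qs]
        self.m = self.Qs[0].shape[0]
        self.change_times = [float(t) for t in change_times]
        self.ops = [_EpochOperator(Q) for Q in self.Qs]
        # boundary[e] = product of completed-epoch propagators up to T_e
        self.boundary = [np.eye(self.m)]
        t_prev = 0.0
        for op, T in zip(self.ops, self.change_times):
            self.boundary.append(self.boundary[-1] @ op.expm(T - t_prev))
            t_prev = T

    @property
    def absorbing(self) -> int:
        return self.m - 1

    def epoch_of(self, t: float) -> int:
        return int(np.searchsorted(self.change_times, t, side="right"))

    def propagator_matrix(self, t: float) -> np.ndarray:
        e = self.epoch_of(t)
        t0 = self.change_times[e - 1] if e > 0 else 0.0
        return self.boundary[e] @ self.ops[e].expm(t - t0)

    def _eval(self, row: int, ts: np.ndarray, target: np.ndarray,
              derivative: bool = False, drop_stationary: bool = False) -> np.ndarray:
        ts = np.atleast_1d(np.asarray(ts, dtype=float))
        if np.any(ts < 0):
            raise ConfigError("times must be non-negative")
        out = np.empty(ts.shape)
        edges = [0.0] + self.change_times + [np.inf]
        for e, op in enumerate(self.ops):
            mask = (ts >= edges[e]) & (ts < edges[e + 1])
            if e == 0:
                mask |= ts == 0.0
            if not mask.any():
                continue
            v = self.boundary[e][row]
            out[mask] = op.transfer(v, target, ts[mask] - edges[e],
                                    derivative=derivative,
                                    drop_stationary=drop_stationary)
        return out

    def cdf(self, row: int, ts) -> np.ndarray:
        target = np.zeros(self.m)
        target[self.absorbing] = 1.0
        return np.clip(self._eval(row, ts, target), 0.0, 1.0)

    def survival(self, row: int, ts) -> np.ndarray:
        target = np.ones(self.m)
        target[self.absorbing] = 0.0
        return np.maximum(self._eval(row, ts, target, drop_stationary=True), 0.0)

    def pdf(self, row: int, ts) -> np.ndarray:
        target = np.zeros(self.m)
        target[self.absorbing] = 1.0
        return np.maximum(self._eval(row, ts, target, derivative=True), 0.0)

    def iicr_values(self, row: int, ts) -> np.ndarray:
        s = self.survival(row, ts)
        f = self.pdf(row, ts)
        with np.errstate(divide="ignore", invalid="ignore"):
            vals = s / f
        vals[f < SETTINGS.pdf_floor] = np.inf
        return vals


def _chain_for(scenario, space: StateSpace | None) -> tuple[_Chain, "RateMatrix | None"]:
    """Build (with caching) the evaluation chain for a scenario, which may
    be a PiecewiseScenario over a StateSpace or a bare RateMatrix."""
    if isinstance(scenario, RateMatrix):
        chain = getattr(scenario, "_chain", None)
        if chain is None:
            chain = _Chain([scenario.entries], [])
            scenario._chain = chain
        return chain, scenario
    cache = scenario.metadata.setdefault("_chains", {})
    key = id(space)
    entry = cache.get(key)
    if entry is None or entry[0] is not space:
        Qs = [build_rate_matrix(e, space).entries for e in scenario.epochs]
        entry = (space, _Chain(Qs, scenario.change_times))
        cache[key] = entry
    return entry[1], None


def _row_of(scenario, space: StateSpace | None, alpha) -> int:
    if isinstance(scenario, RateMatrix):
        return scenario.row_index(alpha)
    if space is None:
        raise ConfigError("a StateSpace is required with a PiecewiseScenario")
    if isinstance(alpha, (int, np.integer)) and not isinstance(alpha, bool):
        return int(alpha) - 1
    return space.index0(alpha)


# ---------------------------------------------------------------------------
# Public evaluation surface
# ---------------------------------------------------------------------------

@dataclass
class Propagator:
    """The stochastic matrix ``P_t`` (or epoch-composed ``P~_t``)."""

    entries: np.ndarray
    t: float

    def max_row_sum_error(self) -> float:
        return float(np.abs(self.entries.sum(axis=1) - 1.0).max())


@dataclass
class CoalescenceDistribution:
    """Callable cdf/pdf of the (first-)coalescence time for one scenario
    and initial configuration."""

    scenario: object
    space: StateSpace | None
    alpha: object
    is_pair: bool = True

    def cdf(self, t):
        return coalescence_cdf(self.scenario, self.space, self.alpha, t)

    def pdf(self, t):
        return coalescence_pdf(self.scenario, self.space, self.alpha, t)


@dataclass
class IICRCurve:
    """An IICR evaluation on a time grid, with the cdf/pdf alongside."""

    times: np.ndarray
    values: np.ndarray
    cdf: np.ndarray
    pdf: np.ndarray
    alpha: object = None
    scenario: object = None


def propagator(Q: RateMatrix, t: float) -> Propagator:
    """``P_t = exp(t Q)`` for a stationary chain."""
    if t < 0:
        raise ConfigError("time must be non-negative")
    chain, _ = _chain_for(Q, None)
    return Propagator(entries=chain.propagator_matrix(float(t)), t=float(t))


def scenario_propagator(scenario: "PiecewiseScenario", space: StateSpace,
                        t: float) -> Propagator:
    """Epoch-composed ``P~_t``: the product of completed-epoch exponentials
    times the partial exponential of the active epoch."""
    if t < 0:
        raise ConfigError("time must be non-negative")
    chain, _ = _chain_for(scenario, space)
    return Propagator(entries=chain.propagator_matrix(float(t)), t=float(t))


def coalescence_cdf(scenario, space, alpha, t):
    """``F(t) = P~_t(n_alpha, n_c)``; scalar in, scalar out."""
    chain, _ = _chain_for(scenario, space)
    row = _row_of(scenario, space, alpha)
    vals = chain.cdf(row, t)
    return float(vals[0]) if np.isscalar(t) else vals


def coalescence_pdf(scenario, space, alpha, t):
    """``f(t) = (P~_t Q_e)(n_alpha, n_c)`` with the right-limit convention
    at epoch boundaries (the epoch active on ``[T_e, T_{e+1})`` is used)."""
    chain, _ = _chain_for(scenario, space)
    row = _row_of(scenario, space, alpha)
    vals = chain.pdf(row, t)
    return float(vals[0]) if np.isscalar(t) else vals


def iicr(scenario, space, alpha, times) -> IICRCurve:
    """Evaluate ``IICR(t) = (1 - F(t)) / f(t)`` on a time grid.

    Where the density vanishes while survival is positive the value is
    ``+inf`` (e.g. two lineages in different demes at ``t = 0``).
    """
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        raise ConfigError("empty time grid")
    if np.any(np.diff(times) <= 0):
        raise ConfigError("time grid must be strictly increasing")
    chain, _ = _chain_for(scenario, space)
    row = _row_of(scenario, space, alpha)
    return IICRCurve(
        times=times,
        values=chain.iicr_values(row, times),
        cdf=chain.cdf(row, times),
        pdf=chain.pdf(row, times),
        alpha=alpha,
        scenario=scenario,
    )


def log_time_grid(t_min: float, t_max: float,
                  points_per_decade: int | None = None) -> np.ndarray:
    """Logarithmic grid, ``points_per_decade`` points per decade."""
    if not 0 < t_min < t_max:
        raise ConfigError("need 0 < t_min < t_max")
    ppd = points_per_decade or SETTINGS.points_per_decade
    count = int(np.ceil(np.log10(t_max / t_min) * ppd)) + 1
    return np.geomspace(t_min, t_max, count)


# ---------------------------------------------------------------------------
# n-island closed form
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NIslandConstants:
    """Spectral constants of the lumped n-island pair chain.

    ``gamma = M/(n-1)``; ``alpha`` and ``beta`` are the two non-zero decay
    rates, roots of ``x^2 - (1 + n*gamma) x + gamma``; the IICR plateau is
    ``1/beta``.
    """

    alpha: float
    beta: float
    gamma: float
    delta: float


def n_island_constants(n: int, M: float) -> NIslandConstants:
    if n < 2 or M <= 0:
        raise ConfigError("need n >= 2 and M > 0")
    gamma = M / (n - 1)
    delta = (1 + n * gamma) ** 2 - 4 * gamma
    sqrt_d = np.sqrt(delta)
    return NIslandConstants(
        alpha=(1 + n * gamma + sqrt_d) / 2,
        beta=(1 + n * gamma - sqrt_d) / 2,
        gamma=gamma,
        delta=delta,
    )


def n_island_iicr_closed_form(n: int, M: float, config: str, t):
    """Closed-form IICR of the n-island model for a pair sampled in the
    same deme (``config="s"``) or different demes (``"d"``)::

        IICR_s(t) = [(1-b) e^{-at} + (a-1) e^{-bt}]
                    / [(a-g) e^{-at} + (g-b) e^{-bt}]
        IICR_d(t) = [b e^{-at} - a e^{-bt}] / [g e^{-at} - g e^{-bt}]

    with a, b, g the constants of :func:`n_island_constants`.  ``IICR_d``
    diverges at ``t = 0`` (no coalescence is possible yet); the value
    returned there is ``+inf``.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ConfigError("time must be non-negative")
    k = n_island_constants(n, M)
    a, b, g = k.alpha, k.beta, k.gamma
    ea, eb = np.exp(-a * t), np.exp(-b * t)
    with np.errstate(divide="ignore", invalid="ignore"):
        if config == "s":
            vals = ((1 - b) * ea + (a - 1) * eb) / ((a - g) * ea + (g - b) * eb)
        elif config == "d":
            vals = (b * ea - a * eb) / (g * ea - g * eb)
        else:
            raise ConfigError(f"config must be 's' or 'd', got {config!r}")
    vals = np.where(np.isnan(vals) | np.isinf(vals), np.inf, vals)
    if config == "s":
        vals = np.where(t == 0, 1.0, vals)
    return float(vals[()]) if vals.ndim == 0 else vals


# ---------------------------------------------------------------------------
# Hitting times and general sample sizes
# ---------------------------------------------------------------------------

def mean_first_coalescence(model: "ModelEpoch", space: StateSpace, alpha) -> float:
    """Expected absorption (first-coalescence) time from configuration
    `alpha` under a stationary model: solves ``-Q_transient u = 1`` on the
    states reachable from alpha."""
    Q = build_rate_matrix(model, space).entries
    row = _row_of(Q_as_rate(Q, space), space, alpha)
    reach = _reachable_set(Q, row)
    absorbing = Q.shape[0] - 1
    if absorbing not in reach:
        raise UnreachableAbsorptionError(
            "the coalesced state is unreachable from the initial configuration"
        )
    idx = sorted(reach - {absorbing})
    sub = Q[np.ix_(idx, idx)]
    try:
        u = np.linalg.solve(-sub, np.ones(len(idx)))
    except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded above
        raise UnreachableAbsorptionError(str(exc)) from exc
    return float(u[idx.index(row)])


def Q_as_rate(Q: np.ndarray, space: StateSpace) -> RateMatrix:
    """Wrap a raw generator array with its state space."""
    return RateMatrix(entries=Q, state_space=space)


def general_k_first_coalescence(scenario, k: int, n: int, alpha, t):
    """Cdf of the first coalescence time among ``k`` sampled lineages.

    Runs the lineage process restricted to the ``|alpha| = k`` stratum,
    with every coalescence rate redirected into a single absorbing state;
    the returned value is the probability the chain has left the stratum
    by ``t``.  For ``k = 2`` this is exactly the pairwise coalescence cdf.
    Guarded by a state-count cap for large ``(n, k)``.
    """
    from .models import PiecewiseScenario  # local import to avoid a cycle

    if isinstance(scenario, PiecewiseScenario):
        epochs, change_times = scenario.epochs, scenario.change_times
    else:
        epochs, change_times = [scenario], []
    if any(e.n != n for e in epochs):
        raise ConfigError("scenario deme count differs from n")

    space = enumerate_states(k, n)
    stratum = [s for s in space.states if not s.is_coalesced and s.total == k]
    m = len(stratum) + 1
    if m > SETTINGS.state_count_cap:
        raise StateSpaceTooLargeError(
            f"stratum chain has {m} states, above the cap of "
            f"{SETTINGS.state_count_cap}"
        )
    index = {s.counts: i for i, s in enumerate(stratum)}
    alpha = alpha if isinstance(alpha, LineageConfiguration) else \
        LineageConfiguration.from_counts(alpha)
    if alpha.total != k:
        raise ConfigError(f"initial configuration has |alpha| = {alpha.total}, not {k}")

    def stratum_Q(model) -> np.ndarray:
        Q = np.zeros((m, m))
        c, M = model.deme_sizes, model.migration
        for a, state in enumerate(stratum):
            counts = state.counts
            total = 0.0
            for i in range(n):
                ai = counts[i]
                if ai == 0:
                    continue
                for j in range(n):
                    if j == i or M[i, j] == 0.0:
                        continue
                    rate = ai * M[i, j] / 2.0
                    beta = list(counts)
                    beta[i] -= 1
                    beta[j] += 1
                    Q[a, index[tuple(beta)]] += rate
                    total += rate
                if ai >= 2:
                    rate = ai * (ai - 1) / (2.0 * c[i])
                    Q[a, m - 1] += rate
                    total += rate
            Q[a, a] = -total
        return Q

    chain = _Chain([stratum_Q(e) for e in epochs], change_times)
    vals = chain.cdf(index[alpha.counts], t)
    return float(vals[0]) if np.isscalar(t) else vals
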