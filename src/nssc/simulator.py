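"""Monte-Carlo oracle: jump-process simulation of coalescence times.

Samples first-coalescence times by simulating the lineage jump process
directly from the per-epoch generators: in state ``i`` the chain waits an
exponential time with rate ``-Q(i, i)`` and then jumps to ``j`` with
probability ``Q(i, j) / (-Q(i, i))``.  A holding time that would cross an
epoch boundary is truncated at the boundary and redrawn under the new
epoch's rates — exact by the memorylessness of the exponential.

All replicates are advanced together in vectorised arrays, one event per
sweep, driven by a single seeded generator, so results are bit-for-bit
reproducible for a given seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, UnreachableAbsorptionError
from .kernel import _chain_for, _reachable_set, _row_of
from .state_space import StateSpace

__all__ = ["SimulationResult", "simulate_T", "empirical_iicr"]


@dataclass
class SimulationResult:
    """Sampled coalescence times (coalescent units) plus provenance."""

    samples: np.ndarray
    alpha: object
    scenario: object
    n_rep: int
    seed: int

    def save_txt(self, path) -> None:
        """One time per line, plain text."""
        with open(path, "w") as fh:
            fh.write(f"# coalescence times, n_rep={self.n_rep}, seed={self.seed}\n")
            for x in self.samples:
                fh.write(f"{x:.12g}\n")


def simulate_T(scenario, space: StateSpace | None, alpha, n_rep: int,
               seed: int) -> SimulationResult:
    """Simulate ``n_rep`` first-coalescence times from configuration alpha.

    Raises :class:`UnreachableAbsorptionError` before simulating if the
    coalesced state cannot be reached under the scenario's final epoch
    (the chain would wander forever).
    """
    if n_rep < 1:
        raise ConfigError("n_rep must be >= 1")
    chain, _ = _chain_for(scenario, space)
    start = _row_of(scenario, space, alpha)
    absorbing = chain.absorbing

    # Fail fast: under the final epoch every state reachable from alpha
    # (under any epoch) must be able to reach absorption.
    union = sum(np.abs(Q) for Q in chain.Qs)
    final = chain.Qs[-1]
    for s in _reachable_set(union, start):
        if s != absorbing and absorbing not in _reachable_set(final, s):
            raise UnreachableAbsorptionError(
                f"state {s} cannot coalesce under the final epoch; "
                "the coalescence time would be infinite"
            )

    rng = np.random.default_rng(seed)
    n_states = chain.m
    n_epochs = len(chain.Qs)
    boundaries = np.array(chain.change_times + [np.inf])
    exit_rates = np.zeros((n_epochs, n_states))
    cum_jump = np.zeros((n_epochs, n_states, n_states))
    for e, Q in enumerate(chain.Qs):
        exit_rates[e] = -np.diag(Q)
        P = Q.copy()
        np.fill_diagonal(P, 0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            P = P / P.sum(axis=1, keepdims=True)
        P[~np.isfinite(P)] = 0.0
        cum_jump[e] = np.cumsum(P, axis=1)

    state = np.full(n_rep, start, dtype=np.int64)
    epoch = np.zeros(n_rep, dtype=np.int64)
    t = np.zeros(n_rep)
    times = np.empty(n_rep)
    active = np.arange(n_rep)

    while active.size:
        st, ep = state[active], epoch[active]
        rate = exit_rates[ep, st]
        with np.errstate(divide="ignore"):
            dt = rng.exponential(1.0, size=active.size) / rate
        t_new = t[active] + dt
        bound = boundaries[ep]
        crossed = t_new >= bound  # includes rate == 0 (dt = inf) waiters

        # replicates that hit the epoch boundary first: advance and redraw
        hit = active[crossed]
        t[hit] = bound[crossed]
        epoch[hit] += 1

        # replicates that jump within the epoch
        jump = active[~crossed]
        if jump.size:
            t[jump] = t_new[~crossed]
            u = rng.random(jump.size)
            rows = cum_jump[epoch[jump], state[jump]]
            state[jump] = (u[:, None] > rows).sum(axis=1)
            done = jump[state[jump] == absorbing]
            times[done] = t[done]
        active = active[state[active] != absorbing]

    return SimulationResult(samples=times, alpha=alpha, scenario=scenario,
                            n_rep=n_rep, seed=int(seed))


def empirical_iicr(result: SimulationResult, times) -> tuple[np.ndarray, np.ndarray]:
    """Estimate the IICR from simulated coalescence times.

    Returns ``(values, cdf_hat)`` on the requested grid:
    ``(1 - F_hat(t)) / f_hat(t)`` with ``F_hat`` the empirical cdf and
    ``f_hat`` a histogram density on log-spaced bins (``ceil(sqrt(n))``
    bins, capped at 200).  Grid points whose bin is empty get ``nan``
    (missing), not infinity.  At least ~1000 samples are recommended for a
    usable curve.
    """
    samples = np.sort(np.asarray(result.samples, dtype=float))
    if samples.size == 0:
        raise ConfigError("empty sample")
    times = np.asarray(times, dtype=float)
    n = samples.size

    cdf_hat = np.searchsorted(samples, times, side="right") / n

    lo = max(samples[0], np.finfo(float).tiny)
    hi = samples[-1]
    n_bins = min(int(np.ceil(np.sqrt(n))), 200)
    edges = np.geomspace(lo, hi, n_bins + 1)
    counts, _ = np.histogram(samples, bins=edges)
    widths = np.diff(edges)
    density = counts / (n * widths)

    bin_idx = np.searchsorted(edges, times, side="right") - 1
    in_range = (bin_idx >= 0) & (bin_idx < n_bins)
    f_hat = np.full(times.shape, np.nan)
    f_hat[in_range] = density[bin_idx[in_range]]

    with np.errstate(divide="ignore", invalid="ignore"):
        values = (1.0 - cdf_hat) / f_hat
    values[(f_hat == 0)] = np.nan
    return values, cdf_hat
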