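# Methods

## Model and assumptions

`nssc` implements the structured coalescent as a finite continuous-time
Markov chain and extends it to piecewise-constant demography.  A
population of `n` demes is described per epoch by a vector of relative
deme sizes `c_i > 0` (haploid deme size `2 c_i N`, with `N` the reference
size) and a matrix of scaled backward migration rates `M_ij ≥ 0`; each
ancestral lineage in deme `i` jumps to deme `j` at rate `M_ij / 2`, and
each pair of lineages co-resident in deme `i` coalesces at rate `1/c_i`.
Time is measured in coalescent units of `2N` generations.  The chain's
states are occupancy vectors `α` (lineages per deme) plus one absorbing
state recording the first coalescence; which deme the coalescence
happened in is deliberately not tracked.

Assumptions inherited from the underlying theory: demes are internally
panmictic and large (the diffusion/coalescent limit), migration is weak
(rates of order `1/N` forward in time), and at most one event happens at
a time.  Migrant conservation — each deme's inflow balancing its outflow,
`c_i Σ_j M_ij = Σ_j c_j M_ji` — is *not* required for the chain to be
well defined; the package exposes it as an optional warning
(`conservation_residual`, `--check-conservation`), never as an error.
Deme sizes are accepted as arbitrary positive reals, a deliberate
generalisation of the integer sizes required by the discrete pre-limit
construction (the packaged Neanderthal demes have relative size 0.16).

Non-stationarity: a scenario is an ordered list of epochs with strictly
increasing change times `T_1 < T_2 < …`, epoch `e` applying on
`[T_e, T_{e+1})`.  The deme count `n` is fixed across epochs so that the
state space, and hence every matrix, keeps one size; population splits
and mergers are encoded *within* the fixed state space by block-structured
migration (zero rates make a block unreachable — an exact encoding,
rather than the alternative approximation of merging demes with a very
large migration rate, which is also expressible but not used by the
packaged scenarios).

## Computation

For each epoch the generator `Q` is built by direct application of the
per-event rates above, addressed through the canonical state order
(descending lineage count, inverse-lexicographic within a count, absorbed
state last).  The pair cdf, density and IICR are read off the propagator
`P_t = e^{tQ}`; multi-epoch scenarios compose per-epoch exponentials via
the semigroup property, with the running product of completed-epoch
propagators cached once per scenario so that a dense time grid costs one
small matrix–vector evaluation per point.

Numerical choices, each tunable through `nssc.SETTINGS`:

* **Matrix exponentials.**  Each epoch generator is eigendecomposed once;
  the spectral form is used when the eigenvector matrix has condition
  number below `1e8`, otherwise the code falls back to scipy's
  scaling-and-squaring `expm`.  Eigendecomposition amortises over dense
  grids, which is the dominant use pattern.
* **Tail accuracy.**  Survival `1 − F(t)` and density are evaluated from
  the spectral expansion with stationary (zero-eigenvalue) coefficients
  dropped when they are at rounding level — they are analytically zero
  for chains that absorb almost surely — so the IICR stays accurate deep
  into the plateau, long after the naive `1 − F` would round to zero.
* **Small-time accuracy.**  For elapsed times with `t‖Q‖ ≤ 0.5` the
  action of `e^{tQ}` on the target vector is computed by truncated Taylor
  series instead: densities that vanish like `t^m` at the origin (e.g.
  two lineages in unconnected-by-one-jump demes) lose relative accuracy
  to cancellation in the spectral sum, while the series keeps the leading
  term exact.
* **Division guard.**  Where the density is below `1e−300` with positive
  survival, the IICR is reported as `+inf` (the different-demes
  configuration at `t = 0` is the expected case), never raised as an
  error.
* **Epoch boundaries.**  The density uses the right-limit convention: at
  exactly `t = T_e` the epoch active on `[T_e, T_{e+1})` supplies the
  rate matrix, so the IICR is right-continuous at change times.
* **Grids.**  The default evaluation grid is logarithmic with 64 points
  per decade, matching PSMC-style log-time plotting.
* **General sample sizes.**  For `k ≥ 3` the distribution of the first
  coalescence among `k` lineages is computed on the `|α| = k` stratum
  with all coalescence rates redirected into one absorbing state; the
  enumeration is capped (default 5000 states) because the state count
  grows like `n^k`, and exceeding the cap raises an explicit error.
  Large-`k` exponential optimisations are out of scope.

Mean first-coalescence times solve the standard absorption linear system
`−Q_transient u = 1`, restricted to the states reachable from the initial
configuration (unreachable blocks would otherwise make the system
singular); unreachable absorption raises a dedicated error.

Two symmetry-lumped chains are provided in closed form: the 3-state
island-model pair chain (same deme / different demes / coalesced) and
the 5-state continent–island chain.  For the island model the package
also carries the analytic IICR with constants
`γ = M/(n−1)`, `Δ = (1+nγ)² − 4γ`, `α, β = (1+nγ ± √Δ)/2`; the plateau is
`1/β`.  These serve as independent oracles for the generic chain in the
tests, not as the computational path.

## Monte-Carlo simulator

The simulator draws first-coalescence times from the same jump process
the kernel integrates, and is the package's internal independent oracle
(one test additionally cross-checks against msprime).  In state `i` it
waits `Exp(−Q(i,i))`; a holding time that would cross an epoch boundary
is truncated there and redrawn under the new epoch — exact by
memorylessness, no thinning needed.  Before simulating, a transitive
closure on the final epoch's rate graph verifies that every state
reachable from the start can still reach absorption; otherwise the run
fails fast rather than looping forever.  All replicates advance together
in vectorised arrays driven by one seeded numpy generator, so results are
bit-for-bit reproducible for a given seed.  The empirical IICR estimator
uses the empirical cdf and a histogram density on log-spaced bins
(`⌈√n⌉` bins, capped at 200); empty bins yield missing values rather than
infinities, and ≥ 10³ samples are recommended.

What the simulator does and does not emulate: it samples the *exact*
model distribution, so agreement (Kolmogorov–Smirnov, moment checks)
validates the numerical kernel — it says nothing about sequence-level
effects (mutation, recombination, PSMC inference noise), which are out of
scope.

## Packaged human/Neanderthal scenarios

The fixture encodes both species as 10-deme structured populations
descending from a structured ancestral population, with all PSMC-visible
features produced by connectivity changes alone (no deme-size changes
within each species).  Human scenario: 10-deme island model with
`M = 0.55, 1, 4, 0.55, 0.85` (recent → ancient), changes at 0.192, 0.287,
1.1 and 3 MYA.  Neanderthal scenario: the same state space; more recently
than the 0.51 MYA split only a 7-deme block at 16% of the human deme size
(deme sizes 200 vs 1276) is connected (`M = 5, 1, 0.5` recent → ancient,
island-model rates `M/6` within the block), the other three demes being
unreachable; from 0.51 MYA backwards all ten demes are unit-size and
connected with the ancestral values.  Calendar dates convert to
coalescent units with reference size `N_ref = 1276` and an *assumed*
generation time of 25 years — a conventional value for Homo that is a
free parameter of the conversion, which is why figure-level reproduction
of published PSMC overlays is not a test target; the mutation rate
1.25e−8 per generation per site is carried in the configs for
sequence-scale conversions.

## Problem sizes used in tests

The test suite and the acceptance script run pair state spaces up to
`n = 12` (79 states), general-`k` strata up to a few dozen states,
Monte-Carlo batches of 10⁵ replicates per scenario (2×10⁵ for the
piecewise consistency check, 3×10³ for the msprime cross-check), 100
random models for the semigroup property, and 64–256-point log grids —
sizes chosen so the full suite completes in well under a minute on one
core while keeping Monte-Carlo standard errors far below the asserted
tolerances.

## Known limitations

* No automated inference or model fitting: the package predicts curves
  for given scenarios.
* No sequence simulation or PSMC/MSMC re-implementation; comparisons to
  inferred curves are up to the user.
* Symmetry reduction is provided only for the two hand-reduced models;
  general automorphism-orbit lumping is not attempted.
* The deme count cannot change between epochs (encode splits/mergers by
  block migration instead).
* Continuous spatial models, two-sex/unequal-generation demographics and
  time-continuous (non-stepwise) parameter change are out of scope.
* No F_ST computation is provided: the mapping between gene-flow values
  and F_ST depends on conventions that differ across the literature.
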