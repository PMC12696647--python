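# Methods

This note documents the models, numerics and design choices behind
`isoflux`: what is simulated, how, with which defaults, and what the test
battery does and does not establish.

## The labeling model

A metabolic network at metabolic steady state is described by pools
(metabolites with a fixed number of traceable carbon atoms) and reactions
with letter-coded atom maps.  Reversible reactions are parameterized in
net/exchange coordinates, `fwd = max(net,0) + xch`, `bwd = max(-net,0) + xch`,
so `net = fwd - bwd` and `xch = min(fwd, bwd) >= 0`.  Exchange is kept on
its natural `[0, inf)` scale with plain box bounds; no compactified
exchange coordinate is used — bounds handle scaling, and the coordinate
remains interpretable.

Feeding an isotopically labeled substrate mixture drives the isotopomer
distributions of all pools.  The full description has `2^n` unknowns per
pool; `isoflux` works in two exact compressions:

* **Cumomer cascade.**  The cumomer `x_{P,m}` is the probability that all
  atoms in subset `m` of pool `P` are 13C.  Balances decouple by subset
  weight: weight-k balances are linear in the weight-k cumomers, with
  source terms that are products of strictly lower-weight cumomers
  wherever a reaction assembles a molecule from several educts.
* **EMU graph.**  An EMU is an atom subset whose state is its mass
  isotopomer distribution (MID, length size+1).  EMUs are discovered
  backward from the measured fragments; condensation reactions contribute
  convolutions of smaller-EMU MIDs, and the system is leveled by EMU size.

Both reductions restrict to *essential* variables: the backward-reachable
set from the measured fragments through the atom transitions.  A
heuristic chooses the representation with fewer scalar unknowns (number
of cumomers vs. the sum of MID lengths); ties go to cumomers, whose
source terms are plain products.  The scalar count is a proxy for the
work per factorization/integration step; the choice can always be
overridden by the caller, and the reduction report records counts and
the reason string.

Untracked cofactors (`atoms="0"`) take part in flux balances but carry no
labeling state.  Symmetric molecules are modeled explicitly by the user
as two transitions carrying half the flux each; there is no automatic
symmetry detection.  Measurements on excreted accumulating pools are
only meaningful at isotopic steady state; their transient labeling (an
integral average over the accumulation history) is not modeled.

## Stationary solves and sensitivities

At isotopic steady state each level is a sparse linear system
`A_k x_k = b_k`: the diagonal carries each pool's total consumption, the
off-diagonal intra-level transfer, and `b_k` inputs plus lower-level
products/convolutions.  Levels are solved in ascending order with sparse
LU (SuperLU); the factorization is cached per flux state and reused for
every input mixture (multi-experiment batching) and for all sensitivity
right-hand sides.  A pool whose total consumption falls below
`1e-12 * max(flux)` triggers a structural-singularity error naming the
level and pool, rather than a mysterious LU failure.  Solutions are
accepted when the per-level residual satisfies
`||A x - b||_inf <= 1e-10 ||b||_inf`.

Sensitivities follow by implicit differentiation,
`A_k dx_k/dp = db_k/dp - (dA_k/dp) x_k`, solved level-by-level with the
cached LU.  Raw parameters are the per-reaction net and exchange
coordinates and the pool sizes; derivatives w.r.t. estimation parameters
(null-space coordinates, log pool sizes) follow by constant chain rules.
Pool sizes have exactly zero stationary sensitivity (structural zero).
Per-parameter solves are mutually independent and may run concurrently;
the implementation executes them sequentially but nothing in the
contract depends on ordering.

## Transient solves

With pool sizes `X` the cascade becomes `X_i dx_i/dt = b_i(x) - (A x)_i`.
All levels are stacked into one block-triangular ODE system so a single
adaptive step controller governs the whole cascade; this avoids the
inter-level interpolation error a sequential level-by-level integration
would introduce.  The default initial condition is the fully unlabeled
network (tracer switch at t = 0); arbitrary initial states are accepted.
Natural isotope abundance is out of scope throughout.

Two stiff integrators are provided:

* **BDF** (variable order/step, via SciPy) with the analytic sparse
  Jacobian.  Because a local-error controller does not bound global
  error, the wrapper passes `0.02 * rtol/atol` to the stepper so the
  *delivered* accuracy matches the requested tolerance on washin-type
  problems; the factor was chosen against closed-form solutions.
* **SDIRK3**: a 3-stage, order-3, L-stable singly diagonally implicit
  Runge-Kutta method (diagonal gamma ~ 0.4359, stiffly accurate) with an
  embedded order-2 error estimate, weighted-RMS error norm, standard
  step-size controller (safety 0.9, growth clamped to [0.2, 5]) and
  simplified Newton iterations sharing one sparse LU of
  `I - h*gamma*J` per step.  Dense output between accepted steps uses
  cubic Hermite interpolation, consistent with the method order.

Defaults are `rtol = 1e-8`, `atol = 1e-10`, exposed in the API and the
CLI.  Forward sensitivity equations (linear in the sensitivities, driven
by the state) are appended to the state system and integrated jointly at
the same tolerances; the Newton matrix uses the block-diagonal state
Jacobian, which affects only iteration counts, not accuracy.  The
`stationary_limit_check` utility integrates to
`T = 50 * max(X) / min(consumption)` — a conservative multiple of the
slowest washin time constant — and reports the deviation from the
stationary solve.

## Measurements and residuals

Measurement groups are MS fragment MIDs.  EMU states are read off
directly; cumomer states are converted per group by the
inclusion–exclusion transform restricted to the measured atom subset
(`T[k, m] = (-1)^{|m|-k} C(|m|, k)`), built once per fragment size.
MIDs are compared as normalized fractions; no per-group scale factors
are fitted (they are a possible extension, not implemented).  Mass
shifts absent from a data file are treated as unmeasured and dropped,
not as zeros.  Residuals are `(sim - meas)/sd`, stacked over
experiments, groups, times and shifts; multiple experiments contribute
additively to the SSR with no re-weighting.

## Estimation

The steady-state balance `S v = 0` plus user equalities define the
affine set `net = v0 + N theta`; `N` and `v0` are computed with rational
arithmetic (exact null space), so stoichiometric equalities hold to
machine precision for every theta.  Bounds map to `G theta <= h` — the
flux polytope.  Pool sizes enter on log scale with box bounds
(default `[1e-2, 1e2]`), which enforces positivity and makes the prior
scale-invariant.

Multi-start least squares draws starts uniformly from the polytope
(seeded hit-and-run from the Chebyshev center), then runs trust-region
reflective least squares with the analytic residual Jacobian.  Singleton
inequality rows become box bounds for the optimizer; any genuinely
multi-variable inequality is enforced through hinge penalty residuals
(weight 1e4).  Fits are deterministic given (seed, starts, options).
Confidence intervals are linearized, from the pseudo-inverse of `J'J`;
rank-deficient directions are reported as unbounded intervals, and the
summary flags the intervals as approximate.

The Bayesian sampler targets `exp(-SSR/2)` (Gaussian likelihood, uniform
prior on the polytope; with no data, the uniform distribution itself).
It is a hit-and-run Metropolis scheme for linearly constrained spaces:
a uniformly random direction, a normal step truncated to the feasible
chord, and the exact Hastings correction for the truncation.  The step
scale adapts toward ~40% acceptance during warmup and is then frozen;
for flat targets the adaptation drives the proposal toward
uniform-on-chord, which is the classical hit-and-run kernel and mixes
rapidly.  Every draw satisfies the constraints.  Split-Rhat and
effective sample sizes are computed (via ArviZ) when several chains are
run.

## The oracle and the fixtures

Ground truth comes from a deliberately independent simulator that keeps
all `2^n` isotopomers per pool, with no reduction and no shared cascade
machinery: stationary states by pool-wise fixed-point iteration to a
1e-12 residual, transients with a generic stiff integrator at rtol
1e-10.  A guard of 4096 total isotopomer variables keeps oracle runs
fast.  Cumomer and EMU predictions are required to agree with it on
every fixture.

The fixture library spans the motifs that exercise the machinery: linear
transport (`linchain`), converging mixing with two substrates and three
experiments (`mix`), branching with an atom permutation that makes a
positional fragment informative (`branch`), cleavage plus reversible
condensation with MID convolution (`cleave_condense`), reversible
exchange (`reversible_loop`), pool sizes spanning four orders of
magnitude (`stiff_pools`), an intentionally non-identifiable pair of
parallel routes (`degenerate_parallel`) and two washin chains with
closed-form solutions (`washin1`, `washin2`).  All fixtures stay at or
below 12 traced atoms.  True parameters are of order one (fluxes ~1 in
arbitrary rate units, pool sizes 1e-3 to 10), timepoint grids cover
roughly 0.2–3 washin time constants, and MS standard deviations of
0.003–0.01 mass-fraction units reflect typical MS repeatability.
`branch` doubles as the identifiable recovery fixture; its transient
configuration measures the terminal pool (full MID and a positional
fragment) *and* two upstream intermediates, because a washin cascade
observed only at its end is invariant (or nearly so) under permuting
upstream and downstream time constants: with only the terminal fragment
measured, a mirror optimum with two pool sizes exchanged fits exactly,
and with a single upstream pool added a weaker secondary optimum
survives in the unobserved branch.  Measuring the intermediates — the
standard nonstationary design remedy — leaves one well-conditioned
global optimum.

The synthetic-data generator simulates a fixture at its true parameters
and adds independent Gaussian noise at the nominal group standard
deviations, clamping to [0, 1] without renormalizing (as measured
spectra, noisy MIDs need not sum to one).  What it deliberately does not
emulate: natural-isotope background and purity effects, correlated
within-spectrum noise, proportional error, instrument drift, and
group-scale factors.  Passing tests therefore demonstrate correctness of
the simulation/estimation machinery under the stated error model, not
robustness to those real-data effects.

## Problem sizes used in verification

The automated checks run the full battery on the fixture networks:
oracle agreement over all fixtures and both representations (stationary
tolerance 1e-9, transient 1e-6 at rtol 1e-8), cumomer/EMU agreement
within 1e-8 over 50 random interior flux states per fixture, washin
closed forms to 1e-8 with sensitivities to 1e-6, finite-difference
sensitivity validation (relative 1e-4 stationary / 1e-3 transient, with
a small absolute floor so round-off on structurally zero sensitivities
is not amplified), recovery on the `branch` fixture (exact data, then 20
noisy replicates at sd 0.003 checked against 3 linearized standard
errors), and uniform sampling of a 2-simplex at 2e4 draws compared with
its centroid.  These sizes keep the whole battery in the minutes range
on a single core while leaving every tolerance safely non-trivial.

## Known limitations

* Single traced element; no multi-isotope tracers, no tandem-MS or NMR
  observables, no natural-abundance correction.
* Only the documented FluxML subset is read; everything else is rejected
  explicitly rather than silently ignored.
* Linearized confidence intervals only; no profile likelihood.
* The hit-and-run sampler is exact but not gradient-informed; strongly
  correlated, high-dimensional posteriors will mix slowly.
* Exchange fluxes can be structurally non-identifiable from stationary
  data (e.g. when back-mixing returns molecules with the marginal
  distribution they left with); transient data or informative mixtures
  are then required.
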