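# Methods

## Model class and conventions

`fptcme` works with well-stirred stochastic reaction networks: `N`
species with integer copy numbers, `M` reaction channels with
stoichiometric reactant/product vectors and propensities
`a_j(x) = c_j h_j(x)`, where `h_j` counts distinct combinations of
reactant molecules (`x` for first order, `x·y` for a bimolecular pair,
`binom(x, s)` in general).  States are copy-number vectors — there is no
volume or concentration variable anywhere.  Time is nondimensional:
every model in the bundled library has a single first-order
degradation/dilution channel whose rate is scaled to 1, so one time unit
is one mean molecule lifetime and all other rates are expressed in those
units.

A `custom` propensity kind covers the two situations mass action cannot:
reactions that fire out of the *complement* of a binary gene species
(see below), and distributed-burst models where each burst size carries
its own rate.  A custom reaction used in deterministic analyses must
also carry its mean-field rate.

Gene states are encoded as a single binary species (bound/unbound or
active/inactive), with the complementary state implicit; this halves the
state space relative to carrying both gene species with a conservation
law.  The mapping for the telegraph model is `g = 1` ⇔ gene active; for
the feedback loop `u = 1` ⇔ gene unbound (free promoter).

## FPT moments by sparse linear algebra

For generator `A` in column convention (`d_t P = A P`) and absorbing
target `Y`, the raw FPT moments from all transient initial states solve

    A_Y^T E[tau^k] = -k E[tau^(k-1)],    E[tau^0] = 1,

with `A_Y^T` the transpose of `A` with the rows and columns of `Y`
deleted, and `tau = 0` on `Y` by convention.  The implementation
factorizes `A_Y^T` once (sparse LU) and back-solves the `k_max`
right-hand sides in succession rather than forming powers of the matrix.
Each solve must achieve a relative residual (infinity norm) below
1e-10; up to three rounds of iterative refinement are applied first,
because generators mixing rates across ~7 orders of magnitude (strong
feedback) leave raw LU residuals around 1e-9.  A singular reduced matrix
is diagnosed by backward reachability on the transient transition graph
and reported with the offending states.

Targets are reach-or-exceed thresholds `Y = {x : x_s >= N}`; bursty
dynamics overshoot targets, and for unit steps this coincides with
"reach exactly N".

## Finite state projection and refinement

The state space is truncated to a rectangular box (`0..max_count` per
species).  Transitions leaving the box are dropped from the off-diagonal
but *kept* in the diagonal, so leaked probability is implicitly
absorbed; the per-state boundary outflow ("column defect") is available
as a diagnostic.  Because escape from the box is indistinguishable from
absorption in `Y`, truncation biases FPT results **low**.  Mitigations:

* default bounds give generous headroom — for a thresholded species,
  `max(N + 10·(max burst), 4·steady-state mean)`;
* `mfpt_with_refinement` doubles the bounds of all non-binary species
  until the MFPT from the initial state changes by less than `rtol`
  (default 1e-6) between refinements, erroring out loudly if a state cap
  (default 2e6) is hit first.

The convergence test is one-sided (values approach the exact answer from
below), so the reported `last_rel_change` is also an error estimate.

## FPT distributions

Deleting the `Y` rows/columns from `A` itself (no transpose) gives the
reduced system `d_t P = A_Y P`; its total transient mass is the survival
function `S(t)`.  Integration uses BDF with the sparse reduced generator
as Jacobian (gene-switching models are stiff when activation and
deactivation rates differ by orders of magnitude), at rtol 1e-8 /
atol 1e-10.  The default grid is 400 points, log-spaced over the first
decade then linear, out to 10× the MFPT; the density is the central
difference −dS/dt.  Survival is clipped to [0, 1] and enforced monotone
after checking that any non-monotonicity is within integration noise.
Mixtures of initial states are supported directly (the reduced equation
is linear, so the mixture survival is the mixture of survivals).

## Deterministic twin and crossing times

The mean-field rate equations replace combination counts by products of
continuous copy numbers; binary gene species become occupancies in
[0, 1].  Crossing times are found by LSODA integration with a terminal
upcrossing event, then a bracketed root polish to ~1e-12.  A threshold
that the trajectory approaches only asymptotically (e.g. a target at or
above the steady state) is classified *unreachable* only when the
trajectory has demonstrably settled (‖rhs‖ below 1e-8 of scale and the
event, if any, has vanishing slope); an unsettled trajectory at `t_max`
raises instead of guessing.

Deterministic initial conditions mirror the stochastic ones: zero
molecules, telegraph gene fully inactive, feedback gene unbound.  For
the feedback loop the mean-field includes protein sequestration by
binding, and the threshold counts **free** protein in both frameworks —
the model text does not pin down whether bound protein counts toward the
threshold, and free-protein counting keeps the stochastic and
deterministic target definitions identical.

## Closed forms

The simple birth–death MFPT from `n` to `N` is the double
falling-factorial sum; each term follows from the previous by a single
multiply (`t_i = t_{i-1}·(m-i)/K·i/(i+1)`), so the sum is
cancellation-free (all terms positive) and stable up to `N` in the
hundreds — it is validated against the linear solve to machine precision
rather than evaluated in extended precision.  The deterministic
counterpart is `-ln(1-rho)`; the `N`-term Taylor truncation
`sum rho^(i+1)/(i+1)` sits strictly between the stochastic mean and the
deterministic time, which proves `eta < 1` for constitutive expression
at every threshold fraction.  For fixed bursts of size `r`, targets
below `K·r·(1 - e^(-1/K)) ≈ r` are crossed faster deterministically,
while any stochastic target below `r` waits exactly one event (`1/K`).

Thresholds from fractions use `N = floor(rho·mean)` uniformly.

## Stochastic simulation oracle

The SSA is the plain direct method — exponential dwell at the total
propensity, channel picked proportionally — with the target test after
every jump so overshoot semantics match the linear solver.  FPT sampling
is vectorized: chains run in fixed chunks of 1024, chunk `c` seeded from
`SeedSequence([seed, c])`, partial chunks simulated at full width and
trimmed.  Consequently (seed, n) determines every sample exactly and
earlier samples never change as `n` grows.  Chains exceeding `t_cap`
(default 1000 time units) are censored; a censoring fraction above 1%
attaches an explicit warning since it biases the mean low.
Zeroth-order propensity columns are filled once per chunk, which matters
for the geometric-burst model (~280 constant channels).

## Geometric bursts

Burst sizes are geometric on {1, 2, ...} with mean `b` — a burst of size
zero is unobservable in a first-passage problem, so the support excludes
it.  The family is truncated where the tail mass drops below 1e-13 and
the tail is lumped onto the largest burst, preserving the total burst
frequency exactly and the mean to better than 1e-10.

## The shipped feedback grids

The feedback sweeps need concrete parameter sets, and the package ships
three illustrative panels (they are defaults, not a published set):

* `low_sigma_b` (`rho_u=10, sigma_b=0.04, sigma_u=20`, `rho_b` 20–1500):
  binding is infrequent but its occupancy grows with protein number.
  Both MFPT and tau_d rise and then fall along the grid: the rising
  steady-state mean drags the 90% target upward faster than the mostly
  unbound gene can chase it, until bound-state production dominates and
  the loop turns effectively constitutive at a high rate.
* `rare_binding` (`rho_u=5, sigma_b=0.001, sigma_u=20`, `rho_b`
  4000–16000): crossing must wait for the first binding event
  (mean wait `1/(sigma_b·rho_u)` = 200 time units) once the target
  escapes the reach of unbound production, while the deterministic model
  glides through its averaged flux — eta reaches ~18.
* `high_sigma_b` (`sigma_b=10`): binding equilibrates essentially
  instantly, the loop is constitutive-like, and tau_d bounds the MFPT
  from above across the grid.

The rise-and-fall and the eta > 10 regimes cannot coexist in a single
panel: an order-of-magnitude eta requires the first binding to be rare,
which pins the MFPT at the constant first-binding waiting time and
prevents it from falling.  Hence two separate low-binding panels.  The
high-`sigma_b` grid stops at `rho_b = 200`; at much larger values the
finite-size correction to the near-constitutive limit changes sign and
eta creeps just above 1.

## Problem sizes and tolerances in the shipped checks

The test suite and `scripts/acceptance.py` use state spaces up to ~16k
states, 10^4 Monte-Carlo samples per cross-check (10^5 where a CV² is
compared), refinement rtol 1e-6, and 3-standard-error acceptance bands
for Monte-Carlo comparisons (Kolmogorov–Smirnov distance < 0.02 for the
distribution check) — sizes chosen so the whole suite runs in about half
a minute while leaving Monte-Carlo bands a few percent wide.

## Known limitations

* Rectangular truncations only; no probability-ranked or adaptive state
  spaces.  Fine for the ≤2-species models here, wasteful beyond that.
* Absorbing sets are single species thresholds (or any user predicate
  over states, but only threshold semantics are tested).
* No time-dependent rates, no SBML, no spatial structure, no
  tau-leaping or hybrid simulation.
* The closed-form MFPT covers the simple birth–death process only;
  telegraph and feedback models have no closed form and rely on the
  FSP/SSA routes.
* The deterministic-model comparison is to the mean-field rate
  equations; no chemical Langevin or moment-closure intermediates.
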