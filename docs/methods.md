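# Methods

This note records the models, numerical procedures and design choices
behind the package, in enough detail to reproduce or audit any result it
computes.

## Models

Three kinetic frameworks describe the same two-protein negative-feedback
network (input enzyme `I` activates `A`; `A*` activates `B`; `B*`
deactivates `A*`; phosphatase `E1` deactivates `B*`):

**Complex-complete (10 species).**  Elementary mass action for every
binding, unbinding and catalytic step, with the four enzyme–substrate
complexes `C1 = I.A`, `C2 = A*.B*`, `C3 = A*.B`, `C4 = B*.E1` as explicit
species.  Each step `i in {A1, A2, B1, B2}` has association, dissociation
and catalytic constants `a_i` (conc⁻¹ t⁻¹), `d_i` (t⁻¹), `k_i` (t⁻¹), and
Michaelis constant `K_i = (d_i + k_i)/a_i`.  The reaction graph induces
four linear conservation laws (for the `A`, `B`, `I` and `E` pools), which
the right-hand side satisfies identically — asserted to 1e-12 relative in
property tests.

**Michaelian reduction (2 species).**  The classical two-variable model
with Michaelis–Menten kinetics on both cycles; complexes are neglected and
`I_tot` enters as a fixed parameter rather than a species.

**Hybrid reduction (2 species).**  As above but with simple mass-action
kinetics (no saturation) on the input/output cycle; the opposer cycle
remains Michaelian.  It represents feedback through de novo synthesis
rather than covalent modification, and differs from the Michaelian model
mainly in the detected adaptation range.

All printed parameter regimes follow the convention `d_i = 1`,
`a_i = (d_i + k_i)/K_i`; the parameter container derives the `a_i` this
way whenever they are not given explicitly.

The isolated input/output cycle (6 species) is also available: a single
reversible covalent-modification cycle whose deactivating enzyme abundance
is a free parameter, used to explain how the opposer output pool `BS*`
positions the dose–response of the full network.

## Steady states

**Initial condition.**  All protein free and unmodified: `A = A_tot`,
`B = B_tot`, `I = I_tot`, `E1 = E_tot`, complexes and active forms zero
(reduced models: `A* = B* = 0`).  This is conservation-consistent,
reproducible, and represents the biologically natural "off" state.

**Default engine.**  A compiled (numba) pseudo-transient continuation
marcher: adaptive backward-Euler steps whose size doubles after each
accepted step and shrinks fourfold when the damped Newton solve fails.
Newton uses analytic Jacobians and a partial-pivot LU factorization.
Backward Euler is L-stable, so the march is robust across the seven
decades of rate magnitudes in the sampled parameter space, and — being a
linear multistep method — it preserves the four conservation laws to
Newton tolerance (measured drift is orders of magnitude below the 1e-6 ×
total acceptance bound).  The two-variable reductions are only defined on
the box `0 ≤ A* ≤ A_tot`, `0 ≤ B* ≤ B_tot`; outside it the Michaelian
denominators change sign and spurious roots appear, so Newton iterates are
projected onto the box.  Step acceptance tolerates negative excursions
only below 1e-3 × the smallest conserved total; larger negativity rejects
the step and, at step-size collapse, raises a solver-failure signal
distinct from simple non-convergence.

**Floating-point floors.**  With rate terms as large as 1e15, both the
Newton residual and any derivative-based steadiness measure bottom out at
the roundoff of a catastrophic cancellation.  Two guards address this:
each species carries its *gross* turnover flux `w_i` (the sum of the
absolute values of its rate terms), and the Newton residual is accepted at
`16 eps (|z| + |y| + dt (w + Σ_j |J_ij||z_j|))` — the Jacobian term covers
cancellations hidden inside a single Michaelian rate term such as
`B_tot − B*`.

**Steadiness criterion.**  A state is steady when
`max_i |dy_i/dt| / max(w_i, |y_i|, floor) ≤ 1e-6` (floor 1e-12) **and**
the last accepted step changed no component by more than the same
tolerance relative to its own scale, at a step size `dt ≥ t/8`.  The first
clause alone cannot certify equilibration of slow modes (`|f| = λ·d` with
small `λ` admits a large remaining distance `d`); a late-time backward-
Euler step with `dt·λ >> 1` moves a slow mode by nearly its full remaining
distance, so a small late step certifies `d` itself.  With this criterion,
halving all tolerances moves steady states by < 1e-8 relative to the
conserved totals across 200 random parameter sets.

**Reference engine.**  `method="lsoda"` integrates with scipy's LSODA
under horizon doubling and the same steadiness measure.  It is the
independent cross-check in the tests (agreement to < 1e-4 relative on all
three models) and a trajectory-faithful fallback; the default engine is
roughly three orders of magnitude faster, which is what makes the
4 × 10⁵ steady-state solves of a screening sweep take under a minute.

**Dose–response.**  One cold-start steady state per input value
(warm-start continuation exists but is off by default, so verdicts cannot
depend on sweep direction; a test asserts grid-refinement leaves existing
points bit-identical).  Per-point failures are flagged, not fatal.

## RPA detection

The setpoint is `sigma = (k_B2/k_B1) E_tot`, the zero-order limit of the
opposer-cycle balance.  Between successive grid inputs, the detector
requires (a) the candidate variable to change by at most 2% (relative to
its value, floor 1e-12), (b) the candidate to lie within ±1% of `sigma` at
*both* inputs, and (c) the actuator variable to change by at least 1%
(relative to its value, with an absolute floor of 1e-6 × its conversion
potential).  `I_S` is the first input of the first pair satisfying
(a)–(c); `I_F` the first later input violating any of them; both are
reported as grid values without interpolation.  Requiring the band at both
pair endpoints, rather than one, excludes slow monotone pass-throughs of
the ±1% band (e.g. `A*` saturating towards `A_tot` with `sigma`
coincidentally nearby), which are crossings, not tracking.

Three exclusions separate adaptation from saturation artifacts, all based
on *conversion potentials* (the maximum steady-state-feasible value of a
variable under the conservation laws — `A_tot` for the A-side variables,
`B_tot` for `B*`, and `B_tot − E_tot(1 + k_B2/k_B1)` for the opposer
output pool `BS* = B* + C2`):

- a candidate whose conversion potential lies below `sigma` can never
  attain the setpoint (verdict `never-tracks`);
- a candidate pinned at its conversion potential across the band, and
- an actuator at or above its conversion potential during the band
  (2% headroom), are both `trivial-only`.

A band still open at the last grid pair has no observed `I_F`; it is
reported as `censored` and not counted RPA-positive.  A band already open
at the *first* grid input is counted (its `I_S` is the smallest examined
input) but is excluded from range-ratio comparisons, where its truncated
range would bias the ratio.  Profiles with any non-converged point are
flagged `non-convergence` and counted as non-RPA in sweep summaries.

Candidate/actuator pairings: `(A*, B*)` for the reduced models;
`(A*, BS*)`, `(AS*, BS*)` and `(C3, BS*)` evaluated independently for the
complex-complete model.

## Monte-Carlo screening

Each catalytic and Michaelis constant is sampled as `10**n`, `n` uniform
on `[−3, 4]`; each total abundance as `10**n`, `n` uniform on `[0, 4]`;
`d_i = 1` with `a_i` derived (independent sampling of the `d_i` is
available as an option).  All values for an ensemble are drawn up-front
from a single seeded generator in a fixed column order, so results depend
only on the seed and never on execution order or worker count (asserted in
tests).  Both models run on the same input grid per set — 40 points,
logarithmic on `[1e-3, 1e4]`, for the screening configuration — so range
comparisons are grid-fair.  The default scale is 5000 sets (about a minute
on one CPU); fractions carry binomial standard errors.

The examined input window is a genuine degree of freedom: adaptation bands
of the complex-complete model often sit at very small inputs (they can
fall below the window and be missed), while Michaelian bands are wide and
extend to large inputs (they can be caught or right-censored).  Detected
fractions and ranges therefore carry a window dependence that cannot be
eliminated, only held fixed.

Targeted searches resample one parameter group log-uniformly on `[−3, 4]`
while holding the rest at a stored regime; the stored-regime library
covers every printed parameter set, each with a qualitative assertion
(monotone `A*` with a `B*` prozone; the `AS* = C3 = sigma`, `A* = 0`
signature; the abundance-constraint boundaries; the half-maximum scaling
`I_half ≈ (k_A2/k_A1) × enzyme` of the isolated cycle; and so on).  One
stored caption lists `k_A2` twice; it is read as `k_A1 = 1` with `k_A2`
varied, and the corresponding assertion checks only the direction of the
effect.

## Diagnostics

The abundance constraints `A_tot > (k_B2/k_B1) E_tot` (the output must be
able to reach the setpoint) and `B_tot > (1 + k_B2/k_B1) E_tot` (enough
opposer protein to fill `C3 = sigma` and `C4 = E_tot` with a non-trivial
actuator pool left) are strict inequalities.  The tQSSA validity condition
`[ES]² << [E][S]` is evaluated per pair (`C1: I·A`, `C2: B*·A*`,
`C3: A*·B`, `C4: E1·B*`); "much smaller" is operationalized as ratio
< 0.1 for summary counts, with raw values always reported.  A pair with
`[E][S] = 0` and `[ES] > 0` fails maximally (ratio ∞) — the situation of
the `C3` and `C4` pairs inside any adaptation band.  An all-zero pair
holds trivially.  Across adaptation-band states of a screening sweep the
`C1`/`C2` pairs satisfy the 0.1 cut in roughly half the states — the
premise is unreliable there, though not rare in the strict sense; the
failure of the `C3`/`C4` pairs is unconditional.

## What the generator does and does not emulate

The sampler reproduces the study conditions: independent log-uniform
biochemical constants over seven decades and abundances over four.  It
does not emulate correlated parameters of real signalling proteins,
stochastic copy-number fluctuations, spatial gradients, or competing
substrates outside the two-protein module.  Passing sweeps therefore
support claims about the deterministic, well-mixed model class under
study, not about any particular measured pathway.

## Scale choices

Screening runs use 5000 sets with a 40-point grid; targeted scenario
searches use 120–300 sets; abundance scans use 5–6 points per decade axis;
the deterministic range-convergence comparison uses a 100-point grid
(at 40 points the narrow complex-complete ranges are quantized too
coarsely for median trends).  These desk-scale sizes keep the full suite
in minutes while leaving every qualitative result stable across seeds;
ensembles of 10⁵–10⁶ sets are reachable through the same API (`opposer
sweep --n ...`).

## Known limitations

- Detected `I_S`/`I_F` are grid values; ranges are quantized to the grid,
  and the actuator-change criterion makes the detected band end depend on
  grid density (a denser grid ends bands earlier).
- The operational criteria admit rare borderline detections in which the
  candidate approaches the setpoint asymptotically rather than holding a
  feedback-regulated plateau; with the trivial-adaptation exclusions these
  are infrequent (order 1 per 1000 sets) but not eliminated.
- Multistationarity is not searched for; cold starts from the "off" state
  define which steady state is reported.
- No stochastic or spatial variants; conclusions are deterministic and
  well-mixed.
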