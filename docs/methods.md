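# Methods

## The model

An enzyme discriminates between a right (R) and a wrong (W) substrate.
Three schemes are implemented as continuous-time Markov chains over a
small set of enzymatic states, with substrate and product concentrations
chemostatted and absorbed into the transition rates:

* **MM** — plain Michaelis–Menten discrimination, states
  {E, ER, EW}: binding `E ⇌ ES` with rates `kS±`, then unidirectional
  catalysis `ES → E + P` at rate `F` (equal for both substrates).
* **KPR** — kinetic proofreading, states {E, ER, EW, E\*R, E\*W}:
  binding `kS±`, internal activation `ES ⇌ ES*` (`hS±`), a futile
  discard transition `ES* ⇌ E + S` (`KS±`), and catalysis from `ES*`.
* **ERPR** — energy-relay proofreading, states
  {E′, E′R, E′W, ER, EW, E}: the energy released by the previous
  catalysis step leaves the enzyme in a metastable high-energy state E′.
  Binding into the high-energy complex (`kS±`, pathway 1), internal
  relaxation `E′S ⇌ ES` (`hS±`), proofreading `E′S ⇌ E + S` (`ℓS±`,
  pathway 2) down to the enzymatic ground state, and upcycling
  `E ⇌ ES` (`mS±`, pathway 3).  Catalysis `ES → E′ + P` closes the
  relay.  No external fuel molecule is hydrolysed; discrimination is
  powered by the stored conformational energy.

Rates are Kramers factors over a free-energy landscape with three
discrimination parameters (kBT units): `gamma` (binding-energy gap
between ER and EW), `delta ≥ 0` (initial kinetic barrier gap, carried by
the forward binding rates), `delta_p ≥ 0` (proofreading barrier gap).
The remaining parameters are the binding scale `eps`, the base attempt
frequency `omega` (sets the unit of time), the attempt frequencies
`omega_i, omega_l, omega_m` of the h/ℓ/m transitions, the internal
energies `eps_i, eps_p`, and the catalysis rate `F`.  Two structural
identities pin the parametrization and are asserted in the test suite:
the proofreading and upcycling cycles are chemically passive (their
affinity is exactly zero), and the reversible right-vs-wrong production
paths differ by exactly `gamma`.

Observables at the steady state `p` of the generator:

* error `η = J_W/(J_R+J_W)` with production fluxes `J_S = F·P(ES)`;
* speed `v = (J_R+J_W)/F = P(ER)+P(EW) ∈ [0,1]`;
* pathway costs `C2 = (J_ℓ,R+J_ℓ,W)/J_p`, `C3 = −(J_m,R+J_m,W)/J_p`.
  Flux balance at the ground state gives `C2 + C3 = 0` identically; the
  reported cost is `C = C2`.  For KPR the cost is the net discard flux
  per product (the conventional proofreading cost); for MM it is zero.
* entropy production rate `σ = Σ'_(edges) (k⁺P_i − k⁻P_j) ln(k⁺P_i/k⁻P_j)`
  over the reversible edges only — the unidirectional catalysis steps
  describe the succession of production cycles, not discrimination, and
  are excluded; with them included σ would be formally divergent.
  `Δσ = σ/J_p` is the entropy production per product.

## Numerical choices

**Steady states** are computed by GTH state reduction (both in the
scalar API and, vectorized over populations, inside the optimizer).
The elimination uses only additions, multiplications and divisions of
non-negative numbers, so each occupancy is obtained with small
*relative* error even when rates span 15+ decades.  This matters twice:
an equilibrated nullspace solve loses the small occupancies to
cancellation, which (a) breaks the exact cost conservation `C2+C3=0` at
the 1e-10 level when the costs are large, and (b) lets the genetic
search exploit cancellation noise as spuriously low errors.  A rank
(SVD) check raises on reducible networks and the residual
`‖G p‖∞ < 1e-10·max rate` is verified after every solve.

Zero rates are permitted in `RateSet` so limits (forward-driven
networks, disabled pathways) are expressible; an included edge that is
one-way but carries flux makes σ infinite, which is returned as `inf`
with a warning.  Net fluxes below 1e-300 contribute zero to σ
(the `x ln x → 0` limit).

**Forward-limit closed forms.**  With all reverse rates sent to zero the
error depends on the kinetic variables only through
`x = (omega_i/omega_l)·e^{eps_p}`.  The shipped expressions — η(x), its
minimum `η_E` and argmin `x*`, the forward-limit cost C(x), and the
costs at `η_eq` and `η_E` — were re-derived symbolically (sympy) from
the factor formula and the Kramers rates, because several printed forms
in circulation are typeset ambiguously; each form is cross-checked in
the tests against the exact solver with reverse rates scaled by 1e-12.
The re-derived cost at the equilibrium error is

    C(η_eq) = (e^γ − e^δ)(1 + e^{δp}) / [(1 + e^δ)(e^{γ+δp} − 1)]   (δ < γ),

which vanishes continuously at δ = γ.  The optimal cost–error relation
C(η) is produced by numeric elimination: solve η(x) = η by bracketed
root finding (brentq on log x) on the low-cost branch `x ≥ x*`, where
the error rises monotonically from η_E towards the MM value f(δ); errors
reachable by plain MM kinetics cost nothing.

**Regimes.**  `δ ≤ γ`: pure relay; `γ < δ ≤ 2γ + δp`: mixed relay/MM;
`δ > 2γ + δp`: pure MM (the argmin x* escapes to infinity and
`η_E = f(δ)` exactly).

## Pareto optimization

Objectives `(η, v, C, Δσ)` with η, C, Δσ minimized and v maximized,
over the six free kinetic variables `omega_i, omega_l, omega_m`
(log10, bounds ±4 around omega), `eps_i, eps_p` (bounds [0, 20] kBT) and
`F` (log10, ±4); `gamma=2, eps=5, omega=1` fixed, `delta, delta_p`
chosen per experiment.  For the relay the physical state ordering
requires `eps_p ≤ eps_i`, enforced by repair; for the scheme comparison
`delta_p` itself becomes a seventh variable in `[0, 5]` and the ordering
constraint is dropped for KPR.

The search is NSGA-II (fast non-dominated sorting, crowding distance,
binary tournament, SBX crossover η=15, polynomial mutation η=20),
population 200 for 400 generations, run four times from independently
seeded random populations and merged through a final non-dominated
filter.  A **hybrid refinement stage** follows: along each pairwise
trade-off of interest, the second objective is polished by bounded
Powell searches with the error pinned (by a penalty, just below the
target so a successful polish strictly dominates the point it started
from) at targets log-spaced across the front's error range, including
the front's own minimum.  The searches are warm-started by continuation
in both directions along the curve — a stall at one target is healed by
the solution propagating from either neighbour — and the dissipation–
error pair is refined a second time at the end.  All polished
evaluations are merged back into the 4-objective non-dominated set, so
the result is again a valid front of the model.  Without this stage the
marginal envelopes retain a 1–3% excess that visibly biases the scaling
fits; with it the front reproduces the analytic cost–error curve to
within 2% of its range.  Every point carries its generating parameters,
and merged fronts are reproducible given the seed.

**Search-bound insensitivity.**  The minimal dissipation envelope
Δσ(η) was recomputed with bounds widened to ±6 and ±8 decades and
energies to 30 and 40 kBT; it is unchanged to 12 digits, so the default
bounds are not cutting the front off.

**Scaling fits.**  Near the minimal error the dissipation–error
trade-off follows `Δσ ≈ α ln(1/(η − η_E))`.  Because the binding step
keeps a fixed driving `eps` (it is parametrized, not free), the network
is never exactly forward-driven and the divergence is physically cut
off once `η − η_E` is comparable to `η_eq·e^{−eps}` (≈ 8e-4 for the
standard parameters); below that the envelope flattens and a fit would
measure the cutoff, not the law.  The fit window is therefore the
decade `[g0, 10·g0]` with `g0 = η_eq·e^{−eps}/2` — the decade nearest
the minimal error that lies in the scaling regime.  On the
(bound-independent) polished envelope this window yields α ≈ 3.0 in the
relay regime.  When several fronts share a regime the common slope is
estimated by per-front demeaning (fixed-effects regression).  The
cost–error curve approaches its minimum-error end as
`C(η_E) − C ∝ (η − η_E)^{1/2}`, fitted as a log–log slope.

**Non-convexity (dynamical phase transition).**  The marginalized
(η, Δσ) front of the mixed regime switches between an MM branch and a
relay branch, leaving a non-convex cavity around the minimal MM error
(depth ≈ 1.7 kB at (δ, δp) = (4, 2), verified by global re-optimization
at pinned errors inside the cavity).  Detection: normalize the front to
the unit square, build the lower convex hull, flag hull chords whose
interior points rise above them by more than 3× the front's resolution
(mean consecutive-point spacing, exact duplicates trimmed so pile-ups
at the ends do not sharpen the test), and discard flagged chords
narrower than 3% of the error range — vertical sampling scatter where
Δσ diverges otherwise produces zero-width false cavities, while the
physical cavity spans ~6% of the range.

**Scheme comparison.**  At fixed (γ, δ) with `delta_p` free, the
marginal Δσ(η) curves of the relay and KPR are interpolated on a common
log-error grid and the largest error below η_eq at which they cross is
reported; above it the relay dissipates less per product.

## Stochastic oracle

An event-driven Gillespie simulation (numba-compiled, seeded, exact
CTMC sampling) provides estimators that are computationally independent
of the flux algebra: the error from catalysis event counts per
substrate, the speed from events per unit time, the costs from *net
pathway traversal counts per product*, occupancies from dwell times.
Standard errors come from batch means over 20 contiguous event batches;
agreement with the exact solver is required within 3 SE at 10^6 events.

## What the random ensembles do and do not show

Two random ensembles feed the property tests: unstructured log-uniform
rate draws (each edge rate independent in 10^[−2,2]), which exercise the
solver and conservation laws far outside the physical parametrization,
and structured draws of `DiscriminationParams`, which stay on the
Kramers manifold.  The bound `|C_i| ≤ 1` under forward net h-flux holds
on the structured ensemble (worst observed 0.996 over 3000 draws) but
*not* for arbitrary rates: flux balance gives `C2 = J_ℓ/J_p` and
`J_h = J_p − J_ℓ`, so a forward h-flux only guarantees `C2 ≤ 1` and
`C3 ≥ −1`; strong reverse circulation around the proofreading loop —
impossible when that cycle is passive — produces counterexamples with
`|C2| ≫ 1`.  Both statements are tested as such.

Synthetic fronts used in unit tests (exact log-law curves, two crossing
convex branches) validate the fitting and detection machinery
self-consistently; they do not emulate GA sampling noise beyond what the
session fronts themselves provide.

## Problem sizes

Defaults were chosen so a full run (test suite or acceptance script)
completes on a single core in minutes: 1000-draw ensembles for the
conservation/bound checks, 50×50 regime grids, 10^6-event trajectories
on 20 instances, and per-front GA budgets of 4×(200×400) evaluations
plus ~180 refinement searches.  All are parameters, not constants.

## Known limitations

* Only steady states; no transients, first-passage statistics or
  fluctuation relations.
* Single-step relay; multi-step relays are out of scope.
* The GA provides no global-optimality guarantee; convergence is
  assessed by repeat-merging, refinement gain, and agreement with the
  closed-form limits.
* The total entropy production including catalysis is not computed
  (formally divergent with strictly unidirectional catalysis).
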