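# Methods

## Model and assumptions

The package analyses host evolution in a density-dependent SIS
host–parasite model. Susceptible hosts reproduce at rate `a` reduced by
crowding `q(S+I)`; all hosts die at rate `b`; infected hosts suffer
additional virulence mortality `α` and recover at rate `γ`. Transmission
is density dependent with coefficient `β`. Three variants generate the
ecological settings of interest:

* **baseline** — constant environment; endemic equilibrium
  `S* = (b+α+γ)/β`, `I* = (a − qS* − b)S*/((q+β)S* − γ)` whenever
  `R0 = βS_dfe/(b+α+γ) > 1` with `S_dfe = (a−b)/q`.
* **seasonal / seasonal_births** — sinusoidal forcing of period 1 on the
  competition coefficient or the birth rate, amplitude `amp ∈ [0,1]`;
  the attractor is a limit cycle whose period is an integer number of
  forcing periods (1 in all parameter ranges shipped, but period
  doubling is checked, not assumed).
* **free_living** — transmission via an environmental propagule pool
  (`βSP`; `dP/dt = θI − decay·P`). Cycles arise intrinsically; their
  period is not tied to any external clock.

The evolving trait is the host's transmission coefficient β (lower =
better defended), with a birth-rate cost
`a(β) = a_ref − (τ₁²/τ₂)(1 − exp((β−β_ref)τ₂/τ₁))`, so that
`a(β_ref) = a_ref`, `a'(β_ref) = τ₁ > 0`, `a''(β_ref) = τ₂`. The sign
of τ₂ (cost curvature) controls evolutionary stability of singular
points. τ₂ = 0 (linear trade-off) is rejected rather than special-cased.

Adaptive-dynamics assumptions throughout: mutants are rare (linearized
dynamics, no mutant–mutant terms), mutations are small and rare enough
that the resident sits on its ecological attractor when each mutant
arises. At invasion into the free-living system the mutant's own
shedding into the shared pool is neglected (it is second order in the
mutant density), keeping the mutant subsystem two-dimensional.

## Invasion fitness

On a resident cycle of period T the mutant's linear time-periodic
system `(S_m, I_m)` has fundamental matrix Φ(T) — the monodromy matrix
C — computed by co-integrating the resident equations with the mutant
linearization over exactly one period (multiplicity × forcing period
for period-doubled cycles) from mutant initial conditions [1,0] and
[0,1]. Fitness is the dominant Floquet exponent `μ = ln(ρ_max)/T`.
The 1/T normalization makes exponents comparable across presets with
different periods (it does not affect signs). If a non-identity initial
basis B is supplied, C is recovered as `M B⁻¹`, which is what makes the
multipliers basis invariant.

The resident is *co-integrated* rather than interpolated from the
stored cycle: the stored attractor supplies only the phase-0 state (an
I-peak) and the period. This avoids interpolation error in stiff
regions; the residual drift of the resident over the period is measured
and an error is raised if it exceeds 1e-2 (the attractor was not
converged).

Special cases, used both for dispatch and as oracles:

* **Equilibrium residents** use the next-generation closed form
  `s = (a(β_m) − qN*)/(b + β_m F*) + γ β_m F*/((b + β_m F*)(α+b+γ)) − 1`
  (per-generation scale; F* is I* for direct transmission, P* for the
  free-living variant). The first term is lifetime reproduction of a
  mutant susceptible, the second its probability of surviving an
  infection episode back into the susceptible class; positivity is
  equivalent to `births/(1 − p_return) > 1`, hence sign-equivalent to
  the dominant eigenvalue of the mutant Jacobian.
* **γ = 0** (unstructured mutant): the period-averaged growth rate
  `r̄ = (1/T)∫(a(β_m,t) − q(t)N*(t) − β_m F*(t))dt − b`, accumulated as
  an extra quadrature state during the co-integration. For this scalar
  case r̄ equals the Floquet exponent exactly, giving a tight (1e-5)
  cross-check of the monodromy machinery.
* A constant resident gives `C = exp(JT)`; the exponent then equals the
  dominant Jacobian eigenvalue, which is the limit used to verify
  amp → 0 continuity of the Floquet route.

Note the per-generation NGM value and the per-time Floquet exponent are
different scales; they agree in sign everywhere and in value only at
neutrality, so cross-scale comparisons are made against the Jacobian
eigenvalue (same scale as the exponent).

## Attractor pipeline and numerics

* **Solver**: `scipy.integrate.solve_ivp`, LSODA by default (automatic
  stiff/non-stiff switching; Radau available). rtol 1e-10 / atol 1e-12.
  These defaults put the neutrality error |s(β,β)| near 1e-8, four
  orders below the 1e-4 health-check band.
* **Log transformation**: the free-living system is integrated in
  (ln S, ln I, ln P) by default — in linear coordinates even implicit
  solvers crawl once densities span many orders of magnitude on a
  cycle. A 2-state log version exists for the forced variants so the
  remedy is uniformly available.
* **Burn-in**: default 500 time units from the interior point
  (1, 1[, 1]) (the attractors are globally attracting in the ranges
  shipped, so the start point is immaterial — verified by the
  warm-start-independence test). Burn-in doubles (up to 8000) when the
  cycle fails to close within 1e-3 relative; warm starts from a
  previous run shorten re-burn-in to 100 units in gradient/sweep loops.
* **Period detection**: peaks of the infected density over a trailing
  60-unit window sampled at 200 points per time unit, prominence
  ≥ 1e-3 of the range; peak times refined by local parabolic
  interpolation, and the period taken from whole groups of peaks
  (first-to-last over n groups). Forced variants snap to the nearest
  integer and read the multiplicity (up to 4) off the repeat pattern of
  peak heights at 1e-3 relative tolerance. Equilibria are declared when
  every state varies by < 1e-6 relative over the last 50 units. Fewer
  than 3 peaks raises "window too short" (the window then doubles);
  interval CV > 0.2 without a height pattern raises "no fixed period"
  (chaos guard, out of scope).
* **Phase convention**: cycles are stored from an I-peak. Fitness is
  phase invariant (tested to 1e-6), so this is cosmetic.

## Adaptive dynamics

Selection gradient: central difference of invasion fitness in β_m at
β_m = β_r, step 1e-3 (absolute in β) — large enough to sit well above
integration noise, verified by the step-halving robustness test.
Singular strategies: root-bracketing (Brent) on the gradient to 1e-4 in
the trait. Bracket ends where the resident parasite cannot persist
(R0 ≤ 1, disease-free attractor — invasion fitness is undefined there)
are slid inward to the endemic region before bracketing.

Classification: evolutionary stability from the second difference of s
in β_m (step 5e-3), convergence stability from the slope of the
gradient across β_r. |curvature| below 1e-3 is reported as
"indeterminate" rather than guessed. Labels: CSS (both stable),
branching (convergent, invadable), garden_of_eden (uninvadable
repeller), repeller.

CSS sweeps track the singular point by continuation: the previous β*
seeds a local bracket (falling back to the full bracket), the previous
end state warm-starts the integration, and the attractor kind/period at
the CSS is recorded. A lost root flags the row and the sweep continues.

`calibrate_tradeoff` pins the non-seasonal singular point at β_ref by
setting `τ₁ = I*(b+α)/(b+α+γ)` (from perturbing the neutral eigenvalue
of the mutant Jacobian in β_m; the shipped τ₁ = 1.58 is this value at
q₀ = 0.5). This is how sweeps across different competition or virulence
levels are made comparable: each panel's trade-off anchors the same
reference trait in the non-seasonal limit.

## Multi-strain simulator

Independent cross-validation of the invasion analysis: strains on a
fixed trait lattice share crowding and (free-living) one propagule
pool; each epoch runs the ecology for 50 time units (an integer number
of forcing periods), culls strains whose **period-averaged** total
density is below 1e-5, and seeds a mutant adjacent to the dominant
strain (direction random, seeded) at 1e-3. Averaging over the final
window rather than point-sampling avoids culling fit strains caught at
a cycle trough. At a lattice edge the single interior neighbour is
used. Only extant strains enter the ODE system, so late epochs stay
small. The default lattice is 61 strains over the trait range;
convergence tests use 21 strains and 120 epochs, where one substitution
takes a few epochs and the whole walk from β = 0.4 to the CSS fits in
seconds — at 61-strain resolution the same walk needs thousands of
epochs for no extra information.

## What the tests do and do not show

All quantitative checks run on the model's own synthetic dynamics: the
deterministic ODE family above, with the preset parameter values. They
validate the numerical machinery (Floquet exponents against closed
forms, trait substitution against located CSSs, log- against
linear-space integration) — not the biological fidelity of the SIS
model to any real system. Demographic stochasticity, chaotic attractors
and host–parasite coevolution are outside scope; the period detector
explicitly refuses trajectories without a fixed period rather than
returning a number.

## Known limitations

* Trajectory-level agreement between log- and linear-space integration
  degrades with horizon (phase error grows along a cycle); the dual
  integration test certifies 1e-3 relative over 50 time units at rtol
  1e-10, not the local tolerance itself.
* The NGM closed form at equilibria assumes `a(β_m) − qN* > 0`
  (satisfied across all shipped presets).
* Multiplicity detection covers period doubling up to 4 forcing
  periods; higher-order cascades raise the chaos guard instead.
* `calibrate_tradeoff` anchors β* = β_ref only in the non-seasonal
  limit of the direct-transmission variants (analytic equilibrium
  required).
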