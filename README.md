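# evocycles

Eco-evolutionary invasion analysis for host–parasite ODE models whose
ecological attractors are **limit cycles** rather than equilibria.

Most adaptive-dynamics theory evaluates a rare mutant's invasion fitness
at a resident *equilibrium*, where closed forms (next-generation
numbers, Jacobian eigenvalues) suffice. But host–parasite dynamics
often cycle — extrinsically (seasonally forced competition or births)
or intrinsically (free-living parasite stages shed into the
environment). On a cycle, a point estimate of mutant density or growth
is meaningless: the mutant may be above or below its starting density
depending on when you look. `evocycles` implements the numerical
machinery that resolves this, for people modelling the evolution of
host defence (and similar traits) in fluctuating populations.

## Model family

Resident susceptible/infected hosts with crowding, virulence α and
recovery γ:

    dS/dt = (a − q(t)(S + I)) S − bS − βSI + γI
    dI/dt = βSI − (b + α + γ) I

with variants: `seasonal` (q(t) = q₀(1 + δ sin 2πt)), `seasonal_births`
(forced a(t)), and `free_living`, where transmission runs through an
environmental propagule pool (βSP, dP/dt = θI − δP) and cycles arise
with no forcing at all. Host defence evolves through the transmission
trait β, paid for via a birth-rate trade-off
a(β) = a_ref − (τ₁²/τ₂)(1 − exp((β − β_ref)τ₂/τ₁)).

## Method

Invasion fitness of a rare mutant on a resident cycle of period T is
the dominant **Floquet exponent** μ = ln(ρ_max)/T, where ρ_max is the
largest eigenvalue of the monodromy matrix **C** mapping the linearized
mutant state (S_m, I_m) across one period:

1. integrate the resident to its attractor (stiff solver; log
   coordinates for the free-living system),
2. detect and measure the cycle period from infected-density peaks
   (snapped to integer multiples of the forcing period when forced,
   checking for period doubling),
3. co-integrate resident + mutant over one period from the linearly
   independent initial conditions [1,0] and [0,1]; the end states are
   the columns of **C**,
4. μ = ln(max eigenvalue)/T; the mutant invades iff μ > 0.

On top of this sit selection gradients (finite differences), pairwise
invasion plots, root-bracketed singular strategies with CSS/branching
classification from local curvatures, CSS continuation across parameter
sweeps, and an independent multi-strain trait-substitution simulator.
Equilibrium residents are handled by the next-generation closed form,
and period-averaged growth (γ = 0) plus matrix-exponential/eigenvalue
oracles cross-check the Floquet route.

## Worked example

```python
import evocycles as ec

pre = ec.load_preset("fig4")          # free-living parasite stages
cyc, _ = ec.compute_attractor(pre.variant, pre.epi, pre.tradeoff)
print(cyc.kind, round(cyc.period, 4)) # -> cycle 10.1356

f = ec.invasion_fitness(pre.variant, pre.epi, pre.tradeoff,
                        beta_m=0.12, attractor=cyc)
print(round(f.value, 4), f.method)    # -> -0.131 floquet
```

The resident settles on an intrinsic limit cycle of period ≈ 10.14 time
units (nothing in the model oscillates at that timescale — the
environmental reservoir generates it), and a mutant with raised
transmission β_m = 0.12 has negative Floquet exponent: it cannot invade
this resident. The `examples/` directory walks through each
capability — attractor, fitness, PIP, CSS sweeps, and the multi-strain
simulation — as short narrative scripts.

Named presets (`fig2a`–`fig5b`) carry the parameter sets of the two
worked examples; every preset also runs end-to-end from the shell:

```
evocycles attractor --preset fig4 --out out/fig4
evocycles pip --preset fig2c --out out/fig2c
evocycles sweep --preset fig3a --out out/fig3a
```

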