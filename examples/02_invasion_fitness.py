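"""Floquet invasion fitness of mutant hosts on a seasonal limit cycle.

The resident sits on its annual cycle (seasonally forced competition);
a rare mutant with a different transmission trait grows or dies
according to the dominant Floquet exponent of its linearized dynamics.
"""

import evocycles as ec

pre = ec.load_preset("fig2b")  # seasonal competition, CSS trade-off
cyc, _ = ec.compute_attractor(pre.variant, pre.epi, pre.tradeoff)
print(f"resident cycle: period {cyc.period} (annual), multiplicity {cyc.multiplicity}")

for beta_m in (0.15, 0.2, 0.25):
    m = ec.monodromy_matrix(pre.variant, pre.epi, pre.tradeoff, beta_m, cyc)
    f = ec.invasion_fitness(pre.variant, pre.epi, pre.tradeoff, beta_m, attractor=cyc)
    verdict = "invades" if f.value > 1e-6 else ("neutral" if abs(f.value) < 1e-6 else "dies out")
    print(f"beta_m={beta_m:.2f}: multipliers {m.multipliers.real.round(4)}, "
          f"exponent {f.value:+.5f}/time -> {verdict}")

# The resident trait (0.20) is exactly neutral against itself; mutants
# with lower transmission pay a birth-rate cost, mutants with higher
# transmission pick up more infection — the signs of the exponents show
# which side of the resident selection currently favours.
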