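"""Resident attractor of the free-living-parasite model.

Integrates the stiff (S, I, P) system in log coordinates past its
transient, detects the intrinsic limit cycle and estimates its period
from inter-peak intervals of the infected density.
"""

import evocycles as ec

pre = ec.load_preset("fig4")
cyc, trace = ec.compute_attractor(pre.variant, pre.epi, pre.tradeoff)

print(f"attractor kind : {cyc.kind}")
print(f"period         : {cyc.period:.4f} time units")
print(f"closure gap    : {cyc.closure_gap:.2e} (relative start/end mismatch)")
print(f"peak densities : S={cyc.states[:,0].max():.2f} "
      f"I={cyc.states[:,1].max():.2f} P={cyc.states[:,2].max():.2f}")

# The period (~10.13) is intrinsic: nothing in the model is forced at
# that timescale — the parasite's environmental reservoir generates the
# oscillation.  The closure gap confirms the cycle is closed, i.e. the
# resident really is on its attractor before any mutant is introduced.
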