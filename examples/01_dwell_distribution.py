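"""Exact dwell-time distribution of the four-state myosin V cycle.

Builds the uni-cycle network with the packaged rate constants, forms
the absorbing-boundary chain at saturating ATP, and prints the decay
spectrum, the splitting probabilities, and a few points of the total
dwell density.
"""

import numpy as np

from myodwell import (Condition, ForceModel, absorption_probabilities,
                      build_absorbing_chain, build_unicycle, decay_spectrum,
                      mean_dwell, step_densities)

cond = Condition(atp=1000.0)          # µM; [ADP] = [P] = 0, no load
chain = build_absorbing_chain(build_unicycle(), cond, ForceModel())

spectrum = decay_spectrum(chain)
print("decay rates (1/s):", np.round(spectrum.rates, 2))
print("  -> the 12/s mode is trailing-head ADP release; it rules the tail")

pis = absorption_probabilities(chain)
print(f"P(backstep | just stepped forward) = {pis.pi('backward', 'DT'):.3e}")
print(f"mean dwell from the post-step state: {mean_dwell(chain, 'DT'):.4f} s")

rho = step_densities(chain)["rho_total"]
for t in (0.0, 0.05, 0.1, 0.3):
    print(f"rho_total({t:4.2f} s) = {rho(t):8.4f} 1/s")
print("the density integrates to", round(rho.mixture.integral, 10))
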