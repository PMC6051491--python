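"""Steady-state SPR affinity over the 10-600 nM analyte ladder.

Generates equilibrium Langmuir responses for a polymerase binding a
primer/template substrate (Kd 15.1 nM, Rmax 400 RU, 2% instrument noise),
subtracts a 5 RU bulk-shift reference, and fits R = Rmax*C/(Kd + C).
"""

import numpy as np

from halopol.spr import BindingSeries, steady_state_fit, subtract_reference
from halopol.synthetic_data import BindingSimParams, simulate_binding

sim = simulate_binding(BindingSimParams(kd=15.1, rmax=400.0, noise_relative=0.02, seed=11))
bulk = BindingSeries(sim.series.concentrations, np.full(7, 5.0))
raw = BindingSeries(sim.series.concentrations, sim.series.responses + 5.0)
series = subtract_reference(raw, bulk)

est = steady_state_fit(series)
print("C (nM)   R (RU)")
for c, r in zip(series.concentrations, series.responses):
    print(f"{c:6.0f}   {r:6.1f}")
print(f"\nKd = {est.kd:.1f} +/- {est.kd_uncertainty:.1f} nM, Rmax = {est.rmax:.0f} RU "
      f"(converged={est.converged})")
print("Kd is the analyte concentration at half-saturation; truth here is 15.1 nM,")
print("the high-affinity primer/template binding of the halophilic polymerase.")
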