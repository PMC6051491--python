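"""Secondary structure and Tyr hydroxyl state from Raman spectra.

Builds a six-band amide-region spectrum (1% noise) with structural areas
planted 50/30/20 (helix/coil/sheet) and a Tyr-doublet spectrum with an
I850/I830 ratio of 1.2, then decomposes both.
"""

import numpy as np

from halopol.raman import fit_bands, secondary_structure, tyr_doublet
from halopol.synthetic_data import RamanSimParams, simulate_raman

quiet = simulate_raman(RamanSimParams())
peak = quiet.spectrum.intensity.max()
sim = simulate_raman(RamanSimParams(noise_sd=0.01 * peak, seed=7))
bands, resid = fit_bands(sim.spectrum)
ss = secondary_structure(bands)
print("six-band decomposition (1500-1800 cm^-1):")
for b in bands:
    print(f"  {b.center:7.1f} cm^-1  area {b.area:6.2f}  fwhm {b.width:5.1f}  {b.assignment}")
print(f"alpha-helix {ss.alpha_pct:.1f}%  random-coil {ss.coil_pct:.1f}%  beta-sheet {ss.beta_pct:.1f}%")
print("(planted: 50/30/20 — a ~30% coil content is the halophile's flexible-structure signature)")

tyr = simulate_raman(RamanSimParams(
    band_centers=(830.0, 850.0), band_widths=(10.0, 10.0), band_areas=(10.0, 12.0),
    mixing_fractions=(0.5, 0.5), wavenumber_grid=np.arange(790.0, 890.5, 0.5), seed=7,
))
td = tyr_doublet(tyr.spectrum)
print()
print(f"Tyr doublet I850/I830 = {td.ratio:.2f} -> {td.classification}")
print("(>1: phenolic OH hydrogen-bonded to solvent, i.e. solvent-exposed tyrosines)")
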