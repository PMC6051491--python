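"""Sub-pixel bead localization from simulated camera frames.

Generates 50 frames of a diffraction-limited bead spot at (20.5, 30.25) px
with 5% pixel noise and measures the 2-D Gaussian fit's localization error.
"""

import numpy as np

from halopol.flowstretch import localize_bead
from halopol.synthetic_data import simulate_bead_frames

truth = (20.5, 30.25)
frames = simulate_bead_frames([truth] * 50, psf_sd=2.0, amplitude=1000.0,
                              noise_sd=50.0, seed=1)
errors = [np.hypot(*(np.array(localize_bead(f)) - truth)) for f in frames]
print(f"planted spot at {truth} px, 50 noisy frames")
print(f"RMS localization error: {np.sqrt(np.mean(np.square(errors))):.3f} px")
print("Sub-0.1 px precision is what makes nm-scale DNA-lengthening signals")
print("measurable from a camera whose pixels span tens of nm.")
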