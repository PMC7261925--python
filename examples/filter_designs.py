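"""Design the pipeline's three filters and measure their printed specs.

The power-line notch runs on the electrophysiology streams at their native
rate; the baseline high-pass and optional low-pass run on the hemoglobin
concentration signals at the fNIRS rate.
"""

import numpy as np

from fnirskit import design_baseline_highpass, design_lowpass, design_notch

notch = design_notch(256.0)
grid = np.arange(45, 55, 0.0005)
mags = notch.magnitude_db(grid)
below = grid[mags < 20 * np.log10(1 / np.sqrt(2))]
print(f"notch: minimum at {grid[mags.argmin()]:.3f} Hz, "
      f"-3 dB bandwidth {below[-1] - below[0]:.3f} Hz")

hp = design_baseline_highpass(3.91)
print(f"baseline high-pass: order {hp.order}, "
      f"drop at 0.005 Hz = {-hp.magnitude_db(np.array([0.005]))[0]:.3f} dB, "
      f"at 0.002 Hz = {-hp.magnitude_db(np.array([0.002]))[0]:.1f} dB")

lp = design_lowpass(3.91, 0.5)
print(f"low-pass: order {lp.order}, "
      f"drop at 0.5 Hz = {-lp.magnitude_db(np.array([0.5]))[0]:.3f} dB")

# The notch null and bandwidth sit on the 50 Hz interference line; the
# high-pass passes its 0.005 Hz edge within its 1 dB ripple and the
# low-pass passes its cutoff within 3 dB.
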