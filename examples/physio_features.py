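"""Beat-wise blood-pressure features and R-peak detection on synthetic traces.

The continuous BP trace yields systolic/diastolic values per beat (and the
hypertension annotation); the ECG yields R-peak times and heart rate.
"""

import numpy as np

from fnirskit import detect_beats, detect_r_peaks, flag_hypertension
from fnirskit.synthetic import SimulationConfig, simulate_streams

_, streams, truth = simulate_streams(SimulationConfig(seed=4, n_trials=4))
by_type = {s.type: s for s in streams}

bp = np.asarray(by_type["BP"].time_series)[:, 0]
beats = detect_beats(bp, by_type["BP"].nominal_srate)
note = flag_hypertension(beats)
print(f"blood pressure: {len(beats)} beats "
      f"(ground truth {len(truth.beat_times)}), "
      f"systolic {note['mean_systolic']:.1f} / diastolic {note['mean_diastolic']:.1f} mm Hg, "
      f"hypertension: {note['hypertension']}")

ecg = np.asarray(by_type["ECG"].time_series)[:, 0]
r_times = detect_r_peaks(ecg, by_type["ECG"].nominal_srate)
hr = 60.0 / np.diff(r_times)
print(f"ECG: {r_times.size} R-peaks, mean heart rate {hr.mean():.1f} bpm")
# Both detectors should agree with the generator's beat times to within a
# beat; the 120/80 mm Hg means sit below the >140/>100 hypertension rule.
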