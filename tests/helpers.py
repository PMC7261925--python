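"""Shared independent oracles for the test suite."""

import numpy as np
from scipy import signal


def band_power(trace: np.ndarray, rate: float, band) -> float:
    """Integrated Welch power of a trace inside a frequency band."""
    freqs, psd = signal.welch(trace, fs=rate, nperseg=min(len(trace), 512))
    mask = (freqs >= band[0]) & (freqs <= band[1])
    return float(np.trapezoid(psd[mask], freqs[mask]))
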