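"""Beat-wise features from blood pressure and ECG, and artifact regressors.

The transfer-function correction regresses each fNIRS channel on a
*reference* trace of the artifact being removed — blood pressure for Mayer
waves, the respiration belt for the respiratory band, ECG-derived heart
rate (or the pulse trace itself) for cardiac pulsation.  This module turns
raw physiological recordings into those references: beat detection on the
continuous blood pressure, R-peak detection on the ECG, and band-limited,
mean-free regressors at the fNIRS rate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np
from scipy import signal

from .errors import ConfigurationError, ProcessingError
from .io_formats import resample_to

if TYPE_CHECKING:  # pragma: no cover
    from .artifact_correction import ArtifactDefinition

#: Minimum inter-beat interval in seconds (refractory; caps detection at 180 bpm).
REFRACTORY_S = 0.33


@dataclass
class BeatSeries:
    """Per-beat blood-pressure features."""

    times: np.ndarray  # systolic peak times, s
    systolic: np.ndarray  # mm Hg
    diastolic: np.ndarray  # mm Hg

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.systolic = np.asarray(self.systolic, dtype=float)
        self.diastolic = np.asarray(self.diastolic, dtype=float)
        if self.times.size > 1 and np.any(np.diff(self.times) <= 0):
            raise ProcessingError("beat times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def rate_bpm(self) -> np.ndarray:
        """Instantaneous heart rate, 60 / inter-beat interval (len-1 values)."""
        return 60.0 / np.diff(self.times)


@dataclass
class RegressorSet:
    """Zero-mean artifact reference traces at the fNIRS rate, by artifact name."""

    traces: dict[str, np.ndarray] = field(default_factory=dict)

    def __contains__(self, name: str) -> bool:
        return name in self.traces

    def __getitem__(self, name: str) -> np.ndarray:
        return self.traces[name]


def detect_beats(bp: np.ndarray, rate: float) -> BeatSeries:
    """Detect beats on a continuous blood-pressure trace.

    Systolic values are local maxima separated by at least the 0.33 s
    refractory interval; each diastolic value is the minimum in the interval
    preceding its systolic peak.  A flat trace yields an empty series with a
    warning rather than an error, mirroring how an analysis should degrade
    when a cuff was disconnected.
    """
    bp = np.asarray(bp, dtype=float)
    if bp.size < 5 * rate:
        raise ProcessingError("need at least 5 s of blood-pressure signal")
    span = np.ptp(bp)
    if span < 1e-9:
        warnings.warn("blood-pressure trace is flat; no beats detected")
        return BeatSeries(np.empty(0), np.empty(0), np.empty(0))
    distance = max(1, round(REFRACTORY_S * rate))
    peaks, _ = signal.find_peaks(bp, distance=distance, prominence=0.25 * span)
    if peaks.size == 0:
        warnings.warn("no beats found in blood-pressure trace")
        return BeatSeries(np.empty(0), np.empty(0), np.empty(0))
    diastolic = np.empty(peaks.size)
    prev = 0
    for i, pk in enumerate(peaks):
        seg = bp[prev:pk] if pk > prev else bp[pk : pk + 1]
        diastolic[i] = seg.min()
        prev = pk
    return BeatSeries(times=peaks / rate, systolic=bp[peaks], diastolic=diastolic)


def detect_r_peaks(
    ecg: np.ndarray, rate: float, auto_polarity: bool = True
) -> np.ndarray:
    """Detect R-peak times (s) on an ECG trace.

    Band-pass (5-30 Hz) to isolate the QRS complex, square for energy, then
    adaptive-threshold peak picking with the 0.33 s refractory interval.
    With ``auto_polarity`` the trace sign is flipped when the dominant
    deflection is negative, so inverted electrode placement detects the
    same beats.
    """
    ecg = np.asarray(ecg, dtype=float)
    if ecg.size < 5 * rate:
        raise ProcessingError("need at least 5 s of ECG signal")
    if np.ptp(ecg) < 1e-9:
        warnings.warn("ECG trace is flat; no R-peaks detected")
        return np.empty(0)
    high = min(30.0, 0.45 * rate)
    sos = signal.butter(4, [5.0, high], "bandpass", fs=rate, output="sos")
    qrs = signal.sosfiltfilt(sos, ecg)
    if auto_polarity and abs(qrs.min()) > abs(qrs.max()):
        qrs = -qrs
    energy = np.square(np.clip(qrs, 0, None))
    threshold = 0.2 * np.percentile(energy, 99.5)
    distance = max(1, round(REFRACTORY_S * rate))
    peaks, _ = signal.find_peaks(energy, height=threshold, distance=distance)
    return peaks / rate


def flag_hypertension(beats: BeatSeries) -> dict | None:
    """Annotate elevated blood pressure from beat-wise means.

    Flags when mean systolic exceeds 140 mm Hg or mean diastolic exceeds
    100 mm Hg (strict inequalities).  Returns ``None`` for an empty series.
    """
    if len(beats) == 0:
        return None
    mean_sys = float(beats.systolic.mean())
    mean_dia = float(beats.diastolic.mean())
    return {
        "mean_systolic": mean_sys,
        "mean_diastolic": mean_dia,
        "hypertension": bool(mean_sys > 140.0 or mean_dia > 100.0),
    }


def beat_series_to_trace(
    beats: BeatSeries, which: str, timestamps: np.ndarray
) -> np.ndarray:
    """Interpolate a beat-wise series (systolic/diastolic/rate) onto timestamps."""
    if which in ("systolic", "diastolic"):
        times, values = beats.times, getattr(beats, which)
    elif which == "rate":
        times, values = beats.times[1:], beats.rate_bpm
    else:
        raise ConfigurationError(f"unknown beat series '{which}'")
    if len(values) < 2:
        raise ProcessingError("too few beats to build a continuous trace")
    return np.interp(timestamps, times, values)


def build_regressors(
    physio: dict[str, np.ndarray],
    artifacts: "list[ArtifactDefinition]",
    rate: float,
) -> RegressorSet:
    """Build zero-mean artifact reference regressors at the fNIRS rate.

    ``physio`` maps trace ids (``bp``, ``resp``, ``hr``, ``ecg``, or
    beat-derived ids like ``bp_dia``) to traces already at the fNIRS rate.
    Each artifact's reference is its source trace band-passed to the
    artifact's correction band (4th-order Butterworth, zero phase) and
    mean-removed.
    """
    out = RegressorSet()
    nyq = rate / 2
    for art in artifacts:
        if art.source not in physio:
            raise ProcessingError(
                f"artifact '{art.name}': no {art.source} data available"
            )
        trace = np.asarray(physio[art.source], dtype=float)
        low, high = art.correction_band
        high = min(high, nyq * 0.98)
        sos = signal.butter(4, [low, high], "bandpass", fs=rate, output="sos")
        ref = signal.sosfiltfilt(sos, trace - trace.mean())
        out.traces[art.name] = ref - ref.mean()
    return out


__all__ = [
    "BeatSeries",
    "RegressorSet",
    "detect_beats",
    "detect_r_peaks",
    "flag_hypertension",
    "beat_series_to_trace",
    "build_regressors",
    "resample_to",
]
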