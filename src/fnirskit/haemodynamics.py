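"""Modified Beer-Lambert conversion and the standard CW-NIRS filter bank.

Continuous-wave NIRS measures only light attenuation, so only *changes* in
chromophore concentration are recoverable.  For each channel the attenuation
change at each wavelength is

    dA(t) = log10(I0 / I(t)),

and the two-wavelength system

    dA_lambda / (x_lambda * l) = eps(lambda, Hb) * dc_Hb
                               + eps(lambda, HbO2) * dc_HbO2

is solved per sample for the oxy-/deoxy-hemoglobin concentration changes
(in mM*mm; the path-length scaling keeps the product with the geometric
distance).  Constant scattering loss cancels in the differential form.

Filters: a 50 Hz power-line notch (IIR, 1.43 Hz bandwidth) for the
high-rate electrophysiology streams, a 6th-order Butterworth high-pass at
0.005 Hz for baseline drift, and an optional 8th-order Butterworth low-pass
with a free cutoff.  The Butterworth edge convention here is
ripple-at-edge: the magnitude drop at the quoted cutoff equals the quoted
passband ripple (1 dB for the high-pass, 3 dB for the low-pass, where it
coincides with the classical -3 dB point).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .errors import ConfigurationError, ProcessingError

# Molar extinction coefficients at 760/850 nm in 1/(mM*mm), from the
# standard compiled hemoglobin spectra used across CW-NIRS software.
# Rows: wavelength (760, 850 nm); columns: (Hb, HbO2).
DEFAULT_EXTINCTION = np.array(
    [
        [0.154852, 0.058600],  # 760 nm: (Hb, HbO2)
        [0.069132, 0.105800],  # 850 nm
    ]
)

#: Differential path length factors for the adult head at (760, 850) nm.
DEFAULT_DPF = (7.25, 6.38)

#: Default source-detector separation in mm (~3 cm optode spacing).
DEFAULT_DISTANCE_MM = 30.0


@dataclass
class BeerLambertConfig:
    """Constants of the modified Beer-Lambert conversion.

    ``extinction``: 2x2 matrix eps(lambda, chromophore) in 1/(mM*mm), rows
    ordered like ``wavelengths``, columns (Hb, HbO2).  ``dpf``: differential
    path length factor per wavelength.  ``distance``: source-detector
    separation l in mm.
    """

    extinction: np.ndarray = field(default_factory=lambda: DEFAULT_EXTINCTION.copy())
    dpf: tuple[float, float] = DEFAULT_DPF
    distance: float = DEFAULT_DISTANCE_MM

    def __post_init__(self):
        self.extinction = np.asarray(self.extinction, dtype=float)
        if self.extinction.shape != (2, 2):
            raise ConfigurationError("extinction must be a 2x2 matrix")
        if abs(np.linalg.det(self.extinction)) < 1e-12:
            raise ConfigurationError("extinction matrix is singular")
        if self.distance <= 0:
            raise ConfigurationError("source-detector distance must be positive")
        if any(x <= 0 for x in self.dpf):
            raise ConfigurationError("DPF values must be positive")


@dataclass
class ConcentrationBlock:
    """Oxy/deoxy concentration-change traces (channels x samples, mM*mm)."""

    hbo: np.ndarray
    hbr: np.ndarray
    rate: float

    def __post_init__(self):
        self.hbo = np.atleast_2d(np.asarray(self.hbo, dtype=float))
        self.hbr = np.atleast_2d(np.asarray(self.hbr, dtype=float))
        if self.hbo.shape != self.hbr.shape:
            raise ProcessingError("hbo and hbr must have identical shapes")
        if not (np.all(np.isfinite(self.hbo)) and np.all(np.isfinite(self.hbr))):
            raise ProcessingError("concentration traces contain non-finite values")

    @property
    def n_channels(self) -> int:
        return self.hbo.shape[0]

    @property
    def n_samples(self) -> int:
        return self.hbo.shape[1]

    def copy(self) -> "ConcentrationBlock":
        return ConcentrationBlock(self.hbo.copy(), self.hbr.copy(), self.rate)


@dataclass
class FilterSpec:
    """A designed digital filter (second-order sections) plus its metadata."""

    kind: str  # notch | highpass | lowpass
    order: int
    edges: tuple[float, ...]  # Hz
    rate: float  # Hz
    sos: np.ndarray
    ripple_db: float | None = None
    attenuation_db: float | None = None

    def __post_init__(self):
        self.sos = np.atleast_2d(np.asarray(self.sos, dtype=float))
        _, poles, _ = signal.sos2zpk(self.sos)
        if np.any(np.abs(poles) >= 1.0):
            raise ConfigurationError(f"{self.kind} filter design is unstable")
        nyq = self.rate / 2
        if any(e >= nyq for e in self.edges):
            raise ConfigurationError("filter edge at or above Nyquist")

    def response(self, freqs: np.ndarray) -> np.ndarray:
        """Complex frequency response at the given frequencies (Hz)."""
        _, h = signal.sosfreqz(self.sos, worN=np.asarray(freqs, float), fs=self.rate)
        return h

    def magnitude_db(self, freqs: np.ndarray) -> np.ndarray:
        mag = np.abs(self.response(freqs))
        return 20 * np.log10(np.maximum(mag, 1e-300))


def attenuation_change(intensity: np.ndarray, baseline: float) -> np.ndarray:
    """Attenuation change dA[n] = log10(baseline / I[n]) for one channel/wavelength.

    ``baseline`` is the reference intensity I0; by package convention the
    temporal mean of the trace (CW-NIRS fixes no absolute reference instant).
    """
    intensity = np.asarray(intensity, dtype=float)
    if baseline <= 0:
        raise ProcessingError("baseline intensity must be positive")
    bad = np.flatnonzero(intensity <= 0)
    if bad.size:
        raise ProcessingError(f"non-positive intensity at sample {bad[0]}")
    return np.log10(baseline / intensity)


def mbll(
    dA760: np.ndarray, dA850: np.ndarray, config: BeerLambertConfig | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Solve the two-wavelength Beer-Lambert system per sample.

    Returns ``(dc_Hb, dc_HbO2)`` in mM*mm.  The right-hand side is the
    attenuation change at each wavelength divided by its pathlength scaling
    ``dpf * distance``; the 2x2 extinction matrix is inverted once.
    """
    config = config or BeerLambertConfig()
    dA760 = np.asarray(dA760, dtype=float)
    dA850 = np.asarray(dA850, dtype=float)
    if dA760.shape != dA850.shape:
        raise ProcessingError("attenuation traces must have equal length")
    rhs = np.vstack(
        [
            dA760 / (config.dpf[0] * config.distance),
            dA850 / (config.dpf[1] * config.distance),
        ]
    )
    dc = np.linalg.solve(config.extinction, rhs)
    return dc[0], dc[1]


def intensities_to_concentration(
    intensities: np.ndarray,
    rate: float,
    config: BeerLambertConfig | None = None,
    baselines: np.ndarray | None = None,
) -> ConcentrationBlock:
    """Convert a channels x samples x 2 intensity array to a ConcentrationBlock.

    ``baselines`` (channels x 2) overrides the default per-trace temporal
    mean used as the Beer-Lambert reference intensity I0.
    """
    config = config or BeerLambertConfig()
    intensities = np.asarray(intensities, dtype=float)
    n_channels = intensities.shape[0]
    if baselines is None:
        baselines = intensities.mean(axis=1)
    hbo = np.empty(intensities.shape[:2])
    hbr = np.empty(intensities.shape[:2])
    for ch in range(n_channels):
        try:
            dA1 = attenuation_change(intensities[ch, :, 0], baselines[ch, 0])
            dA2 = attenuation_change(intensities[ch, :, 1], baselines[ch, 1])
        except ProcessingError as exc:
            raise ProcessingError(f"channel {ch}: {exc}") from exc
        hbr[ch], hbo[ch] = mbll(dA1, dA2, config)
    return ConcentrationBlock(hbo=hbo, hbr=hbr, rate=rate)


def design_notch(rate: float) -> FilterSpec:
    """50 Hz power-line notch with a -3 dB bandwidth of 1.43 Hz.

    Intended for the electrophysiology streams at their native rate; raises
    for rates at or below 100 Hz where 50 Hz is not safely below Nyquist.
    """
    if rate <= 100:
        raise ConfigurationError(
            f"notch at 50 Hz requires rate > 100 Hz, got {rate} Hz"
        )
    f0, bandwidth = 50.0, 1.43
    b, a = signal.iirnotch(f0, Q=f0 / bandwidth, fs=rate)
    return FilterSpec(
        kind="notch",
        order=2,
        edges=(f0 - bandwidth / 2, f0 + bandwidth / 2),
        rate=rate,
        sos=signal.tf2sos(b, a),
    )


def design_baseline_highpass(rate: float) -> FilterSpec:
    """6th-order Butterworth high-pass for baseline drift removal.

    Passband edge 0.005 Hz with at most 1 dB drop there (ripple-at-edge
    convention); the monotone stopband reaches the quoted 30 dB below
    ~0.0028 Hz.
    """
    if rate <= 0.02:
        raise ConfigurationError("sampling rate too low for 0.005 Hz high-pass")
    order, edge, ripple = 6, 0.005, 1.0
    # -3 dB corner placed so the Butterworth magnitude is exactly -ripple dB
    # at the passband edge: (fc/edge)^(2n) = 10^(ripple/10) - 1.
    fc = edge * (10 ** (ripple / 10) - 1) ** (1 / (2 * order))
    sos = signal.butter(order, fc, "highpass", fs=rate, output="sos")
    return FilterSpec(
        kind="highpass", order=order, edges=(edge,), rate=rate, sos=sos,
        ripple_db=ripple, attenuation_db=30.0,
    )


def design_lowpass(rate: float, cutoff: float) -> FilterSpec:
    """8th-order Butterworth low-pass with a user-selected cutoff.

    Ripple-at-edge convention with a 3 dB ripple, which for a Butterworth
    coincides (to ~0.03%) with the classical -3 dB corner.
    """
    if not 0 < cutoff < rate / 2:
        raise ConfigurationError(
            f"low-pass cutoff must lie in (0, {rate / 2}) Hz, got {cutoff}"
        )
    order, ripple = 8, 3.0
    fc = cutoff / (10 ** (ripple / 10) - 1) ** (1 / (2 * order))
    fc = min(fc, rate / 2 * (1 - 1e-9))
    sos = signal.butter(order, fc, "lowpass", fs=rate, output="sos")
    return FilterSpec(
        kind="lowpass", order=order, edges=(cutoff,), rate=rate, sos=sos,
        ripple_db=ripple, attenuation_db=30.0,
    )


def apply_filter(trace: np.ndarray, spec: FilterSpec) -> np.ndarray:
    """Causal single-pass application of a designed filter along the last axis."""
    trace = np.asarray(trace, dtype=float)
    if trace.shape[-1] <= 3 * spec.order:
        raise ProcessingError(
            f"signal too short for order-{spec.order} filter "
            f"({trace.shape[-1]} samples)"
        )
    return signal.sosfilt(spec.sos, trace, axis=-1)


def filter_block(block: ConcentrationBlock, spec: FilterSpec) -> ConcentrationBlock:
    """Apply a designed filter to both chromophores of a ConcentrationBlock."""
    return ConcentrationBlock(
        hbo=apply_filter(block.hbo, spec),
        hbr=apply_filter(block.hbr, spec),
        rate=block.rate,
    )
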