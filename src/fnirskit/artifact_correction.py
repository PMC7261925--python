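"""Physiological artifact detection and removal for fNIRS concentration signals.

Cerebral hemodynamic responses ride on systemic oscillations: Mayer
(third-order blood-pressure) waves near 0.1 Hz, respiration near 0.3 Hz and
cardiac pulsation above 1 Hz.  Three correction methods are provided:

* **CAR** (common average reference): subtract the cross-channel mean at
  every sample — systemic components are common to all channels.
* **ICA** via **SOBI** (second-order blind identification): whiten the
  channel block, jointly diagonalize time-lagged covariance matrices by
  Givens rotations, select components dominated by an artifact band or
  correlated with an artifact reference, and reconstruct without them.
* **TF models**: regress each channel on lagged copies of a simultaneously
  recorded artifact reference (FIR transfer function, least squares) and
  keep the residual.

Each artifact carries a spectral *search window* (where its peak is looked
for) and a *correction band* (what is removed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .errors import ConfigurationError, ProcessingError
from .haemodynamics import ConcentrationBlock
from .physio import RegressorSet

#: Spectral search windows (Hz) for the three physiological artifacts.
DEFAULT_SEARCH_WINDOWS = {
    "MTH": (0.07, 0.13),
    "RF": (0.2, 0.4),
    "HR": (1.0, 1.5),
}

#: Widening (Hz) applied to a search window to form the default correction band.
BAND_MARGIN_HZ = 0.02

#: Default physiological source trace per artifact.  The cardiac artifact
#: uses the pulsatile BP trace (its fundamental sits at the heart rate);
#: the beat-wise rate-in-bpm trace carries no power there.
DEFAULT_SOURCES = {"MTH": "bp_dia", "RF": "resp", "HR": "bp"}


@dataclass
class ArtifactDefinition:
    """One physiological artifact: spectral windows and reference source."""

    name: str
    search_window: tuple[float, float]
    correction_band: tuple[float, float] | None = None
    source: str = ""

    def __post_init__(self):
        low, high = self.search_window
        if not 0 < low < high:
            raise ConfigurationError(
                f"artifact '{self.name}': invalid search window {self.search_window}"
            )
        if self.correction_band is None:
            self.correction_band = (max(low - BAND_MARGIN_HZ, 1e-4), high + BAND_MARGIN_HZ)
        if not self.source:
            self.source = DEFAULT_SOURCES.get(self.name, "")


def default_artifacts(
    names: tuple[str, ...] = ("MTH", "RF", "HR"), mth_source: str = "bp_dia"
) -> list[ArtifactDefinition]:
    """Standard artifact set in correction order (Mayer, respiration, cardiac)."""
    arts = []
    for name in names:
        source = mth_source if name == "MTH" else DEFAULT_SOURCES[name]
        arts.append(ArtifactDefinition(name, DEFAULT_SEARCH_WINDOWS[name], source=source))
    return arts


@dataclass
class PowerSpectrum:
    """Welch power spectral density in dB."""

    frequencies: np.ndarray  # Hz, 0 .. Nyquist
    power_db: np.ndarray
    resolution: float  # Hz between bins


@dataclass
class ICADecomposition:
    """SOBI decomposition X = A S (+ channel means)."""

    mixing: np.ndarray  # channels x components
    sources: np.ndarray  # components x samples
    means: np.ndarray  # channels
    selected: list[int] = field(default_factory=list)

    def reconstruct(self) -> np.ndarray:
        return self.mixing @ self.sources + self.means[:, None]


@dataclass
class TFModel:
    """FIR transfer-function model x[n] ~= sum_u g[u] * y[n-u]."""

    order: int
    coefficients: np.ndarray  # length order + 1

    def __post_init__(self):
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.order < 0 or self.coefficients.shape != (self.order + 1,):
            raise ConfigurationError("TF model needs order+1 finite coefficients")
        if not np.all(np.isfinite(self.coefficients)):
            raise ConfigurationError("TF model coefficients must be finite")


def power_spectrum(trace: np.ndarray, rate: float) -> PowerSpectrum:
    """Welch PSD: Hann window, 120 s segments (or full length), 50% overlap."""
    trace = np.asarray(trace, dtype=float)
    if trace.size == 0:
        raise ProcessingError("cannot estimate the spectrum of an empty signal")
    nperseg = min(trace.size, int(round(120 * rate)))
    freqs, psd = signal.welch(
        trace, fs=rate, window="hann", nperseg=nperseg, noverlap=nperseg // 2
    )
    power_db = 10 * np.log10(np.maximum(psd, 1e-300))
    return PowerSpectrum(
        frequencies=freqs, power_db=power_db, resolution=float(freqs[1] - freqs[0])
    )


def find_artifact_peak(
    spectrum: PowerSpectrum, artifact: ArtifactDefinition, min_prominence_db: float = 3.0
) -> float | None:
    """Frequency of the strongest peak inside the artifact's search window.

    Returns ``None`` when the maximum is less than ``min_prominence_db``
    above the window's median power (no identifiable artifact line).  On
    exact ties the lower frequency wins.
    """
    low, high = artifact.search_window
    mask = (spectrum.frequencies >= low) & (spectrum.frequencies <= high)
    if not np.any(mask):
        return None
    window_power = spectrum.power_db[mask]
    peak_idx = int(np.argmax(window_power))  # first maximum -> lowest frequency
    if window_power[peak_idx] - np.median(window_power) < min_prominence_db:
        return None
    return float(spectrum.frequencies[mask][peak_idx])


def car(block: ConcentrationBlock) -> ConcentrationBlock:
    """Common average reference: subtract the cross-channel mean per sample.

    Applied independently to the oxy and deoxy channel sets.
    """
    if block.n_channels < 2:
        raise ProcessingError("CAR is undefined for fewer than 2 channels")
    return ConcentrationBlock(
        hbo=block.hbo - block.hbo.mean(axis=0, keepdims=True),
        hbr=block.hbr - block.hbr.mean(axis=0, keepdims=True),
        rate=block.rate,
    )


def _joint_diagonalize(
    matrices: np.ndarray, tol: float = 1e-8, max_sweeps: int = 200
) -> np.ndarray:
    """Jointly diagonalize symmetric matrices by iterative Givens rotations.

    Jacobi-like scheme: each (p, q) plane rotation maximizes the summed
    squared diagonals of the stack.  Returns the orthogonal matrix V such
    that V.T @ M @ V is near-diagonal for all M.
    """
    k, n, _ = matrices.shape
    V = np.eye(n)
    M = matrices.copy()
    for _ in range(max_sweeps):
        max_sin = 0.0
        for p in range(n - 1):
            for q in range(p + 1, n):
                # optimal rotation from the 2x2 structure of the stack
                h1 = M[:, p, p] - M[:, q, q]
                h2 = M[:, p, q] + M[:, q, p]
                G = np.array(
                    [[h1 @ h1, h1 @ h2], [h2 @ h1, h2 @ h2]]
                )
                eigvals, eigvecs = np.linalg.eigh(G)
                x, y = eigvecs[:, np.argmax(eigvals)]
                if x < 0:
                    x, y = -x, -y
                r = np.hypot(x, y)
                c = np.sqrt((x + r) / (2 * r))
                s = y / np.sqrt(2 * r * (x + r))
                if abs(s) < tol:
                    continue
                max_sin = max(max_sin, abs(s))
                rot_p = c * M[:, :, p] + s * M[:, :, q]
                rot_q = -s * M[:, :, p] + c * M[:, :, q]
                M[:, :, p], M[:, :, q] = rot_p, rot_q
                rot_p = c * M[:, p, :] + s * M[:, q, :]
                rot_q = -s * M[:, p, :] + c * M[:, q, :]
                M[:, p, :], M[:, q, :] = rot_p, rot_q
                vp = c * V[:, p] + s * V[:, q]
                vq = -s * V[:, p] + c * V[:, q]
                V[:, p], V[:, q] = vp, vq
        if max_sin < tol:
            break
    return V


def sobi(block: np.ndarray, lags: list[int] | None = None) -> ICADecomposition:
    """Second-order blind identification of a channels x samples block.

    Whitens the (demeaned) data, forms symmetrized covariance matrices at
    the given positive lags (default ``1..min(100, samples // 3)``) and
    jointly diagonalizes them.  The mixing matrix is the inverse of the
    composed unmixing transform, so ``mixing @ sources`` restores the
    demeaned input exactly.
    """
    X = np.atleast_2d(np.asarray(block, dtype=float))
    n_ch, n_samp = X.shape
    if n_ch < 2:
        raise ProcessingError("SOBI needs at least 2 channels")
    if lags is None:
        lags = list(range(1, min(100, n_samp // 3) + 1))
    if n_samp <= 3 * max(lags):
        raise ProcessingError("too few samples for the requested SOBI lags")

    means = X.mean(axis=1)
    Xc = X - means[:, None]
    C0 = (Xc @ Xc.T) / n_samp
    eigvals, eigvecs = np.linalg.eigh(C0)
    if eigvals[-1] <= 0 or eigvals[0] < 1e-12 * eigvals[-1]:
        raise ProcessingError(
            "rank-deficient channel covariance; exclude redundant or flat channels"
        )
    whitener = (eigvecs / np.sqrt(eigvals)).T  # rows scale eigen-directions
    Z = whitener @ Xc

    stack = np.empty((len(lags), n_ch, n_ch))
    for i, lag in enumerate(lags):
        R = (Z[:, :-lag] @ Z[:, lag:].T) / (n_samp - lag)
        stack[i] = 0.5 * (R + R.T)
    V = _joint_diagonalize(stack)

    sources = V.T @ Z
    mixing = np.linalg.inv(V.T @ whitener)
    return ICADecomposition(mixing=mixing, sources=sources, means=means)


def band_power_fraction(trace: np.ndarray, rate: float, band: tuple[float, float]) -> float:
    """Fraction of a trace's total spectral power inside a frequency band."""
    trace = np.asarray(trace, dtype=float)
    nperseg = min(trace.size, 512)
    freqs, psd = signal.welch(trace, fs=rate, nperseg=nperseg)
    total = psd.sum()
    if total <= 0:
        return 0.0
    mask = (freqs >= band[0]) & (freqs <= band[1])
    return float(psd[mask].sum() / total)


def select_artifact_components(
    dec: ICADecomposition,
    artifacts: list[ArtifactDefinition],
    regressors: RegressorSet | None,
    rate: float,
    band_fraction_threshold: float = 0.5,
    correlation_threshold: float = 0.6,
) -> list[int]:
    """Indices of components attributable to a physiological artifact.

    A component is selected when more than half its spectral power falls in
    any artifact's correction band, or when its absolute correlation with
    that artifact's reference regressor exceeds the correlation threshold.
    """
    selected = []
    for idx, src in enumerate(dec.sources):
        for art in artifacts:
            if band_power_fraction(src, rate, art.correction_band) > band_fraction_threshold:
                selected.append(idx)
                break
            if regressors is not None and art.name in regressors:
                ref = regressors[art.name]
                n = min(len(ref), len(src))
                s, r = src[:n] - src[:n].mean(), ref[:n] - ref[:n].mean()
                denom = np.linalg.norm(s) * np.linalg.norm(r)
                if denom > 0 and abs(s @ r) / denom > correlation_threshold:
                    selected.append(idx)
                    break
    return selected


def remove_components(dec: ICADecomposition, indices: list[int]) -> np.ndarray:
    """Reconstruct the channel block with the selected source rows zeroed."""
    n_comp = dec.sources.shape[0]
    for idx in indices:
        if not 0 <= idx < n_comp:
            raise ProcessingError(f"component index {idx} out of range 0..{n_comp - 1}")
    kept = dec.sources.copy()
    if indices:
        kept[np.asarray(indices, dtype=int)] = 0.0
    return dec.mixing @ kept + dec.means[:, None]


def fit_tf_model(x: np.ndarray, y: np.ndarray, m: int = 8) -> TFModel:
    """Least-squares FIR fit of channel ``x`` on lagged regressor ``y``.

    Solves ``x[n] = sum_{u=0}^{m} g[u] y[n-u] + residual`` over the samples
    where all lags are defined (``n >= m``).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if y.size != n:
        raise ProcessingError("channel and regressor must have equal length")
    if n <= 10 * (m + 1):
        raise ProcessingError(f"need more than {10 * (m + 1)} samples for order {m}")
    if np.ptp(y) < 1e-12:
        raise ProcessingError("constant regressor: singular TF design matrix")
    design = np.column_stack([y[m - u : n - u] for u in range(m + 1)])
    # lagged copies of a narrow-band regressor are nearly collinear; truncate
    # small singular values so the solution stays bounded
    coeffs, *_ = np.linalg.lstsq(design, x[m:], rcond=1e-6)
    return TFModel(order=m, coefficients=coeffs)


def apply_tf_correction(x: np.ndarray, y: np.ndarray, model: TFModel) -> np.ndarray:
    """Residual after subtracting the FIR-predicted perturbation.

    For the first ``m`` samples the unavailable lags are treated as zero.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    predicted = np.convolve(y, model.coefficients)[: x.size]
    return x - predicted


def tf_correct_block(
    block: ConcentrationBlock,
    regressors: RegressorSet,
    artifacts: list[ArtifactDefinition],
    order: int = 8,
) -> tuple[ConcentrationBlock, dict[str, list[TFModel]]]:
    """Sequential per-channel TF correction, one artifact at a time.

    Artifacts are removed in list order on the running residual, each with
    its own FIR fit per channel and chromophore.  Returns the cleaned block
    and the fitted models keyed by ``{artifact}/{chromophore}``.
    """
    hbo, hbr = block.hbo.copy(), block.hbr.copy()
    models: dict[str, list[TFModel]] = {}
    for art in artifacts:
        if art.name not in regressors:
            raise ProcessingError(f"no regressor available for artifact '{art.name}'")
        y = regressors[art.name]
        for label, data in (("hbo", hbo), ("hbr", hbr)):
            fitted = []
            for ch in range(data.shape[0]):
                model = fit_tf_model(data[ch], y, m=order)
                data[ch] = apply_tf_correction(data[ch], y, model)
                fitted.append(model)
            models[f"{art.name}/{label}"] = fitted
    return ConcentrationBlock(hbo=hbo, hbr=hbr, rate=block.rate), models


def ica_correct_block(
    block: ConcentrationBlock,
    artifacts: list[ArtifactDefinition],
    regressors: RegressorSet | None = None,
    lags: list[int] | None = None,
) -> tuple[ConcentrationBlock, dict[str, list[int]]]:
    """SOBI decomposition and artifact-component removal per chromophore."""
    cleaned = {}
    selections = {}
    for label, data in (("hbo", block.hbo), ("hbr", block.hbr)):
        dec = sobi(data, lags=lags)
        idx = select_artifact_components(dec, artifacts, regressors, block.rate)
        dec.selected = idx
        cleaned[label] = remove_components(dec, idx)
        selections[label] = idx
    return (
        ConcentrationBlock(hbo=cleaned["hbo"], hbr=cleaned["hbr"], rate=block.rate),
        selections,
    )


def correct_block(
    block: ConcentrationBlock,
    method: str,
    artifacts: list[ArtifactDefinition] | None = None,
    regressors: RegressorSet | None = None,
    tf_order: int = 8,
) -> ConcentrationBlock:
    """Dispatch to the configured correction method.

    ``method`` is one of ``uncorrected`` (identity), ``car``, ``ica``, ``tf``.
    """
    method = method.lower()
    if method == "uncorrected":
        return block.copy()
    if method == "car":
        return car(block)
    if method == "ica":
        if artifacts is None:
            artifacts = default_artifacts()
        cleaned, _ = ica_correct_block(block, artifacts, regressors)
        return cleaned
    if method == "tf":
        if artifacts is None:
            artifacts = default_artifacts()
        if regressors is None:
            raise ProcessingError("TF correction requires artifact regressors")
        cleaned, _ = tf_correct_block(block, regressors, artifacts, order=tf_order)
        return cleaned
    raise ConfigurationError(f"unknown correction method '{method}'")
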