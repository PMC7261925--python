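"""Ground-truthed synthetic recordings: block-design hemodynamics forward-
modelled into two-wavelength intensities, plus coherent physiological traces.

The generator builds what the acquisition stack would record during a
block-design motor task:

* a clean oxy response per channel — a single-gamma hemodynamic response
  (time-to-peak 6 s, optional undershoot) convolved with the task boxcar —
  with the deoxy response a scaled, sign-flipped copy;
* systemic oscillations shared across channels: Mayer waves (~0.1 Hz),
  respiration (~0.3 Hz) and cardiac pulsation (~1.2 Hz), each a sinusoid
  whose frequency wanders slowly (±10%) to mimic nonstationarity;
* white measurement noise;
* two-wavelength intensities obtained by running the summed concentration
  changes through the Beer-Lambert forward model around per-channel
  baseline intensities;
* ECG (R/T morphology), pulsatile blood pressure (set systolic/diastolic),
  a respiration-belt trace and a continuous heart-rate trace, all phase-
  locked to the same oscillators so transfer-function correction has a
  truthful reference;
* a paradigm marker stream at the task onsets.

Everything is deterministic under the configured seed, and the ground
truth (clean traces, artifact components, event times, baselines) is
returned alongside — so every pipeline stage can be scored against what
was actually embedded.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .errors import ConfigurationError
from .haemodynamics import BeerLambertConfig
from .io_formats import RecordingMetadata, write_hdr
from .xdf import XDFStream, write_xdf


@dataclass
class ArtifactSpec:
    """One embedded systemic oscillation."""

    frequency: float  # Hz (center; wanders +-jitter)
    amplitude: float  # mM*mm in the fNIRS signal
    jitter: float = 0.10  # relative slow frequency wander


@dataclass
class SimulationConfig:
    """All knobs of the synthetic recording.

    Defaults reproduce the acquisition conditions of the supported stack:
    fNIRS at 3.91 Hz, ECG/respiration at 256 Hz, BP/HR at 200 Hz, a
    5 s pre / 12 s task / 8 s post block design, Mayer/respiratory/cardiac
    oscillations inside their standard physiological bands, resting heart
    rate 72 bpm and blood pressure 120/80 mm Hg.
    """

    seed: int = 0
    n_channels: int = 8
    fnirs_rate: float = 3.91
    pre: float = 5.0
    task: float = 12.0
    post: float = 8.0
    n_trials: int = 10
    conditions: list[tuple[str, int]] = field(default_factory=lambda: [("task", 1)])
    lead_in: float = 25.0
    lead_out: float = 15.0
    hrf_amplitude: float = 1.0e-3  # peak oxy response, mM*mm
    hrf_time_to_peak: float = 6.0  # s
    hrf_undershoot: float = 0.15  # relative undershoot amplitude
    deoxy_ratio: float = -0.3  # deoxy response = ratio * oxy response
    artifacts: dict[str, ArtifactSpec] = field(
        default_factory=lambda: {
            "MTH": ArtifactSpec(0.10, 4.0e-4),
            "RF": ArtifactSpec(0.30, 2.0e-4),
            "HR": ArtifactSpec(1.20, 2.0e-4),
        }
    )
    noise_sd: float = 1.0e-4  # white noise on each concentration trace, mM*mm
    ecg_rate: float = 256.0
    resp_rate: float = 256.0
    bp_rate: float = 200.0
    hr_rate: float = 200.0
    systolic: float = 120.0  # mm Hg
    diastolic: float = 80.0
    bp_mayer_amplitude: float = 3.0  # mm Hg of Mayer modulation on BP
    hr_mayer_amplitude: float = 2.0  # bpm of Mayer modulation on the HR trace
    beer_lambert: BeerLambertConfig = field(default_factory=BeerLambertConfig)

    def __post_init__(self):
        for rate in (self.fnirs_rate, self.ecg_rate, self.resp_rate, self.bp_rate, self.hr_rate):
            if rate <= 0:
                raise ConfigurationError("all sampling rates must be positive")
        nyq = self.fnirs_rate / 2
        for name, art in self.artifacts.items():
            if art.amplitude < 0:
                raise ConfigurationError(f"artifact {name}: negative amplitude")
            if art.frequency >= nyq:
                raise ConfigurationError(
                    f"artifact {name}: {art.frequency} Hz is not below the "
                    f"fNIRS Nyquist ({nyq:.3g} Hz)"
                )
        if self.task <= 0 or self.pre < 0 or self.post < 0:
            raise ConfigurationError("need task > 0 and pre/post >= 0 seconds")

    @property
    def trial_duration(self) -> float:
        return self.pre + self.task + self.post

    @property
    def duration(self) -> float:
        return self.lead_in + self.n_trials * self.trial_duration + self.lead_out


@dataclass
class GroundTruth:
    """What was embedded: clean signals, artifact components, events."""

    timestamps: np.ndarray  # fNIRS timeline, s
    clean_hbo: np.ndarray  # channels x samples, mM*mm
    clean_hbr: np.ndarray
    artifact_traces: dict[str, np.ndarray]  # unit common-mode traces (fNIRS grid)
    artifact_gains: dict[str, np.ndarray]  # per-channel amplitude of each artifact
    hbo_total: np.ndarray  # clean + artifacts + noise (what intensities encode)
    hbr_total: np.ndarray
    onset_samples: np.ndarray  # task-onset fNIRS sample indices
    marker_values: np.ndarray
    r_peak_times: np.ndarray  # s
    beat_times: np.ndarray  # BP systolic peak times, s
    baselines: np.ndarray  # channels x 2 baseline intensities I0
    taps: np.ndarray | None = None  # FIR taps, for TF fixtures


def hrf_kernel(rate: float, time_to_peak: float = 6.0, undershoot: float = 0.15,
               duration: float = 30.0) -> np.ndarray:
    """Single-gamma hemodynamic response (peak 1) with optional undershoot."""
    t = np.arange(0, duration, 1 / rate)
    shape = 6.0
    scale = time_to_peak / (shape - 1)
    main = t ** (shape - 1) * np.exp(-t / scale)
    main /= main.max()
    if undershoot > 0:
        u_scale = 2 * time_to_peak / (shape - 1)
        under = t ** (shape - 1) * np.exp(-t / u_scale)
        main = main - undershoot * under / under.max()
        main /= main.max()
    return main


def _wandering_phase(rng, f0: float, jitter: float, fine_t: np.ndarray) -> np.ndarray:
    """Phase of an oscillator whose frequency wanders slowly by +-jitter."""
    n_knots = max(4, int(fine_t[-1] / 30) + 2)  # one knot per ~30 s
    knots = np.linspace(fine_t[0], fine_t[-1], n_knots)
    wander = rng.uniform(-1, 1, n_knots)
    freq = f0 * (1 + jitter * np.interp(fine_t, knots, wander))
    return 2 * np.pi * cumulative_trapezoid(freq, fine_t, initial=0.0)


def _ecg_waveform(t: np.ndarray, r_times: np.ndarray) -> np.ndarray:
    """Sum of R (sharp) and T (broad) bumps at the given beat times."""
    ecg = np.zeros_like(t)
    for rt in r_times:
        near = np.abs(t - rt) < 0.6
        dt = t[near] - rt
        ecg[near] += 1.0 * np.exp(-0.5 * (dt / 0.018) ** 2)  # R
        ecg[near] += 0.28 * np.exp(-0.5 * ((dt - 0.30) / 0.05) ** 2)  # T
        ecg[near] -= 0.12 * np.exp(-0.5 * ((dt - 0.045) / 0.02) ** 2)  # S
    return ecg


def _bp_waveform(t: np.ndarray, beat_times: np.ndarray, systolic: float,
                 diastolic: float) -> np.ndarray:
    """Pulsatile arterial pressure: fast systolic rise, decay to diastole."""
    bp = np.full_like(t, diastolic)
    bounds = np.concatenate([beat_times, [t[-1] + 1.0]])
    for k in range(len(beat_times)):
        t0, t1 = bounds[k], bounds[k + 1]
        seg = (t >= t0) & (t < t1)
        if not np.any(seg):
            continue
        s = (t[seg] - t0) / 0.12
        pulse = s * np.exp(1 - s)  # peak 1 at s = 1 (0.12 s after foot)
        bp[seg] = diastolic + (systolic - diastolic) * pulse
    return bp


def simulate_streams(config: SimulationConfig) -> tuple[RecordingMetadata, list[XDFStream], GroundTruth]:
    """Build the synthetic recording in memory (metadata, XDF streams, truth)."""
    rng = np.random.default_rng(config.seed)
    rate = config.fnirs_rate
    n_samples = int(round(config.duration * rate))
    ts = np.arange(n_samples) / rate
    n_ch = config.n_channels

    # master fine grid for oscillator phases, shared by every stream
    fine_rate = max(config.ecg_rate, config.bp_rate)
    fine_t = np.arange(int(round(config.duration * fine_rate))) / fine_rate
    phases = {
        name: _wandering_phase(rng, art.frequency, art.jitter, fine_t)
        for name, art in config.artifacts.items()
    }

    # block design: trial onsets on exact fNIRS samples
    trial_samples = int(round(config.trial_duration * rate))
    first = int(round((config.lead_in + config.pre) * rate))
    onsets = first + trial_samples * np.arange(config.n_trials)
    boxcar = np.zeros(n_samples)
    task_samples = int(round(config.task * rate))
    for onset in onsets:
        boxcar[onset : onset + task_samples] = 1.0
    kernel = hrf_kernel(rate, config.hrf_time_to_peak, config.hrf_undershoot)
    response = np.convolve(boxcar, kernel)[:n_samples]
    response *= config.hrf_amplitude / max(response.max(), 1e-30)

    clean_hbo = np.tile(response, (n_ch, 1))
    clean_hbr = config.deoxy_ratio * clean_hbo

    artifact_traces, artifact_gains = {}, {}
    hbo_total = clean_hbo.copy()
    hbr_total = clean_hbr.copy()
    for name, art in config.artifacts.items():
        common = np.sin(np.interp(ts, fine_t, phases[name]))
        gains = art.amplitude * rng.uniform(0.8, 1.2, n_ch)
        artifact_traces[name] = common
        artifact_gains[name] = gains
        hbo_total += gains[:, None] * common[None, :]
        hbr_total += abs(config.deoxy_ratio) * gains[:, None] * common[None, :]
    hbo_total += rng.normal(0, config.noise_sd, hbo_total.shape)
    hbr_total += rng.normal(0, config.noise_sd, hbr_total.shape)

    # Beer-Lambert forward model: dA = (eps @ [dHb, dHbO2]) * dpf * l
    bl = config.beer_lambert
    baselines = rng.uniform(0.5, 2.0, (n_ch, 2))
    intensities = np.empty((n_ch, n_samples, 2))
    for ch in range(n_ch):
        dc = np.vstack([hbr_total[ch], hbo_total[ch]])
        dA = bl.extinction @ dc  # per wavelength
        for w in range(2):
            intensities[ch, :, w] = baselines[ch, w] * 10.0 ** (
                -dA[w] * bl.dpf[w] * bl.distance
            )

    # cardiac events from the HR oscillator phase (beats at phase = 2*pi*k)
    hr_phase = phases.get("HR")
    if hr_phase is None:
        hr_phase = _wandering_phase(rng, 1.2, 0.1, fine_t)
    n_beats = int(hr_phase[-1] // (2 * np.pi))
    beat_times = np.interp(
        2 * np.pi * np.arange(1, n_beats + 1), hr_phase, fine_t
    )

    ecg_t = np.arange(int(round(config.duration * config.ecg_rate))) / config.ecg_rate
    ecg = _ecg_waveform(ecg_t, beat_times) + rng.normal(0, 0.01, ecg_t.size)

    resp_t = np.arange(int(round(config.duration * config.resp_rate))) / config.resp_rate
    rf_phase = phases.get("RF")
    if rf_phase is None:
        rf_phase = _wandering_phase(rng, 0.3, 0.1, fine_t)
    resp = np.sin(np.interp(resp_t, fine_t, rf_phase)) + rng.normal(0, 0.01, resp_t.size)

    bp_t = np.arange(int(round(config.duration * config.bp_rate))) / config.bp_rate
    bp = _bp_waveform(bp_t, beat_times, config.systolic, config.diastolic)
    mth_phase = phases.get("MTH")
    if mth_phase is None:
        mth_phase = _wandering_phase(rng, 0.1, 0.1, fine_t)
    bp += config.bp_mayer_amplitude * np.sin(np.interp(bp_t, fine_t, mth_phase))
    bp += rng.normal(0, 0.2, bp_t.size)

    hr_t = np.arange(int(round(config.duration * config.hr_rate))) / config.hr_rate
    inst_rate = 60.0 / np.diff(beat_times)
    hr_trace = np.interp(hr_t, beat_times[1:], inst_rate)
    hr_trace += config.hr_mayer_amplitude * np.sin(np.interp(hr_t, fine_t, mth_phase))

    # markers: condition values cycle over trials, stamped at exact onset times
    cond_values = [marker for _, marker in config.conditions]
    marker_values = np.array(
        [cond_values[k % len(cond_values)] for k in range(config.n_trials)]
    )
    marker_times = ts[onsets]

    fnirs_vals = np.concatenate(
        [intensities[:, :, 0].T, intensities[:, :, 1].T], axis=1
    )
    streams = [
        XDFStream(1, "NIRScout", "NIRS", 2 * n_ch, rate, "double64",
                  fnirs_vals, ts),
        XDFStream(2, "gUSBamp-ECG", "ECG", 1, config.ecg_rate, "double64",
                  ecg[:, None], ecg_t),
        XDFStream(3, "RespBelt", "Resp", 1, config.resp_rate, "double64",
                  resp[:, None], resp_t),
        XDFStream(4, "CNAP-BP", "BP", 1, config.bp_rate, "double64",
                  bp[:, None], bp_t),
        XDFStream(5, "HeartRate", "HR", 1, config.hr_rate, "double64",
                  hr_trace[:, None], hr_t),
        XDFStream(6, "ParadigmMarkers", "Markers", 1, 0.0, "int32",
                  marker_values[:, None].astype(np.int32), marker_times),
    ]

    metadata = RecordingMetadata(
        n_sources=16,
        n_detectors=24,
        wavelengths=[760.0, 850.0],
        sampling_rate=rate,
        date="2026-01-01",
        filename="synthetic",
        active_channels=list(range(1, n_ch + 1)),
    )
    truth = GroundTruth(
        timestamps=ts,
        clean_hbo=clean_hbo,
        clean_hbr=clean_hbr,
        artifact_traces=artifact_traces,
        artifact_gains=artifact_gains,
        hbo_total=hbo_total,
        hbr_total=hbr_total,
        onset_samples=onsets,
        marker_values=marker_values,
        r_peak_times=beat_times,
        beat_times=beat_times,
        baselines=baselines,
    )
    return metadata, streams, truth


def simulate_recording(
    config: SimulationConfig, out_dir
) -> tuple[dict[str, Path], GroundTruth]:
    """Write HDR + XDF (+ JSON ground-truth sidecar) for a synthetic run.

    Returns the file paths and the full in-memory ground truth.  The sidecar
    keeps the compact part of the truth (events, gains, baselines, config);
    the dense traces live on the returned object.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    metadata, streams, truth = simulate_streams(config)
    hdr_path = out_dir / "synthetic.hdr"
    xdf_path = out_dir / "synthetic.xdf"
    truth_path = out_dir / "synthetic_truth.json"
    write_hdr(hdr_path, metadata)
    write_xdf(xdf_path, streams)
    sidecar = {
        "config": _config_dict(config),
        "onset_samples": truth.onset_samples.tolist(),
        "marker_values": truth.marker_values.tolist(),
        "beat_times": truth.beat_times.tolist(),
        "artifact_gains": {k: v.tolist() for k, v in truth.artifact_gains.items()},
        "baselines": truth.baselines.tolist(),
    }
    truth_path.write_text(json.dumps(sidecar, indent=1))
    return {"hdr": hdr_path, "xdf": xdf_path, "truth": truth_path}, truth


def _config_dict(config: SimulationConfig) -> dict:
    d = asdict(config)
    d["beer_lambert"] = {
        "extinction": config.beer_lambert.extinction.tolist(),
        "dpf": list(config.beer_lambert.dpf),
        "distance": config.beer_lambert.distance,
    }
    return d


def make_tf_fixture(
    taps: np.ndarray,
    n_samples: int = 2000,
    noise_sd: float = 0.01,
    rate: float = 3.91,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, GroundTruth]:
    """Exact FIR fixture: x[n] = sum_u g[u] y[n-u] + white noise.

    The regressor ``y`` is band-limited noise (white noise smoothed by a
    short moving average) so the FIR design matrix is well conditioned.
    Returns ``(x, y, truth)`` with the taps recorded in the truth.
    """
    taps = np.asarray(taps, dtype=float)
    rng = np.random.default_rng(seed)
    y = rng.standard_normal(n_samples)
    y = np.convolve(y, np.ones(3) / 3, mode="same")
    y -= y.mean()
    x = np.convolve(y, taps)[:n_samples]
    if noise_sd > 0:
        x = x + rng.normal(0, noise_sd, n_samples)
    ts = np.arange(n_samples) / rate
    empty = np.empty((0, 0))
    truth = GroundTruth(
        timestamps=ts, clean_hbo=empty, clean_hbr=empty, artifact_traces={},
        artifact_gains={}, hbo_total=empty, hbr_total=empty,
        onset_samples=np.empty(0, int), marker_values=np.empty(0, int),
        r_peak_times=np.empty(0), beat_times=np.empty(0),
        baselines=np.empty((0, 2)), taps=taps,
    )
    return x, y, truth
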