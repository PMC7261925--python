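"""Run configuration, validation, and single-run / grand-average orchestration.

A run is described by a layered YAML document (schema version 1) mirroring
the analysis settings a user would otherwise click together: input files,
condition table, correction method and artifact windows, filter toggles,
timing, exclusions and figure options.  ``validate_config`` checks the
document against the available streams and reports every problem instead of
crashing; ``run_single`` executes the full pipeline
(io -> conversion -> filters -> correction -> epochs -> averaging ->
outputs) and ``run_grand_average`` combines subject outputs.

Outputs land in ``output_dir/study/subject/run/condition`` with the
subject/task/condition prefix and correction-method suffix in file names.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from numbers import Real
from pathlib import Path

import numpy as np
import yaml

from . import artifact_correction as ac
from . import epochs as ep
from . import haemodynamics as hd
from . import physio as ph
from . import probe_outputs as po
from .errors import FnirsKitError, ProcessingError
from .io_formats import RawRecording, align_streams, load_xdf, parse_hdr

SCHEMA_VERSION = 1

VALID_METHODS = ("uncorrected", "car", "ica", "tf")
VALID_MTH_SOURCES = ("bp_dia", "bp_sys", "hr")


@dataclass
class ValidationMessage:
    severity: str  # error | warning
    step: str
    text: str


@dataclass
class ValidationReport:
    """Outcome of configuration validation; ready iff no error messages."""

    messages: list[ValidationMessage] = field(default_factory=list)

    @property
    def status(self) -> str:
        return "error" if self.errors else "ready"

    @property
    def errors(self) -> list[ValidationMessage]:
        return [m for m in self.messages if m.severity == "error"]

    def add_error(self, step: str, text: str) -> None:
        self.messages.append(ValidationMessage("error", step, text))

    def add_warning(self, step: str, text: str) -> None:
        self.messages.append(ValidationMessage("warning", step, text))


@dataclass
class RunConfig:
    """Parsed analysis settings for one run."""

    hdr: str = ""
    xdf: list[str] = field(default_factory=list)
    output_dir: str = "."
    study: str = "study"
    subject: str = "S01"
    run: str = "1"
    task: str = "task"
    probe_set: int = 8
    display: str = "averaged"  # continuous | averaged
    conditions: list[dict] = field(default_factory=lambda: [{"name": "task", "marker": 1}])
    condition: str = ""
    method: str = "uncorrected"
    correct_artifacts: list[str] = field(default_factory=lambda: ["MTH", "RF", "HR"])
    mth_source: str = "bp_dia"
    windows: dict = field(default_factory=dict)
    bands: dict = field(default_factory=dict)
    baseline_filter: bool = True
    notch_filter: bool = True
    lowpass_filter: bool = False
    lowpass_cutoff: object = 0.5
    pre: float = 5.0
    task_s: float = 12.0
    post: float = 8.0
    exclude_trials: list[int] = field(default_factory=list)  # 1-based
    exclude_channels: list[int] = field(default_factory=list)  # 1-based
    optode_failure: dict | None = None  # {"channel": 1-based, "neighbors": [...]}
    figures: bool = False
    topomap_windows: list | None = None
    concentration_range: list | None = None
    tf_order: int = 8
    subtract_pre_mean: bool = False

    @classmethod
    def from_dict(cls, doc: dict) -> "RunConfig":
        cfg = cls()
        inp = doc.get("input", {})
        cfg.hdr = inp.get("hdr", doc.get("hdr", ""))
        xdf = inp.get("xdf", doc.get("xdf", []))
        cfg.xdf = [xdf] if isinstance(xdf, str) else list(xdf)
        for key in ("output_dir", "study", "subject", "task", "probe_set",
                    "display", "conditions", "condition", "method", "tf_order",
                    "subtract_pre_mean"):
            if key in doc:
                setattr(cfg, key, doc[key])
        cfg.run = str(doc.get("run", cfg.run))
        art = doc.get("artifacts", {})
        cfg.correct_artifacts = list(art.get("correct", cfg.correct_artifacts))
        cfg.mth_source = art.get("mth_source", cfg.mth_source)
        cfg.windows = {k: tuple(v) for k, v in art.get("windows", {}).items()}
        cfg.bands = {k: tuple(v) for k, v in art.get("bands", {}).items()}
        filt = doc.get("filters", {})
        cfg.baseline_filter = bool(filt.get("baseline", cfg.baseline_filter))
        cfg.notch_filter = bool(filt.get("notch", cfg.notch_filter))
        cfg.lowpass_filter = bool(filt.get("lowpass", cfg.lowpass_filter))
        cfg.lowpass_cutoff = filt.get("lowpass_cutoff", cfg.lowpass_cutoff)
        timing = doc.get("timing", {})
        cfg.pre = timing.get("pre", cfg.pre)
        cfg.task_s = timing.get("task", cfg.task_s)
        cfg.post = timing.get("post", cfg.post)
        excl = doc.get("exclude", {})
        cfg.exclude_trials = list(excl.get("trials", []))
        cfg.exclude_channels = list(excl.get("channels", []))
        cfg.optode_failure = excl.get("optode_failure")
        figs = doc.get("figures", {})
        if isinstance(figs, dict):
            cfg.figures = bool(figs.get("enabled", False))
            cfg.topomap_windows = figs.get("topomap_windows")
            cfg.concentration_range = figs.get("concentration_range")
        else:
            cfg.figures = bool(figs)
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(doc)

    def artifact_definitions(self) -> list[ac.ArtifactDefinition]:
        arts = []
        for name in ("MTH", "RF", "HR"):  # fixed correction order
            if name not in self.correct_artifacts:
                continue
            window = tuple(self.windows.get(name, ac.DEFAULT_SEARCH_WINDOWS[name]))
            band = self.bands.get(name)
            source = self.mth_source if name == "MTH" else ac.DEFAULT_SOURCES[name]
            arts.append(ac.ArtifactDefinition(name, window, band, source))
        return arts

    def paradigm(self) -> ep.Paradigm:
        conds = [
            ep.Condition(str(c["name"]), int(c["marker"]), c.get("n_trials"))
            for c in self.conditions
        ]
        return ep.Paradigm(conditions=conds, pre=self.pre, task=self.task_s, post=self.post)

    def selected_condition(self) -> ep.Condition:
        paradigm = self.paradigm()
        if not self.condition:
            return paradigm.conditions[0]
        for cond in paradigm.conditions:
            if cond.name == str(self.condition):
                return cond
        raise ProcessingError(f"condition '{self.condition}' is not defined")


def validate_config(config: RunConfig, available_streams: set[str] | None = None) -> ValidationReport:
    """Validate completeness, types and stream availability; never raises."""
    report = ValidationReport()
    try:
        _validate(config, available_streams, report)
    except Exception as exc:  # validation is total
        report.add_error("validation", f"internal validation failure: {exc}")
    return report


def _artifact_sources_needed(config: RunConfig) -> dict[str, str]:
    needed = {}
    for name in config.correct_artifacts:
        if name == "MTH":
            needed[name] = config.mth_source
        elif name in ac.DEFAULT_SOURCES:
            needed[name] = ac.DEFAULT_SOURCES[name]
        else:
            needed[name] = "?"
    return needed


def _validate(config: RunConfig, streams: set[str] | None, report: ValidationReport) -> None:
    if config.method not in VALID_METHODS:
        report.add_error("signal processing",
                         f"unknown correction method '{config.method}'")
    if config.display not in ("continuous", "averaged"):
        report.add_error("basics", f"unknown display mode '{config.display}'")

    markers = []
    for cond in config.conditions:
        if "name" not in cond or "marker" not in cond:
            report.add_error("conditions", f"condition missing name/marker: {cond}")
            continue
        if not isinstance(cond["marker"], int):
            report.add_error("conditions",
                             f"incorrect value: marker of condition '{cond['name']}'"
                             " must be an integer")
            continue
        markers.append(cond["marker"])
    if len(set(markers)) != len(markers):
        report.add_error("conditions", "condition marker values are not unique")
    if config.condition:
        names = [str(c.get("name")) for c in config.conditions]
        if str(config.condition) not in names:
            report.add_error("basics", f"selected condition '{config.condition}'"
                             " is not defined")

    for label, value in (("pre", config.pre), ("task", config.task_s), ("post", config.post)):
        if not isinstance(value, Real):
            report.add_error("timing", f"incorrect value: {label} must be a number")
    if isinstance(config.task_s, Real) and config.task_s <= 0:
        report.add_error("timing", "task duration must be positive")

    if config.lowpass_filter:
        cutoff = config.lowpass_cutoff
        if not isinstance(cutoff, Real):
            report.add_error("filters",
                             f"incorrect value: low-pass cutoff '{cutoff}'"
                             " is not a number")
        elif not 0 < float(cutoff) < 3.91 / 2:
            report.add_error("filters",
                             f"low-pass cutoff {cutoff} Hz outside (0, Nyquist)")

    try:
        n_channels = int(config.probe_set)
    except (TypeError, ValueError):
        report.add_error("basics", f"incorrect value: probe set '{config.probe_set}'")
        n_channels = None
    if n_channels is not None:
        for ch in list(config.exclude_channels):
            if not isinstance(ch, int) or not 1 <= ch <= n_channels:
                report.add_error("channels",
                                 f"excluded channel {ch} not in probe set 1..{n_channels}")
        if config.optode_failure:
            target = config.optode_failure.get("channel")
            neighbors = config.optode_failure.get("neighbors", [])
            members = [target, *neighbors]
            if not neighbors:
                report.add_error("artifacts", "optode failure needs neighbor channels")
            if target in neighbors:
                report.add_error("artifacts",
                                 f"optode-failure channel {target} listed as its own neighbor")
            for ch in members:
                if not isinstance(ch, int) or not 1 <= ch <= n_channels:
                    report.add_error("artifacts",
                                     f"optode-failure channel {ch} not in probe set")
        if config.method == "car" and n_channels < 2:
            report.add_error("signal processing", "CAR needs at least 2 channels")

    for t in config.exclude_trials:
        if not isinstance(t, int) or t < 1:
            report.add_error("artifacts", f"incorrect value: trial number {t}")

    if config.method == "tf" and "MTH" in config.correct_artifacts:
        if config.mth_source not in VALID_MTH_SOURCES:
            report.add_error("signal processing",
                             f"unknown MTH-waves source '{config.mth_source}'")

    if streams is not None and config.method in ("tf", "ica"):
        for name, source in _artifact_sources_needed(config).items():
            stream_needed = {"bp_dia": "bp", "bp_sys": "bp", "hr": "hr",
                             "resp": "resp", "ecg": "ecg"}.get(source, source)
            alternates = {"hr": ("ecg",)}.get(stream_needed, ())
            if stream_needed not in streams and not any(a in streams for a in alternates):
                if stream_needed == "bp":
                    report.add_error("signal processing",
                                     f"artifact {name}: no blood pressure data available")
                else:
                    report.add_error("signal processing",
                                     f"artifact {name}: no {stream_needed} data available")


def _load_and_concatenate(config: RunConfig, log: po.RunLog) -> RawRecording:
    """Load HDR + all XDF files, notch-filter ECG/resp, align, concatenate."""
    metadata = parse_hdr(Path(config.hdr).read_text())
    recordings = []
    for path in config.xdf:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            streams = load_xdf(path)
            if config.notch_filter:
                for kind in ("ecg", "resp"):
                    st = streams.get(kind)
                    if st is not None and st.nominal_rate > 100:
                        spec = hd.design_notch(st.nominal_rate)
                        st.values = hd.apply_filter(st.values.T, spec).T
                        log.info(f"{path}: 50 Hz notch applied to {kind} "
                                 f"({st.nominal_rate:g} Hz)")
            rec = align_streams(streams, metadata)
        for w in caught:
            log.warning(str(w.message))
        recordings.append(rec)
        log.info(f"loaded {path}: {rec.n_channels} channels, {rec.n_samples} samples")
    if len(recordings) == 1:
        return recordings[0]
    # concatenate runs on the time axis with per-file marker offsets
    offset = 0
    intensities, markers, physio_parts = [], [], {k: [] for k in recordings[0].physio}
    for rec in recordings:
        intensities.append(rec.intensities)
        markers.extend((idx + offset, val) for idx, val in rec.markers)
        for kind in physio_parts:
            if kind not in rec.physio:
                raise ProcessingError(f"run files disagree on available {kind} data")
            physio_parts[kind].append(rec.physio[kind])
        offset += rec.n_samples
    first = recordings[0]
    return RawRecording(
        intensities=np.concatenate(intensities, axis=1),
        timestamps=np.arange(offset) / metadata.sampling_rate,
        physio={k: np.concatenate(v) for k, v in physio_parts.items()},
        markers=markers,
        metadata=metadata,
    )


def _physio_traces(rec: RawRecording, streams_native: dict, log: po.RunLog) -> dict[str, np.ndarray]:
    """Continuous physiological traces at the fNIRS rate, incl. beat-derived ones."""
    traces = dict(rec.physio)
    bp = streams_native.get("bp")
    if bp is not None:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            beats = ph.detect_beats(bp[0], bp[1])
        for w in caught:
            log.warning(str(w.message))
        if len(beats) >= 2:
            for which, name in (("diastolic", "bp_dia"), ("systolic", "bp_sys")):
                traces[name] = ph.beat_series_to_trace(beats, which, rec.timestamps)
            annotation = ph.flag_hypertension(beats)
            log.info(f"blood pressure: mean systolic {annotation['mean_systolic']:.1f}, "
                     f"mean diastolic {annotation['mean_diastolic']:.1f} mm Hg"
                     + (" — hypertension" if annotation["hypertension"] else ""))
    if "hr" not in traces:
        ecg = streams_native.get("ecg")
        if ecg is not None:
            r_times = ph.detect_r_peaks(ecg[0], ecg[1])
            if r_times.size >= 3:
                hr = 60.0 / np.diff(r_times)
                traces["hr"] = np.interp(rec.timestamps, r_times[1:], hr)
                log.info(f"heart rate derived from ECG: {r_times.size} R-peaks")
    return traces


def run_single(config: RunConfig, validate: bool = True) -> dict:
    """Execute a full single-run analysis; returns the output bundle.

    The bundle carries the corrected block, epochs, averaged traces,
    before/after spectra, written file paths, the run log and the
    validation report.
    """
    log = po.RunLog(title=f"{config.subject} {config.task} {config.condition or ''}".strip())
    rec = _load_and_concatenate(config, log)

    report = None
    if validate:
        report = validate_config(config, set(rec.physio) | {"fnirs"})
        for msg in report.messages:
            (log.error if msg.severity == "error" else log.warning)(
                f"[{msg.step}] {msg.text}")
        if report.status != "ready":
            raise ProcessingError(
                "configuration errors: "
                + "; ".join(m.text for m in report.errors)
            )

    # native-rate streams for beat/R-peak detection
    native = {}
    for path in config.xdf[:1]:
        streams = load_xdf(path)
        for kind in ("bp", "ecg"):
            st = streams.get(kind)
            if st is not None:
                trace = st.values[:, 0] if st.values.ndim == 2 else st.values
                native[kind] = (trace, st.nominal_rate)

    block = hd.intensities_to_concentration(rec.intensities, rec.rate)
    log.info(f"Beer-Lambert conversion: {block.n_channels} channels, "
             f"{block.n_samples} samples at {block.rate:g} Hz")
    if config.baseline_filter:
        block = hd.filter_block(block, hd.design_baseline_highpass(block.rate))
        log.info("baseline drift removed (6th-order Butterworth high-pass, 0.005 Hz)")
    if config.lowpass_filter:
        spec = hd.design_lowpass(block.rate, float(config.lowpass_cutoff))
        block = hd.filter_block(block, spec)
        log.info(f"low-pass applied (8th-order Butterworth, {config.lowpass_cutoff} Hz)")

    raw_block = block.copy()
    artifacts = config.artifact_definitions()
    traces = _physio_traces(rec, native, log)
    regressors = None
    if config.method in ("tf", "ica") and artifacts:
        fallbacks = {"bp_dia": ("hr",), "bp_sys": ("hr",), "bp": ("ecg", "hr")}
        usable = []
        for art in artifacts:
            if art.source in traces:
                usable.append(art)
                continue
            alt = next((a for a in fallbacks.get(art.source, ()) if a in traces), None)
            if alt is not None:
                log.warning(f"artifact {art.name}: source '{art.source}' unavailable; "
                            f"falling back to '{alt}'")
                usable.append(ac.ArtifactDefinition(art.name, art.search_window,
                                                    art.correction_band, alt))
            else:
                raise ProcessingError(f"artifact '{art.name}': no {art.source} data available")
        artifacts = usable
        regressors = ph.build_regressors(traces, artifacts, block.rate)

    # artifact peak detection on the channel-mean spectrum
    mean_spectrum = ac.power_spectrum(block.hbo.mean(axis=0), block.rate)
    for art in artifacts:
        peak = ac.find_artifact_peak(mean_spectrum, art)
        if peak is None:
            log.warning(f"artifact {art.name}: no peak found in "
                        f"{art.search_window} Hz search window")
        else:
            log.info(f"artifact {art.name}: spectral peak at {peak:.3f} Hz")

    block = ac.correct_block(block, config.method, artifacts, regressors,
                             tf_order=config.tf_order)
    log.info(f"artifact correction: method={config.method}, "
             f"artifacts={[a.name for a in artifacts]}"
             + (f", FIR order {config.tf_order}" if config.method == "tf" else ""))

    if config.optode_failure:
        target = config.optode_failure["channel"] - 1
        neighbors = [n - 1 for n in config.optode_failure["neighbors"]]
        block = ep.interpolate_channel(block, target, neighbors)
        log.info(f"optode failure: channel {target + 1} interpolated from "
                 f"{[n + 1 for n in neighbors]}")

    paradigm = config.paradigm()
    condition = config.selected_condition()
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        epochs = ep.segment_trials(block, rec.markers, paradigm, condition)
        epochs.exclude_trials_1based(config.exclude_trials)
        epochs.excluded_channels |= {c - 1 for c in config.exclude_channels}
        averaged = ep.average_trials(epochs, subtract_pre_mean=config.subtract_pre_mean)
    for w in caught:
        log.warning(str(w.message))
    log.info(f"condition '{condition.name}': {epochs.n_trials} trials, "
             f"{epochs.n_samples} samples per epoch"
             + (f", excluded trials {sorted(epochs.excluded_trials)}"
                if epochs.excluded_trials else ""))

    out_dir = (Path(config.output_dir) / config.study / config.subject
               / config.run / condition.name)
    prefix = f"{config.subject}_{config.task}_{condition.name}"
    suffix = config.method.upper()
    paths = po.export_tables(averaged, out_dir, prefix=prefix, method_suffix=suffix)

    spectra = {}
    for label, blk in (("raw", raw_block), ("clean", block)):
        spectrum = ac.power_spectrum(blk.hbo.mean(axis=0), blk.rate)
        spectra[label] = spectrum
    import pandas as pd

    spec_frame = pd.DataFrame({
        "frequency_hz": spectra["raw"].frequencies,
        "raw_db": spectra["raw"].power_db,
        "clean_db": spectra["clean"].power_db,
    })
    spec_path = out_dir / po.output_name("Spectra_Compared", prefix, suffix, "csv")
    spec_frame.to_csv(spec_path, index=False, float_format="%.12g")
    paths.append(spec_path)

    if config.figures:
        layout = po.grid_layout(block.n_channels)
        spec_kwargs = {}
        if config.topomap_windows:
            spec_kwargs["windows"] = [tuple(w) for w in config.topomap_windows]
        if config.concentration_range:
            spec_kwargs["concentration_range"] = tuple(config.concentration_range)
        topo_spec = po.TopomapSpec(**spec_kwargs)
        kept = averaged["channels"]
        grids = po.topographic_grid(averaged["hbo"], averaged["time"], layout,
                                    topo_spec, channel_ids=list(kept))
        paths.append(po.plot_topomaps(
            grids, topo_spec, out_dir / po.output_name("Topoplot", prefix, suffix, "png")))
        paths.append(po.plot_averaged_channels(
            averaged, out_dir / po.output_name("Channels_Average", prefix, suffix, "png")))

    log_path = log.write(out_dir / po.output_name("Text_Output", prefix, suffix, "txt"))
    paths.append(log_path)

    return {
        "block": block,
        "raw_block": raw_block,
        "epochs": epochs,
        "averaged": averaged,
        "spectra": spectra,
        "paths": paths,
        "out_dir": out_dir,
        "log": log,
        "report": report,
        "recording": rec,
    }


def run_grand_average(
    subject_outputs: list[dict],
    rois: list[ep.ROIDefinition] | None = None,
    out_dir=None,
) -> dict:
    """Group-level analysis: grand average across subjects, then ROI traces."""
    if not subject_outputs:
        raise ProcessingError("grand average needs at least one subject output")
    result = {}
    averaged0 = subject_outputs[0]["averaged"]
    for key in ("hbo", "hbr"):
        result[key] = ep.grand_average([s["averaged"][key] for s in subject_outputs])
    result["time"] = averaged0["time"]
    result["channels"] = averaged0["channels"]
    result["rois"] = {}
    for roi in rois or []:
        result["rois"][roi.name] = {
            key: ep.roi_average(result[key], roi) for key in ("hbo", "hbr")
        }
    if out_dir is not None:
        out_dir = Path(out_dir)
        po.export_tables(result, out_dir, prefix="grand_average")
        for name, traces in result["rois"].items():
            import pandas as pd

            frame = pd.DataFrame({
                "time_s": result["time"],
                "hbo": traces["hbo"],
                "hbr": traces["hbr"],
            })
            frame.to_csv(out_dir / f"ROI_{name}.csv", index=False, float_format="%.12g")
    return result


__all__ = [
    "RunConfig",
    "ValidationReport",
    "ValidationMessage",
    "validate_config",
    "run_single",
    "run_grand_average",
    "FnirsKitError",
]
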