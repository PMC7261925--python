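"""Reading HDR metadata and XDF recordings, and aligning streams in time.

A continuous-wave NIRS measurement arrives as two files: a plain-text header
(HDR) with the optode setup, and an XDF container with the synchronized
streams — two-wavelength fNIRS intensities, ECG, respiration, continuous
blood pressure and heart rate, and the paradigm marker stream.  This module
parses both and resamples every auxiliary stream onto the fNIRS timeline so
that downstream processing can index everything by fNIRS sample.

HDR dialect
-----------
The header is INI-style ``key=value`` text.  The keys this package reads
(and its generator writes) are::

    [GeneralInfo]
    FileName="..."
    Date="..."
    [ImagingParameters]
    Sources=16
    Detectors=24
    Wavelengths="760 850"
    SamplingRate=3.91
    [DataStructure]
    ChannelIndices="1 2 3 ..."

Unknown keys and sections are ignored; quotes around values are optional.

fNIRS stream layout: a stream with ``2 * n_channels`` columns, the first
``n_channels`` at the first wavelength (760 nm) and the rest at the second
(850 nm).
"""

from __future__ import annotations

import configparser
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .errors import MetadataError, StreamError
from .xdf import XDFStream, read_xdf

#: Case-insensitive keywords used to infer a stream's kind from its
#: name/type fields.  First match (in this order) wins; override via the
#: ``kind_overrides`` argument of :func:`load_xdf`.
STREAM_KIND_KEYWORDS: dict[str, tuple[str, ...]] = {
    "markers": ("marker",),
    "fnirs": ("nirs",),
    "ecg": ("ecg",),
    "resp": ("resp",),
    "hr": ("hr", "heart"),
    "bp": ("bp", "cnap", "pressure"),
}

PHYSIO_KINDS = ("ecg", "resp", "bp", "hr")


@dataclass
class RecordingMetadata:
    """Measurement-setup metadata parsed from an HDR file."""

    n_sources: int
    n_detectors: int
    wavelengths: list[float]
    sampling_rate: float
    date: str = ""
    filename: str = ""
    active_channels: list[int] = field(default_factory=list)

    def __post_init__(self):
        if self.n_sources < 1 or self.n_detectors < 1:
            raise MetadataError("source and detector counts must be >= 1")
        if len(self.wavelengths) != 2:
            raise MetadataError(
                f"exactly two wavelengths required, got {self.wavelengths}"
            )
        if self.sampling_rate <= 0:
            raise MetadataError("sampling rate must be positive")


@dataclass
class Stream:
    """One named time series of a recording."""

    name: str
    kind: str  # fnirs | ecg | resp | bp | hr | markers
    timestamps: np.ndarray  # seconds
    values: np.ndarray  # samples x channels (markers: samples,)
    nominal_rate: float


@dataclass
class StreamSet:
    """All streams of one recording, keyed by kind."""

    streams: dict[str, Stream]

    def __contains__(self, kind: str) -> bool:
        return kind in self.streams

    def __getitem__(self, kind: str) -> Stream:
        return self.streams[kind]

    def get(self, kind: str):
        return self.streams.get(kind)


@dataclass
class RawRecording:
    """Synchronized recording on the fNIRS timeline.

    ``intensities`` is channels x samples x 2 wavelengths (arbitrary units);
    ``physio`` maps kind -> trace resampled to the fNIRS rate; ``markers``
    is a list of ``(sample_index, value)`` pairs.
    """

    intensities: np.ndarray
    timestamps: np.ndarray
    physio: dict[str, np.ndarray]
    markers: list[tuple[int, int]]
    metadata: RecordingMetadata

    @property
    def n_channels(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[1]

    @property
    def rate(self) -> float:
        return self.metadata.sampling_rate


def _unquote(value: str) -> str:
    value = value.strip()
    if len(value) >= 2 and value[0] == value[-1] and value[0] in "\"'":
        return value[1:-1]
    return value


_REQUIRED_HDR = {
    "Sources": ("ImagingParameters", int),
    "Detectors": ("ImagingParameters", int),
    "Wavelengths": ("ImagingParameters", str),
    "SamplingRate": ("ImagingParameters", float),
}


def parse_hdr(text: str) -> RecordingMetadata:
    """Parse HDR header text into :class:`RecordingMetadata`.

    Raises :class:`MetadataError` naming the first missing required key.
    """
    if not text or not text.strip():
        raise MetadataError("empty HDR content")
    parser = configparser.ConfigParser(interpolation=None, strict=False)
    try:
        parser.read_string(text)
    except configparser.Error as exc:
        raise MetadataError(f"unparseable HDR content: {exc}") from exc

    flat = {}
    for section in parser.sections():
        for key, value in parser.items(section):
            flat[key.lower()] = _unquote(value)

    for key in _REQUIRED_HDR:
        if key.lower() not in flat:
            raise MetadataError(f"HDR is missing required key '{key}'")

    try:
        wavelengths = [float(w) for w in flat["wavelengths"].split()]
        channels_raw = flat.get("channelindices", "")
        active = [int(c) for c in channels_raw.split()] if channels_raw else []
        return RecordingMetadata(
            n_sources=int(flat["sources"]),
            n_detectors=int(flat["detectors"]),
            wavelengths=wavelengths,
            sampling_rate=float(flat["samplingrate"]),
            date=flat.get("date", ""),
            filename=flat.get("filename", ""),
            active_channels=active,
        )
    except ValueError as exc:
        raise MetadataError(f"malformed HDR value: {exc}") from exc


def write_hdr(path, metadata: RecordingMetadata) -> None:
    """Write metadata in the HDR dialect read by :func:`parse_hdr`."""
    lines = [
        "[GeneralInfo]",
        f'FileName="{metadata.filename}"',
        f'Date="{metadata.date}"',
        "",
        "[ImagingParameters]",
        f"Sources={metadata.n_sources}",
        f"Detectors={metadata.n_detectors}",
        f'Wavelengths="{" ".join(f"{w:g}" for w in metadata.wavelengths)}"',
        f"SamplingRate={metadata.sampling_rate:g}",
        "",
        "[DataStructure]",
        f'ChannelIndices="{" ".join(str(c) for c in metadata.active_channels)}"',
        "",
    ]
    with open(path, "w") as fh:
        fh.write("\n".join(lines))


def _infer_kind(st: XDFStream, overrides: dict[str, str] | None) -> str | None:
    if overrides and st.name in overrides:
        return overrides[st.name]
    haystack = f"{st.name} {st.type}".lower()
    for kind, keywords in STREAM_KIND_KEYWORDS.items():
        if any(kw in haystack for kw in keywords):
            return kind
    return None


def load_xdf(path, kind_overrides: dict[str, str] | None = None) -> StreamSet:
    """Load an XDF file and classify its streams.

    Stream kinds are inferred from the stream name/type with the keyword map
    :data:`STREAM_KIND_KEYWORDS`; ``kind_overrides`` maps stream names to
    explicit kinds.  A missing fNIRS stream is fatal; a missing physiological
    stream only triggers a warning so the analysis can fall back to methods
    that do not need it.
    """
    streams: dict[str, Stream] = {}
    for st in read_xdf(path):
        kind = _infer_kind(st, kind_overrides)
        if kind is None:
            warnings.warn(f"stream '{st.name}' has unrecognized kind; ignored")
            continue
        ts = np.asarray(st.time_stamps, dtype=float)
        if ts.size > 1 and np.any(np.diff(ts) <= 0):
            raise StreamError(f"stream '{st.name}': timestamps not strictly increasing")
        if kind == "markers":
            if st.channel_format == "string":
                values = np.array([int(v[0]) for v in st.time_series])
            else:
                values = np.asarray(st.time_series, dtype=float)[:, 0].round().astype(int)
        else:
            values = np.asarray(st.time_series, dtype=float)
        streams[kind] = Stream(
            name=st.name, kind=kind, timestamps=ts, values=values,
            nominal_rate=st.nominal_srate,
        )
    if "fnirs" not in streams:
        raise StreamError(f"{path}: no fNIRS stream found")
    for kind in PHYSIO_KINDS:
        if kind not in streams:
            warnings.warn(f"no {kind} stream available")
    return StreamSet(streams=streams)


def resample_to(
    values: np.ndarray,
    timestamps: np.ndarray,
    target_timestamps: np.ndarray,
    source_rate: float,
    target_rate: float,
) -> np.ndarray:
    """Resample a trace onto target timestamps with anti-alias filtering.

    The trace is low-passed (zero phase) at 0.45x the target rate before
    interpolation, so downsampling from the physiological rates (200/256 Hz)
    to the fNIRS rate cannot alias.
    """
    vals = np.asarray(values, dtype=float)
    if source_rate > 2.5 * target_rate:
        sos = signal.butter(4, 0.45 * target_rate, "lowpass", fs=source_rate, output="sos")
        vals = signal.sosfiltfilt(sos, vals, axis=0)
    return np.interp(target_timestamps, timestamps, vals)


def align_streams(streams: StreamSet, metadata: RecordingMetadata) -> RawRecording:
    """Resample physiological streams and map markers onto the fNIRS timeline.

    Each marker is assigned the nearest fNIRS sample at or after its
    timestamp (causal: an epoch never starts before its event).  A
    physiological stream with no overlap with the fNIRS time span is dropped
    with a warning.
    """
    if "fnirs" not in streams:
        raise StreamError("fNIRS stream required for alignment")
    fnirs = streams["fnirs"]
    ts = fnirs.timestamps
    vals = fnirs.values
    n_channels = vals.shape[1] // 2
    # columns [0, n) -> wavelength 1, [n, 2n) -> wavelength 2
    intensities = np.stack([vals[:, :n_channels].T, vals[:, n_channels:].T], axis=-1)

    physio: dict[str, np.ndarray] = {}
    for kind in PHYSIO_KINDS:
        st = streams.get(kind)
        if st is None:
            continue
        if st.timestamps[-1] < ts[0] or st.timestamps[0] > ts[-1]:
            warnings.warn(f"{kind} stream lies outside the fNIRS time span; dropped")
            continue
        trace = st.values[:, 0] if st.values.ndim == 2 else st.values
        physio[kind] = resample_to(
            trace, st.timestamps, ts, st.nominal_rate, metadata.sampling_rate
        )

    markers: list[tuple[int, int]] = []
    mk = streams.get("markers")
    if mk is not None:
        for t, v in zip(mk.timestamps, mk.values):
            idx = int(np.searchsorted(ts, t, side="left"))
            if idx >= len(ts):
                warnings.warn(f"marker value {v} after the last fNIRS sample; dropped")
                continue
            markers.append((idx, int(v)))

    return RawRecording(
        intensities=intensities,
        timestamps=ts,
        physio=physio,
        markers=markers,
        metadata=metadata,
    )
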