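"""Probe-set montages, topographic maps, tables, figures and the run log.

Channel positions live on the unit disc (schematic scalp, nose up).  The
shipped montages place channels on a regular grid — positions affect only
visualization, never statistics — and can be replaced by editable layout
files.  Topographic maps time-average the trial mean inside configured
windows and interpolate the channel values onto a grid (linear
scattered-data interpolation, masked outside the convex hull, clipped to a
configured concentration range).

Tabular exports follow the toolbox naming scheme: subject/task/condition
prefix, ``Signal_oxy``/``Signal_deoxy`` stem, correction-method suffix;
CSV always, ``.xlsx`` when openpyxl is importable.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import griddata

from .errors import ConfigurationError, ProcessingError


@dataclass
class ProbeSetLayout:
    """Montage: channel id -> (source id, detector id, unit-disc position)."""

    name: str
    channels: dict[int, tuple[int, int, tuple[float, float]]]

    def __post_init__(self):
        for ch, (_, _, (x, y)) in self.channels.items():
            if x * x + y * y > 1.0 + 1e-9:
                raise ConfigurationError(f"channel {ch} position outside the unit disc")

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    def positions(self, channel_ids: list[int] | None = None) -> np.ndarray:
        ids = sorted(self.channels) if channel_ids is None else channel_ids
        return np.array([self.channels[ch][2] for ch in ids])


def grid_layout(n_channels: int, name: str | None = None) -> ProbeSetLayout:
    """Regular-grid montage for ``n_channels`` channels on the unit disc.

    Channels are laid out row-major on the smallest near-square grid and
    scaled to radius 0.9; sources/detectors are numbered consecutively as a
    schematic pairing.
    """
    if n_channels < 1:
        raise ConfigurationError("montage needs at least one channel")
    n_cols = int(np.ceil(np.sqrt(n_channels)))
    n_rows = int(np.ceil(n_channels / n_cols))
    channels = {}
    for ch in range(n_channels):
        row, col = divmod(ch, n_cols)
        x = (col - (n_cols - 1) / 2) / max((n_cols - 1) / 2, 1) * 0.636
        y = ((n_rows - 1) / 2 - row) / max((n_rows - 1) / 2, 1) * 0.636
        channels[ch] = (ch // 2 + 1, ch % 2 + 1, (x, y))
    return ProbeSetLayout(name=name or f"grid-{n_channels}", channels=channels)


@dataclass
class TopomapSpec:
    """Topographic-map settings: time windows (s, relative to task onset),
    concentration clipping range (mM*mm) and grid resolution."""

    windows: list[tuple[float, float]] = field(
        default_factory=lambda: [(-5.0, 0.0), (0.0, 7.0), (7.0, 14.0), (14.0, 20.0)]
    )
    concentration_range: tuple[float, float] = (-1.0, 1.0)
    grid_resolution: int = 64

    def __post_init__(self):
        lo, hi = self.concentration_range
        if lo >= hi:
            raise ConfigurationError("concentration range min must be < max")
        for i, (a, b) in enumerate(self.windows):
            if a >= b:
                raise ConfigurationError(f"topomap window {i} is empty")
            if i and a < self.windows[i - 1][1]:
                raise ConfigurationError("topomap windows must be ordered, non-overlapping")


def topographic_grid(
    traces: np.ndarray,
    time: np.ndarray,
    layout: ProbeSetLayout,
    spec: TopomapSpec,
    channel_ids: list[int] | None = None,
) -> list[np.ndarray]:
    """Interpolate window-averaged channel values onto 2-D scalp grids.

    ``traces`` is channels x samples with ``time`` in seconds relative to
    task onset.  Per window: average each channel over ``[start, end)``,
    clip to the concentration range, then linear scattered-data
    interpolation onto a ``grid_resolution`` square grid over [-1, 1]^2;
    points outside the convex hull of the channel positions are NaN.
    """
    traces = np.atleast_2d(np.asarray(traces, dtype=float))
    if traces.shape[0] < 3:
        raise ProcessingError("topographic interpolation needs >= 3 channels")
    points = layout.positions(channel_ids)
    if points.shape[0] != traces.shape[0]:
        raise ConfigurationError("layout/channel count mismatch")
    axis = np.linspace(-1, 1, spec.grid_resolution)
    gx, gy = np.meshgrid(axis, axis)
    lo, hi = spec.concentration_range
    grids = []
    for start, end in spec.windows:
        mask = (time >= start) & (time < end)
        if not np.any(mask):
            raise ProcessingError(f"topomap window [{start}, {end}) has no samples")
        values = np.clip(traces[:, mask].mean(axis=1), lo, hi)
        grids.append(griddata(points, values, (gx, gy), method="linear"))
    return grids


def output_name(stem: str, prefix: str = "", method_suffix: str = "", ext: str = "csv") -> str:
    """Compose ``{prefix}_{stem}_{suffix}.{ext}`` omitting empty parts."""
    parts = [p for p in (prefix, stem, method_suffix) if p]
    return "_".join(parts) + f".{ext}"


def export_tables(
    averaged: dict[str, np.ndarray],
    out_dir,
    prefix: str = "",
    method_suffix: str = "",
    write_xlsx: bool = True,
) -> list[Path]:
    """Write the averaged oxy/deoxy traces as time x channel tables.

    One file per chromophore (``Signal_oxy`` / ``Signal_deoxy``): rows are
    time points, first column the time axis, remaining columns the kept
    channels (1-based labels).  CSV at full float precision; an ``.xlsx``
    copy is written when openpyxl is available and ``write_xlsx`` is set.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    channels = averaged.get("channels")
    written = []
    for stem, key in (("Signal_oxy", "hbo"), ("Signal_deoxy", "hbr")):
        data = np.asarray(averaged[key])
        labels = (
            [f"ch{int(c) + 1}" for c in channels]
            if channels is not None
            else [f"ch{i + 1}" for i in range(data.shape[0])]
        )
        frame = pd.DataFrame(data.T, columns=labels)
        frame.insert(0, "time_s", averaged["time"])
        path = out_dir / output_name(stem, prefix, method_suffix, "csv")
        frame.to_csv(path, index=False, float_format="%.12g")
        written.append(path)
        if write_xlsx:
            try:
                import openpyxl  # noqa: F401
            except ImportError:
                continue
            xlsx = out_dir / output_name(stem, prefix, method_suffix, "xlsx")
            frame.to_excel(xlsx, index=False)
            written.append(xlsx)
    return written


def read_table(path) -> dict[str, np.ndarray]:
    """Read back an exported table as ``{"time", "data"}`` (channels x samples)."""
    frame = pd.read_csv(path)
    return {
        "time": frame["time_s"].to_numpy(),
        "data": frame.drop(columns="time_s").to_numpy().T,
    }


class RunLog:
    """Ordered, timestamped record of processing steps, warnings and errors."""

    def __init__(self, title: str = "analysis"):
        self.title = title
        self.events: list[tuple[str, str, str]] = []  # (timestamp, severity, message)

    def _stamp(self) -> str:
        return _dt.datetime.now().isoformat(timespec="seconds")

    def info(self, message: str) -> None:
        self.events.append((self._stamp(), "INFO", message))

    def warning(self, message: str) -> None:
        self.events.append((self._stamp(), "WARNING", message))

    def error(self, message: str) -> None:
        self.events.append((self._stamp(), "ERROR", message))

    def write(self, path) -> Path:
        return write_run_log(self.events, path, title=self.title)


def write_run_log(events: list[tuple[str, str, str]], path, title: str = "analysis") -> Path:
    """Write the run log as plain text: a header line, then one event per line."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = [f"# {title} — processing log", ""]
    lines += [f"{ts} [{sev}] {msg}" for ts, sev, msg in events]
    path.write_text("\n".join(lines) + "\n")
    return path


def plot_topomaps(grids: list[np.ndarray], spec: TopomapSpec, path, title: str = "") -> Path:
    """Render topographic maps to an image file (headless)."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, len(grids), figsize=(3 * len(grids), 3))
    axes = np.atleast_1d(axes)
    lo, hi = spec.concentration_range
    for ax, grid, (a, b) in zip(axes, grids, spec.windows):
        im = ax.imshow(grid, origin="lower", extent=(-1, 1, -1, 1), vmin=lo, vmax=hi,
                       cmap="RdBu_r")
        ax.set_title(f"{a:g}–{b:g} s")
        ax.set_axis_off()
    fig.colorbar(im, ax=axes, shrink=0.7, label="Δc (mM·mm)")
    if title:
        fig.suptitle(title)
    path = Path(path)
    fig.savefig(path, dpi=100)
    plt.close(fig)
    return path


def plot_averaged_channels(averaged: dict[str, np.ndarray], path, title: str = "") -> Path:
    """Render the trial-averaged oxy/deoxy traces for all kept channels."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 4))
    t = averaged["time"]
    ax.plot(t, averaged["hbo"].T, color="crimson", alpha=0.5, lw=0.8)
    ax.plot(t, averaged["hbr"].T, color="royalblue", alpha=0.5, lw=0.8)
    ax.axvline(0, color="k", lw=0.8)
    ax.set_xlabel("time from task onset (s)")
    ax.set_ylabel("Δc (mM·mm)")
    if title:
        ax.set_title(title)
    path = Path(path)
    fig.savefig(path, dpi=100)
    plt.close(fig)
    return path
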