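"""Epoch segmentation, trial/grand/ROI averaging, exclusions, interpolation.

A block-design run is cut into epochs around each paradigm marker: a
pre-task reference interval, the task interval and a post-task rest.  Epoch
length is ``round(pre * rate) + round((task + post) * rate)`` samples, with
the time axis zeroed at task onset.  Averages can exclude trials and
channels (configuration indices are 1-based, as users count them; internal
indices are 0-based), faulty optodes can be replaced by a neighbor mean,
and subject-level means combine into grand averages and ROI traces by
plain element-wise means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, ProcessingError
from .haemodynamics import ConcentrationBlock


@dataclass
class Condition:
    """One experimental condition: display name and its paradigm marker value."""

    name: str
    marker: int
    n_trials: int | None = None  # expected count; observed markers win


@dataclass
class Paradigm:
    """Block-design timing (seconds) and the condition table."""

    conditions: list[Condition]
    pre: float = 5.0
    task: float = 12.0
    post: float = 8.0

    def __post_init__(self):
        markers = [c.marker for c in self.conditions]
        if len(set(markers)) != len(markers):
            raise ConfigurationError("condition marker values must be unique")
        if self.pre < 0 or self.post < 0 or self.task <= 0:
            raise ConfigurationError("need pre/post >= 0 and task > 0 seconds")

    def epoch_samples(self, rate: float) -> tuple[int, int]:
        """(samples before onset, samples from onset) for one epoch."""
        return round(self.pre * rate), round((self.task + self.post) * rate)


@dataclass
class EpochSet:
    """Per-trial epochs: trials x channels x samples, for one chromophore pair."""

    hbo: np.ndarray
    hbr: np.ndarray
    rate: float
    pre_samples: int
    condition: str
    excluded_trials: set[int] = field(default_factory=set)
    excluded_channels: set[int] = field(default_factory=set)

    def __post_init__(self):
        self.hbo = np.asarray(self.hbo, dtype=float)
        self.hbr = np.asarray(self.hbr, dtype=float)
        if self.hbo.shape != self.hbr.shape or self.hbo.ndim != 3:
            raise ProcessingError("epochs must be trials x channels x samples, paired")
        for idx in self.excluded_trials:
            if not 0 <= idx < self.n_trials:
                raise ConfigurationError(f"excluded trial index {idx} out of range")
        for idx in self.excluded_channels:
            if not 0 <= idx < self.n_channels:
                raise ConfigurationError(f"excluded channel index {idx} out of range")

    @property
    def n_trials(self) -> int:
        return self.hbo.shape[0]

    @property
    def n_channels(self) -> int:
        return self.hbo.shape[1]

    @property
    def n_samples(self) -> int:
        return self.hbo.shape[2]

    @property
    def time(self) -> np.ndarray:
        """Time axis in seconds, 0 at task onset."""
        return (np.arange(self.n_samples) - self.pre_samples) / self.rate

    def exclude_trials_1based(self, trials: list[int]) -> None:
        """Exclude trials given as 1-based user-facing numbers."""
        for t in trials:
            if not 1 <= t <= self.n_trials:
                raise ConfigurationError(f"trial number {t} out of range 1..{self.n_trials}")
            self.excluded_trials.add(t - 1)


def segment_trials(
    block: ConcentrationBlock,
    markers: list[tuple[int, int]],
    paradigm: Paradigm,
    condition: Condition,
) -> EpochSet:
    """Cut one epoch per marker matching the condition's marker value.

    Epochs that would extend beyond the recording are dropped with a
    warning; no matching marker at all is an error.
    """
    if not markers:
        raise ProcessingError("no paradigm markers available for segmentation")
    before, after = paradigm.epoch_samples(block.rate)
    onsets = [idx for idx, val in markers if val == condition.marker]
    if not onsets:
        raise ProcessingError(
            f"no markers with value {condition.marker} for condition '{condition.name}'"
        )
    hbo_trials, hbr_trials = [], []
    for trial_no, onset in enumerate(onsets, start=1):
        start, stop = onset - before, onset + after
        if start < 0 or stop > block.n_samples:
            warnings.warn(
                f"trial {trial_no} (onset sample {onset}) exceeds the recording; dropped"
            )
            continue
        hbo_trials.append(block.hbo[:, start:stop])
        hbr_trials.append(block.hbr[:, start:stop])
    if not hbo_trials:
        raise ProcessingError(f"all trials of condition '{condition.name}' out of bounds")
    if condition.n_trials is not None and len(hbo_trials) != condition.n_trials:
        warnings.warn(
            f"condition '{condition.name}': expected {condition.n_trials} trials, "
            f"found {len(hbo_trials)}; proceeding with observed markers"
        )
    return EpochSet(
        hbo=np.stack(hbo_trials),
        hbr=np.stack(hbr_trials),
        rate=block.rate,
        pre_samples=before,
        condition=condition.name,
    )


def average_trials(
    epochs: EpochSet, subtract_pre_mean: bool = False
) -> dict[str, np.ndarray]:
    """Mean and SD over non-excluded trials, non-excluded channels only.

    Returns ``{"hbo", "hbr", "hbo_sd", "hbr_sd", "time", "channels"}`` where
    the arrays are channels x samples over the kept channel subset (original
    indices in ``channels``).  SD uses the n-1 denominator; a single kept
    trial reports SD 0 with a warning.  ``subtract_pre_mean`` removes each
    trial's pre-task mean first (per-trial baseline), default off.
    """
    trials = [t for t in range(epochs.n_trials) if t not in epochs.excluded_trials]
    if not trials:
        raise ProcessingError("all trials are excluded")
    channels = [c for c in range(epochs.n_channels) if c not in epochs.excluded_channels]
    if not channels:
        raise ProcessingError("all channels are excluded")
    hbo = epochs.hbo[np.ix_(trials, channels)]
    hbr = epochs.hbr[np.ix_(trials, channels)]
    if subtract_pre_mean and epochs.pre_samples > 0:
        hbo = hbo - hbo[:, :, : epochs.pre_samples].mean(axis=2, keepdims=True)
        hbr = hbr - hbr[:, :, : epochs.pre_samples].mean(axis=2, keepdims=True)
    if len(trials) == 1:
        warnings.warn("single trial: standard deviation reported as 0")
        sd_hbo = np.zeros_like(hbo[0])
        sd_hbr = np.zeros_like(hbr[0])
    else:
        sd_hbo = hbo.std(axis=0, ddof=1)
        sd_hbr = hbr.std(axis=0, ddof=1)
    return {
        "hbo": hbo.mean(axis=0),
        "hbr": hbr.mean(axis=0),
        "hbo_sd": sd_hbo,
        "hbr_sd": sd_hbr,
        "time": epochs.time,
        "channels": np.asarray(channels),
    }


def interpolate_channel(
    block: ConcentrationBlock, target: int, neighbors: list[int]
) -> ConcentrationBlock:
    """Replace a faulty-optode channel by the element-wise mean of neighbors."""
    if not neighbors:
        raise ConfigurationError("optode interpolation needs at least one neighbor")
    if target in neighbors:
        raise ConfigurationError(f"channel {target} cannot interpolate itself")
    for ch in [target, *neighbors]:
        if not 0 <= ch < block.n_channels:
            raise ConfigurationError(f"channel {ch} out of range")
    out = block.copy()
    out.hbo[target] = block.hbo[neighbors].mean(axis=0)
    out.hbr[target] = block.hbr[neighbors].mean(axis=0)
    return out


def grand_average(subject_means: list[np.ndarray]) -> np.ndarray:
    """Element-wise mean across subjects (channels x samples each)."""
    if not subject_means:
        raise ProcessingError("no subject means to average")
    shapes = [np.asarray(m).shape for m in subject_means]
    if len(set(shapes)) != 1:
        raise ProcessingError(f"subject shapes differ: {shapes}")
    return np.mean([np.asarray(m, dtype=float) for m in subject_means], axis=0)


@dataclass
class ROIDefinition:
    """A named set of channels averaged into one trace (0-based ids)."""

    name: str
    channels: list[int]

    def __post_init__(self):
        if not self.channels:
            raise ConfigurationError(f"ROI '{self.name}' has no channels")


def roi_average(
    traces: np.ndarray, roi: ROIDefinition, excluded: set[int] | None = None
) -> np.ndarray:
    """Element-wise mean over the ROI's member channels of a channels x samples array."""
    traces = np.atleast_2d(np.asarray(traces, dtype=float))
    excluded = excluded or set()
    bad = [ch for ch in roi.channels if ch in excluded]
    if bad:
        raise ProcessingError(f"ROI '{roi.name}' references excluded channels {bad}")
    for ch in roi.channels:
        if not 0 <= ch < traces.shape[0]:
            raise ConfigurationError(f"ROI '{roi.name}': channel {ch} out of range")
    return traces[roi.channels].mean(axis=0)
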