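"""Core data containers shared by every analysis stage.

A :class:`Recording` holds a continuous multichannel signal in microvolts
together with its sampling rate, ordered channel labels, and a stimulus
event stream.  An :class:`EpochSet` holds stimulus-locked trials as a
``trials x channels x samples`` array with per-trial condition labels and
validity flags.  Millisecond quantities are converted to samples with
``round(ms / 1000 * fs)`` throughout, so every window size is reproducible
at any sampling rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

#: The 14-site 10-20 montage shared by both systems after harmonization.
CHANNELS_14 = (
    "AF3", "F7", "F3", "FC5", "T7", "P7", "O1",
    "O2", "P8", "T8", "FC6", "F4", "F8", "AF4",
)

#: Electrode regions of interest used by the spectral analysis.
ROIS = {
    "anterior": ("AF3", "AF4", "F3", "F4"),
    "central": ("FC5", "FC6", "T7", "T8"),
    "posterior": ("P7", "P8", "O1", "O2"),
}

#: Frontal ROI used for ERP peak measurements.
FRONTAL_ROI = ("F3", "F4")

#: Occipital pair used for the resting-state envelope analysis.
OCCIPITAL_PAIR = ("O1", "O2")


def ms_to_samples(ms: float, fs: float) -> int:
    """Convert milliseconds to a whole number of samples at ``fs``."""
    return int(np.round(ms / 1000.0 * fs))


@dataclass
class Recording:
    """Continuous multichannel EEG segment.

    Parameters
    ----------
    signal
        ``(n_channels, n_samples)`` array in microvolts.
    fs
        Sampling rate in Hz.
    channels
        Ordered channel labels; must be unique.
    events
        ``(sample_index, label)`` pairs marking stimulus onsets.
    reference
        Free-text description of the current reference scheme.
    """

    signal: np.ndarray
    fs: float
    channels: tuple[str, ...]
    events: list[tuple[int, str]] = field(default_factory=list)
    reference: str = "raw"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        self.channels = tuple(self.channels)
        if self.signal.ndim != 2:
            raise ValueError("signal must be 2-D (channels x samples)")
        if self.signal.shape[0] != len(self.channels):
            raise ValueError(
                f"{self.signal.shape[0]} signal rows but "
                f"{len(self.channels)} channel labels"
            )
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("channel labels must be unique")
        n = self.signal.shape[1]
        for idx, label in self.events:
            if not 0 <= idx < n:
                raise ValueError(f"event {label!r} at sample {idx} outside [0, {n})")

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel_index(self, label: str) -> int:
        try:
            return self.channels.index(label)
        except ValueError:
            raise KeyError(f"unknown channel {label!r}") from None

    def pick(self, labels: Sequence[str]) -> np.ndarray:
        """Return the ``(len(labels), n_samples)`` view of selected channels."""
        return self.signal[[self.channel_index(c) for c in labels]]

    def copy_with(self, **changes) -> "Recording":
        return replace(self, **changes)


@dataclass
class EpochSet:
    """Stimulus-locked trials.

    ``data`` is ``(n_trials, n_channels, n_samples)``; the epoch covers the
    half-open interval ``[onset + start_ms, onset + end_ms)`` with the onset
    sample mapped exactly to t = 0.
    """

    data: np.ndarray
    fs: float
    channels: tuple[str, ...]
    window_ms: tuple[float, float]
    conditions: np.ndarray
    valid: np.ndarray
    baseline_interval_ms: tuple[float, float] | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.channels = tuple(self.channels)
        self.conditions = np.asarray(self.conditions, dtype=object)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.data.ndim != 3:
            raise ValueError("data must be 3-D (trials x channels x samples)")
        n_trials = self.data.shape[0]
        if self.conditions.shape != (n_trials,) or self.valid.shape != (n_trials,):
            raise ValueError("conditions/valid must have one entry per trial")
        expected = ms_to_samples(self.window_ms[1] - self.window_ms[0], self.fs)
        if self.data.shape[2] != expected:
            raise ValueError(
                f"epoch length {self.data.shape[2]} inconsistent with window "
                f"{self.window_ms} at fs={self.fs} (expected {expected})"
            )

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def onset_index(self) -> int:
        # index of the t = 0 sample inside the epoch
        return -ms_to_samples(self.window_ms[0], self.fs)

    @property
    def times_ms(self) -> np.ndarray:
        return (np.arange(self.n_samples) - self.onset_index) * 1000.0 / self.fs

    def channel_index(self, label: str) -> int:
        try:
            return self.channels.index(label)
        except ValueError:
            raise KeyError(f"unknown channel {label!r}") from None

    def roi_indices(self, roi: Sequence[str]) -> list[int]:
        return [self.channel_index(c) for c in roi]

    def copy_with(self, **changes) -> "EpochSet":
        return replace(self, **changes)
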