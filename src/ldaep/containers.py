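"""In-memory containers shared across the pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import defaults as d


@dataclass
class ContinuousRecording:
    """Continuous multi-channel recording in microvolts.

    ``samples`` is channels x time. ``bad_channels`` accumulates labels
    flagged by the robust-reference and noisy-channel rules;
    ``rejected_intervals`` holds [start, stop) sample spans masked by the
    segment-rejection rule. EOG channels are auxiliary: they are excluded
    from referencing, rejection statistics and interpolation.
    """

    samples: np.ndarray
    rate: float
    channel_labels: tuple[str, ...]
    bad_channels: set[str] = field(default_factory=set)
    rejected_intervals: list[tuple[int, int]] = field(default_factory=list)
    #: channels excluded from the average-reference estimate only; they stay
    #: in the data and are not interpolated
    reference_excluded: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        self.channel_labels = tuple(self.channel_labels)
        if self.samples.ndim != 2:
            raise ValueError("samples must be channels x time")
        if self.samples.shape[0] != len(self.channel_labels):
            raise ValueError("one label per channel required")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        if self.rate <= 0:
            raise ValueError("rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    def index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in recording") from None

    @property
    def eeg_labels(self) -> tuple[str, ...]:
        return tuple(ch for ch in self.channel_labels
                     if ch not in d.EOG_CHANNELS)

    @property
    def eog_labels(self) -> tuple[str, ...]:
        return tuple(ch for ch in self.channel_labels if ch in d.EOG_CHANNELS)

    def get(self, label: str) -> np.ndarray:
        return self.samples[self.index(label)]

    def copy(self) -> "ContinuousRecording":
        return ContinuousRecording(
            self.samples.copy(), self.rate, self.channel_labels,
            set(self.bad_channels), list(self.rejected_intervals),
            set(self.reference_excluded))


def make_event_table(onsets: np.ndarray, intensities: np.ndarray,
                     rate: float) -> pd.DataFrame:
    """Build and validate the event table (onset_sample, onset_s, intensity_db).

    Onsets must be strictly increasing and consecutive trials must differ in
    intensity (equal-loudness tones are never presented back to back).
    """
    onsets = np.asarray(onsets, dtype=int)
    intensities = np.asarray(intensities, dtype=float)
    if onsets.shape != intensities.shape:
        raise ValueError("onsets and intensities must align")
    if np.any(np.diff(onsets) <= 0):
        raise ValueError("event onsets must be strictly increasing")
    if np.any(intensities[1:] == intensities[:-1]):
        raise ValueError("consecutive trials must differ in intensity")
    return pd.DataFrame({
        "onset_sample": onsets,
        "onset_s": onsets / rate,
        "intensity_db": intensities,
    })


@dataclass
class EpochSet:
    """Stimulus-locked epochs: trials x channels x samples (uV).

    ``offsets`` are sample offsets relative to stimulus onset (onset = 0);
    ``retained`` marks trials surviving amplitude rejection.
    """

    data: np.ndarray
    rate: float
    channel_labels: tuple[str, ...]
    offsets: np.ndarray              # sample offsets rel. onset, len = n_samples
    intensity: np.ndarray            # per-trial dB
    retained: np.ndarray             # per-trial bool
    reference: str = "average"       # or "linked_mastoid"
    baseline_corrected: bool = False

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.channel_labels = tuple(self.channel_labels)
        self.offsets = np.asarray(self.offsets, dtype=int)
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.retained = np.asarray(self.retained, dtype=bool)
        n_trials, n_ch, n_samp = self.data.shape
        if n_ch != len(self.channel_labels) or n_samp != len(self.offsets):
            raise ValueError("epoch dimensions inconsistent with labels/offsets")
        if len(self.intensity) != n_trials or len(self.retained) != n_trials:
            raise ValueError("per-trial metadata inconsistent")

    @property
    def times_ms(self) -> np.ndarray:
        """Latency of each epoch sample in ms relative to stimulus onset."""
        return self.offsets * 1000.0 / self.rate

    def index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in epochs") from None

    def copy(self) -> "EpochSet":
        return EpochSet(self.data.copy(), self.rate, self.channel_labels,
                        self.offsets.copy(), self.intensity.copy(),
                        self.retained.copy(), self.reference,
                        self.baseline_corrected)


@dataclass
class EvokedSet:
    """Per-intensity average waveforms: intensity x channel x sample (uV)."""

    waveforms: np.ndarray
    intensities: np.ndarray
    n_trials: np.ndarray
    rate: float
    channel_labels: tuple[str, ...]
    offsets: np.ndarray

    @property
    def times_ms(self) -> np.ndarray:
        return self.offsets * 1000.0 / self.rate

    def index(self, label: str) -> int:
        return self.channel_labels.index(label)
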