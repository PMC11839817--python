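"""Configuration objects for the synthetic cohort generator and the
preprocessing chain, with YAML round-tripping.

All defaults are the study conditions the package emulates: a 100-subject
healthy-adult cohort (65 F / 35 M, ages 18-71), a 5-level loudness paradigm
(55-95 dB, 80 trials per level, ISI 1.2-1.8 s) recorded at 2048 Hz, and the
preprocessing parameters of the standard LDAEP pipeline.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

from . import defaults as d


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic LDAEP cohort.

    Slope units are uV/dB throughout (reported downstream under the
    conventional "uV/10 dB" label).
    """

    n_subjects: int = d.N_SUBJECTS
    sex_ratio: float = d.FEMALE_FRACTION          # fraction female
    age_range: tuple[float, float] = d.AGE_RANGE_YEARS
    hc_fraction: float = d.HC_FRACTION            # of females < hc_age_cutoff
    hc_age_cutoff: float = d.HC_AGE_CUTOFF

    intensities: tuple[float, ...] = d.INTENSITIES_DB
    trials_per_level: int = d.TRIALS_PER_LEVEL
    isi_range_ms: tuple[float, float] = d.ISI_RANGE_MS
    sampling_rate: float = d.SAMPLING_RATE_HZ
    montage: tuple[str, ...] = d.DEFAULT_MONTAGE

    base_slope_mean: Mapping[str, float] = field(
        default_factory=lambda: dict(d.BASE_SLOPE_MEAN))
    base_slope_sd: Mapping[str, float] = field(
        default_factory=lambda: dict(d.BASE_SLOPE_SD))
    base_amplitude_75db: Mapping[str, float] = field(
        default_factory=lambda: dict(d.BASE_AMPLITUDE_75DB))
    n1_fraction: float = 0.45                     # N1 share of the N1P2 split
    channel_correlation: float = 0.9              # subject deviations across channels

    beta_sex: float = d.BETA_SEX_MALE             # male = 1, female reference
    beta_age: float = d.BETA_AGE_PER_YEAR         # per year, age centered
    beta_hc: float = d.BETA_HC_USE                # HC user = 1

    # Couplings of distress/cognition to the FCz N1P2 slope z-score, in score
    # points per SD. Null by default; exposed for power studies only.
    bdi_slope_coupling: float = 0.0
    pss_slope_coupling: float = 0.0
    cognitive_slope_coupling: float = 0.0

    session_reliability: float = 0.8              # target single-measure ICC
    noise_spectrum_exponent: float = 1.0
    noise_rms_uv: float = 10.0
    blink_rate_per_min: float = 12.0
    blink_amplitude_uv: float = 100.0
    bad_channel_prob: float = 0.05
    line_noise_hz: float = 50.0
    line_noise_amplitude_uv: float = 0.0
    #: Stimulus onsets are locked to this sample grid (2 ms at 2048 Hz) so
    #: that decimation to the analysis rate preserves trial alignment.
    event_grid_samples: int = 4
    #: Scale injected evoked lobes so the measurement chain reads back the
    #: configured amplitudes (see recording.injection_gains).
    calibrate_injection: bool = True

    seed: int = 0

    def __post_init__(self) -> None:
        self.intensities = tuple(float(v) for v in self.intensities)
        if any(b <= a for a, b in zip(self.intensities, self.intensities[1:])):
            raise ValueError("intensities must be strictly increasing")
        if self.trials_per_level < 1:
            raise ValueError("trials_per_level must be >= 1")
        if not 0.0 < self.session_reliability <= 1.0:
            raise ValueError("session_reliability must lie in (0, 1]")
        if any(sd < 0 for sd in self.base_slope_sd.values()):
            raise ValueError("base_slope_sd values must be >= 0")
        if not 0.0 <= self.sex_ratio <= 1.0:
            raise ValueError("sex_ratio must lie in [0, 1]")
        if self.age_range[0] >= self.age_range[1]:
            raise ValueError("age_range must be increasing")
        if not 0.0 < self.n1_fraction < 1.0:
            raise ValueError("n1_fraction must lie in (0, 1)")
        required = set(d.MIDLINE_CHANNELS) | set(d.MASTOID_CHANNELS)
        if not required.issubset(self.montage):
            raise ValueError(
                f"montage must include {sorted(required)}")
        if not any(ch in self.montage for ch in d.EOG_CHANNELS):
            raise ValueError("montage must include at least one EOG channel")

    @property
    def eog_channels(self) -> tuple[str, ...]:
        return tuple(ch for ch in self.montage if ch in d.EOG_CHANNELS)

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data = {k: (list(v) if isinstance(v, tuple) else v)
                for k, v in data.items()}
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GeneratorConfig":
        data = yaml.safe_load(Path(path).read_text())
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - names
        if unknown:
            raise ValueError(f"unknown generator config keys: {sorted(unknown)}")
        for key in ("age_range", "intensities", "isi_range_ms", "montage"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


@dataclass
class PreprocessParams:
    """Parameters of the preprocessing chain (defaults = standard pipeline)."""

    analysis_rate: float = d.ANALYSIS_RATE_HZ
    highpass_hz: float = 1.0
    lowpass_hz: float = 30.0
    notch_hz: float | None = None
    highpass_order: int = 4
    lowpass_order: int = 5
    reference_sd_bounds: tuple[float, float] = (1.0, 25.0)
    segment_seconds: float = 1.0
    segment_channel_fraction: float = 0.5
    segment_amplitude_uv: float = 100.0
    channel_point_fraction: float = 0.1
    channel_amplitude_uv: float = 100.0
    epoch_window_ms: tuple[float, float] = (-100.0, 450.0)
    mastoids: tuple[str, str] = d.MASTOID_CHANNELS
    reject_channels: tuple[str, ...] = d.MIDLINE_CHANNELS
    reject_threshold_uv: float = 50.0

    def __post_init__(self) -> None:
        if not 0 < self.highpass_hz < self.lowpass_hz < self.analysis_rate / 2:
            raise ValueError("need 0 < highpass < lowpass < analysis_rate/2")
        lo, hi = self.epoch_window_ms
        if not lo < 0 < hi:
            raise ValueError("epoch window must straddle stimulus onset")

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data = {k: (list(v) if isinstance(v, tuple) else v)
                for k, v in data.items()}
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PreprocessParams":
        data = yaml.safe_load(Path(path).read_text())
        for key in ("reference_sd_bounds", "epoch_window_ms", "mastoids",
                    "reject_channels"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


#: Peak-measurement windows (closed, ms post-stimulus).
N1_WINDOW_MS = (60.0, 140.0)
P2_WINDOW_MS = (150.0, 250.0)
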