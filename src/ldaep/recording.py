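"""Continuous EEG synthesis for simulated LDAEP sessions.

Each recording is a sum of independent parts: 1/f-shaped Gaussian background
noise, optional line-noise sinusoid, blink transients propagated from the
EOG site over the frontal scalp, and the stimulus-locked evoked response.
The evoked response at each tone is a pair of Gaussian lobes (N1 negative,
centered 100 ms; P2 positive, centered 180 ms) scaled so that the N1P2
peak-to-peak at a midline channel follows the subject's session slope.
The subject's amplitude line is anchored at the softest level: the cohort
mean amplitude at 55 dB is common, and a subject's amplitudes grow from
there with their own slope, so steep subjects have large responses at loud
levels rather than impossible negative responses at soft ones. Targets are
floored at a small positive amplitude: evoked components do not invert, so
a (rare) subject whose line would cross zero saturates instead.

Because the downstream measurement chain (decimation plus zero-phase 1-30 Hz
filtering) is not perfectly amplitude-transparent, the injected lobe
amplitudes are calibrated against that chain: a small Newton solve on the
filtered unit-lobe responses makes the pipeline read back exactly the
configured amplitudes. The calibration is a deterministic function of the
configuration. Set ``calibrate_injection=False`` for raw nominal templates.

Stimulus onsets are locked to a coarse sample grid (2 ms at 2048 Hz) so that
decimation to the analysis rate preserves trial alignment exactly.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
import pandas as pd

from . import defaults as d
from .config import GeneratorConfig, PreprocessParams, N1_WINDOW_MS, P2_WINDOW_MS
from .containers import ContinuousRecording, make_event_table
from .synthetic import SubjectTruth

N1_CENTER_MS, N1_SIGMA_MS = 100.0, 15.0
P2_CENTER_MS, P2_SIGMA_MS = 180.0, 20.0

#: smallest injectable N1P2 peak-to-peak (uV); evoked responses never invert
AMPLITUDE_FLOOR_UV = 0.5


def target_amplitudes(truth: SubjectTruth, session: int,
                      config: GeneratorConfig) -> dict[str, dict[float, float]]:
    """Per-channel, per-level N1P2 peak-to-peak targets injected into a
    session recording (uV).

    amplitude(level) = mean amplitude at the softest level
                       + session_slope * (level - softest), floored at
    ``AMPLITUDE_FLOOR_UV``. The cohort mean at every level then follows the
    configured base amplitude and slope means.
    """
    lo = min(config.intensities)
    center = float(np.mean(config.intensities))
    slopes = truth.session_slopes[session - 1]
    out: dict[str, dict[float, float]] = {}
    for ch in d.MIDLINE_CHANNELS:
        base_soft = (config.base_amplitude_75db[ch]
                     - (center - lo) * config.base_slope_mean[ch])
        out[ch] = {lvl: max(base_soft + slopes[ch] * (lvl - lo),
                            AMPLITUDE_FLOOR_UV)
                   for lvl in config.intensities}
    return out


def nominal_lobe_amplitudes(n1p2: float, n1_fraction: float = 0.45
                            ) -> tuple[float, float]:
    """Split a target N1P2 peak-to-peak into (N1 depth, P2 height)."""
    return n1_fraction * n1p2, (1.0 - n1_fraction) * n1p2


def _lobes(times_s: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unit-peak N1 and P2 Gaussian lobes on a post-onset time axis (s)."""
    g1 = np.exp(-0.5 * ((times_s - N1_CENTER_MS / 1000) /
                        (N1_SIGMA_MS / 1000)) ** 2)
    g2 = np.exp(-0.5 * ((times_s - P2_CENTER_MS / 1000) /
                        (P2_SIGMA_MS / 1000)) ** 2)
    return g1, g2


def evoked_template(rate: float, n1_depth: float, p2_height: float,
                    duration_s: float = 0.45) -> np.ndarray:
    """Noise-free evoked waveform from stimulus onset: -N1 lobe + P2 lobe."""
    t = np.arange(int(round(duration_s * rate))) / rate
    g1, g2 = _lobes(t)
    return -n1_depth * g1 + p2_height * g2


def _measure_unit_response(template: np.ndarray, rate: float,
                           params: PreprocessParams) -> tuple[float, float]:
    """Push a single-pulse template through resample + filter + epoch +
    baseline and read the windowed N1/P2 extrema."""
    from . import preprocess as pp
    from .peaks import find_peak

    pad = int(round(4.0 * rate))
    sig = np.zeros(2 * pad + len(template))
    sig[pad:pad + len(template)] += template
    rec = ContinuousRecording(sig[None, :], rate, ("CAL",))
    events = pd.DataFrame({"onset_sample": [pad], "onset_s": [pad / rate],
                           "intensity_db": [75.0]})
    rec, events = pp.resample(rec, params.analysis_rate, events)
    rec = pp.filter_recording(rec, params.highpass_hz, params.lowpass_hz,
                              params.notch_hz, params.highpass_order,
                              params.lowpass_order)
    epochs, _ = pp.epoch(rec, events, params.epoch_window_ms)
    epochs = pp.baseline_correct(epochs)
    wave = epochs.data[0, 0]
    t = epochs.times_ms
    n1, _ = find_peak(wave, t, N1_WINDOW_MS, "negative")
    p2, _ = find_peak(wave, t, P2_WINDOW_MS, "positive")
    return n1, p2


@lru_cache(maxsize=8)
def _calibration_cached(key: tuple) -> tuple[float, float]:
    (rate, analysis_rate, hp, lp, notch, hp_order, lp_order, n1f, win) = key
    params = PreprocessParams(analysis_rate=analysis_rate, highpass_hz=hp,
                              lowpass_hz=lp, notch_hz=notch,
                              highpass_order=hp_order,
                              lowpass_order=lp_order, epoch_window_ms=win)
    rate_t = np.arange(int(round(0.45 * rate))) / rate
    g1, g2 = _lobes(rate_t)

    target = np.array([-n1f, 1.0 - n1f])     # measured (N1, P2) for unit N1P2
    # response matrix of the measurement chain to unit lobes
    r_n1 = _measure_unit_response(-g1, rate, params)
    r_p2 = _measure_unit_response(g2, rate, params)
    M = np.array([[r_n1[0], r_p2[0]], [r_n1[1], r_p2[1]]])
    amps = np.linalg.solve(M, target)
    for _ in range(3):                       # Newton polish (extrema may shift)
        measured = np.array(_measure_unit_response(
            amps[0] * (-g1) + amps[1] * g2, rate, params))
        if np.max(np.abs(measured - target)) < 1e-12:
            break
        amps += np.linalg.solve(M, target - measured)
    return float(amps[0]), float(amps[1])


def injection_gains(config: GeneratorConfig,
                    params: PreprocessParams | None = None
                    ) -> tuple[float, float]:
    """Lobe amplitudes (N1 depth scale, P2 height scale) per unit target
    N1P2, calibrated to the measurement chain. Pure function of the config
    and the preprocessing parameters."""
    if not config.calibrate_injection:
        return nominal_lobe_amplitudes(1.0, config.n1_fraction)
    params = params or PreprocessParams()
    key = (config.sampling_rate, params.analysis_rate, params.highpass_hz,
           params.lowpass_hz, params.notch_hz, params.highpass_order,
           params.lowpass_order, config.n1_fraction, params.epoch_window_ms)
    return _calibration_cached(key)


# ---------------------------------------------------------------------------
# event sequencing

def make_event_sequence(config: GeneratorConfig, rng: np.random.Generator
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Pseudo-randomized level sequence (no immediate repeats) and onset
    samples with ISI uniform in the configured range."""
    levels = np.repeat(config.intensities, config.trials_per_level)
    for _ in range(100):
        rng.shuffle(levels)
        if _repair_repeats(levels, rng):
            break
    else:
        raise RuntimeError("could not build a no-repeat level sequence")

    lo, hi = config.isi_range_ms
    isi = rng.uniform(lo, hi, size=len(levels) - 1) / 1000.0
    onsets = np.empty(len(levels), dtype=int)
    grid = config.event_grid_samples
    pos = 2.0  # seconds of lead-in
    onsets[0] = int(round(pos * config.sampling_rate / grid)) * grid
    for i, gap in enumerate(isi, start=1):
        raw = onsets[i - 1] + gap * config.sampling_rate
        onsets[i] = int(round(raw / grid)) * grid
    return onsets, levels


def _repair_repeats(levels: np.ndarray, rng: np.random.Generator) -> bool:
    """In-place swap repair of immediate repeats; True on success."""
    for _ in range(10 * len(levels)):
        bad = np.flatnonzero(levels[1:] == levels[:-1])
        if len(bad) == 0:
            return True
        i = bad[0] + 1
        cands = np.flatnonzero(
            (levels != levels[i])
            & (np.r_[levels[1:], np.nan] != levels[i])
            & (np.r_[np.nan, levels[:-1]] != levels[i]))
        cands = cands[cands != i - 1]
        if len(cands) == 0:
            return False
        j = int(rng.choice(cands))
        levels[i], levels[j] = levels[j], levels[i]
    return False


# ---------------------------------------------------------------------------
# signal synthesis

def one_over_f_noise(n_samples: int, rate: float, exponent: float,
                     rms: float, rng: np.random.Generator) -> np.ndarray:
    """Gaussian noise with a 1/f^exponent amplitude spectrum, scaled to the
    requested RMS."""
    white = rng.standard_normal(n_samples)
    if exponent == 0:
        x = white
    else:
        spec = np.fft.rfft(white)
        f = np.fft.rfftfreq(n_samples, 1.0 / rate)
        shape = np.ones_like(f)
        shape[1:] = f[1:] ** (-exponent / 2.0)
        shape[0] = 0.0
        x = np.fft.irfft(spec * shape, n=n_samples)
    sd = x.std()
    return x * (rms / sd) if sd > 0 else x


def _blink_wave(rate: float) -> np.ndarray:
    """300 ms positive-lobed blink transient (sin^2 envelope), unit peak."""
    t = np.arange(int(round(0.3 * rate))) / rate
    return np.sin(np.pi * t / 0.3) ** 2


def subject_rng(config: GeneratorConfig, subject_index: int,
                session: int) -> np.random.Generator:
    """Deterministic per-subject, per-session stream from the config seed."""
    return np.random.default_rng(
        np.random.SeedSequence([config.seed, 7919, subject_index, session]))


def generate_recording(truth: SubjectTruth, session: int,
                       config: GeneratorConfig,
                       rng: np.random.Generator | None = None,
                       params: PreprocessParams | None = None
                       ) -> tuple[ContinuousRecording, pd.DataFrame]:
    """Synthesize the continuous recording and event table for one session.

    ``session`` is 1-based and must be realized on ``truth``; midline
    channels carry the subject's exact per-channel evoked amplitudes, the
    surrounding scalp a scaled copy of the FCz response, and the
    mastoid-adjacent pair stays evoked-free.
    """
    if session > len(truth.session_slopes):
        raise ValueError(f"session {session} not realized for "
                         f"{truth.subject_id}")
    if rng is None:
        rng = subject_rng(config, 0, session)
    montage = config.montage
    rate = config.sampling_rate

    onsets, levels = make_event_sequence(config, rng)
    n_samples = int(np.ceil((onsets[-1] / rate + 3.0)))  # whole seconds
    n_samples = int(n_samples * rate)
    n_ch = len(montage)
    data = np.zeros((n_ch, n_samples))

    # background noise + line noise
    if config.noise_rms_uv > 0:
        for i in range(n_ch):
            data[i] += one_over_f_noise(n_samples, rate,
                                        config.noise_spectrum_exponent,
                                        config.noise_rms_uv, rng)
    if config.line_noise_amplitude_uv > 0:
        t = np.arange(n_samples) / rate
        phase = rng.uniform(0, 2 * np.pi)
        line = config.line_noise_amplitude_uv * np.sin(
            2 * np.pi * config.line_noise_hz * t + phase)
        for i, ch in enumerate(montage):
            if ch not in d.EOG_CHANNELS:
                data[i] += line

    # blinks on EOG, propagated to scalp
    if config.blink_rate_per_min > 0 and config.blink_amplitude_uv > 0:
        wave = _blink_wave(rate)
        n_blinks = rng.poisson(config.blink_rate_per_min *
                               n_samples / rate / 60.0)
        starts = rng.integers(0, n_samples - len(wave),
                              size=n_blinks) if n_blinks else []
        for s in starts:
            for i, ch in enumerate(montage):
                if ch in d.EOG_CHANNELS:
                    gain = 1.0
                else:
                    gain = d.BLINK_PROPAGATION.get(ch, 0.05)
                data[i, s:s + len(wave)] += (config.blink_amplitude_uv
                                             * gain * wave)

    # evoked responses
    a_n_unit, a_p_unit = injection_gains(config, params)
    t_template = np.arange(int(round(0.45 * rate))) / rate
    g1, g2 = _lobes(t_template)
    amp = target_amplitudes(truth, session, config)
    for onset, lvl in zip(onsets, levels):
        span = slice(onset, onset + len(t_template))
        for i, ch in enumerate(montage):
            if ch in d.EOG_CHANNELS or ch in d.MASTOID_CHANNELS:
                continue
            target = (amp[ch][lvl] if ch in amp
                      else d.EVOKED_SIDE_GAIN * amp["FCz"][lvl])
            data[i, span] += target * (-a_n_unit * g1 + a_p_unit * g2)

    # bad channels: large-amplitude noise on non-essential scalp sites
    essential = set(d.MIDLINE_CHANNELS) | set(d.MASTOID_CHANNELS) \
        | set(d.EOG_CHANNELS)
    if config.bad_channel_prob > 0:
        for i, ch in enumerate(montage):
            if ch in essential:
                continue
            if rng.random() < config.bad_channel_prob:
                data[i] = rng.normal(0.0, 80.0, size=n_samples)

    recording = ContinuousRecording(data, rate, montage)
    events = make_event_table(onsets, levels, rate)
    return recording, events
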