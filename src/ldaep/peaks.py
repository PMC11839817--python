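"""Evoked averaging and N1/P2 peak measurement.

The N1 is the most negative value 60-140 ms post-stimulus, the P2 the most
positive value 150-250 ms; windows are closed intervals over exact sample
latencies and ties break toward the earlier latency. N1P2 is the
peak-to-peak difference p2 - n1. Manual peak selection is supported through
an override table that pins a component to a fixed latency.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .config import N1_WINDOW_MS, P2_WINDOW_MS
from .containers import EpochSet, EvokedSet


def average_by_intensity(epochs: EpochSet) -> EvokedSet:
    """Average retained trials per loudness level (arithmetic mean)."""
    levels = np.unique(epochs.intensity)
    waves, counts = [], []
    for level in levels:
        mask = (epochs.intensity == level) & epochs.retained
        if not mask.any():
            raise ValueError(f"no retained trials at {level:g} dB")
        waves.append(epochs.data[mask].mean(axis=0))
        counts.append(int(mask.sum()))
    return EvokedSet(np.stack(waves), levels, np.array(counts), epochs.rate,
                     epochs.channel_labels, epochs.offsets.copy())


def find_peak(waveform: np.ndarray, times_ms: np.ndarray,
              window_ms: tuple[float, float], polarity: str
              ) -> tuple[float, float]:
    """Extremum of the stated polarity within a closed latency window.

    Returns ``(amplitude_uv, latency_ms)``; the latency is the exact sample
    latency (callers round for reporting). Ties break earliest.
    """
    lo, hi = window_ms
    mask = (times_ms >= lo) & (times_ms <= hi)
    if not mask.any():
        raise ValueError(f"window {window_ms} contains no samples at this rate")
    seg = waveform[mask]
    seg_t = times_ms[mask]
    if polarity == "negative":
        i = int(np.argmin(seg))
    elif polarity == "positive":
        i = int(np.argmax(seg))
    else:
        raise ValueError("polarity must be 'negative' or 'positive'")
    return float(seg[i]), float(seg_t[i])


def _amplitude_at(waveform: np.ndarray, times_ms: np.ndarray,
                  latency_ms: float) -> tuple[float, float]:
    """Amplitude at the sample nearest a requested latency."""
    if latency_ms < times_ms[0] or latency_ms > times_ms[-1]:
        raise ValueError(f"override latency {latency_ms} ms outside epoch")
    i = int(np.argmin(np.abs(times_ms - latency_ms)))
    return float(waveform[i]), float(times_ms[i])


def measure_components(evoked: EvokedSet,
                       channels: Sequence[str] = ("Fz", "FCz", "Cz"),
                       overrides: Mapping[tuple[str, float, str], float]
                       | None = None) -> pd.DataFrame:
    """Measure N1, P2 and N1P2 per channel x intensity.

    ``overrides`` maps ``(channel, intensity_db, component)`` to a manual
    latency in ms; the amplitude is then read at that latency and the row is
    flagged ``manual_override``. Output is a tidy table with one row per
    channel x intensity.
    """
    overrides = dict(overrides or {})
    t = evoked.times_ms
    rows = []
    for ch in channels:
        ci = evoked.index(ch)
        for li, level in enumerate(evoked.intensities):
            wave = evoked.waveforms[li, ci]
            flag = False
            key_n1 = (ch, float(level), "N1")
            key_p2 = (ch, float(level), "P2")
            if key_n1 in overrides:
                n1, n1_lat = _amplitude_at(wave, t, overrides[key_n1])
                flag = True
            else:
                n1, n1_lat = find_peak(wave, t, N1_WINDOW_MS, "negative")
            if key_p2 in overrides:
                p2, p2_lat = _amplitude_at(wave, t, overrides[key_p2])
                flag = True
            else:
                p2, p2_lat = find_peak(wave, t, P2_WINDOW_MS, "positive")
            rows.append({
                "channel": ch,
                "intensity_db": float(level),
                "n1_amplitude": n1,
                "n1_latency_ms": round(n1_lat),
                "p2_amplitude": p2,
                "p2_latency_ms": round(p2_lat),
                "n1p2": p2 - n1,
                "n_trials": int(evoked.n_trials[li]),
                "manual_override": flag,
            })
    return pd.DataFrame(rows)


def read_overrides(path) -> dict[tuple[str, float, str], float]:
    """Load a manual peak-selection table (TSV: channel, intensity_db,
    component, latency_ms; optional subject/session columns are ignored
    here)."""
    df = pd.read_csv(path, sep="\t")
    return {(r["channel"], float(r["intensity_db"]), r["component"]):
            float(r["latency_ms"]) for _, r in df.iterrows()}
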