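"""Preprocessing chain operations and their fixed-point / boundary
conventions."""

import itertools

import numpy as np
import pandas as pd
import pytest

from conftest import make_epochs
from ldaep.containers import ContinuousRecording
from ldaep.preprocess import average_reference, baseline_correct, \
    drop_noisy_channels, epoch, epoch_offsets, filter_recording, \
    interpolate_bad_channels, reject_epochs_amplitude, \
    reject_noisy_intervals, reindex_events, remove_eog_artifacts, resample, \
    rereference_linked_mastoid, robust_average_reference


def make_recording(data, rate=512.0, labels=None):
    data = np.atleast_2d(np.asarray(data, dtype=float))
    labels = labels or tuple(f"ch{i}" for i in range(data.shape[0]))
    return ContinuousRecording(data, rate, labels)


def events_frame(onsets, rate, intensities=None):
    onsets = np.asarray(onsets)
    if intensities is None:
        intensities = np.resize([55.0, 65.0], len(onsets))
    return pd.DataFrame({"onset_sample": onsets, "onset_s": onsets / rate,
                         "intensity_db": intensities})


class TestResample:
    def test_passband_tone_amplitude_preserved(self):
        t = np.arange(int(2048 * 4)) / 2048
        rec = make_recording(np.sin(2 * np.pi * 10 * t), rate=2048.0)
        out = resample(rec, 512.0)
        mid = out.samples[0, 256:-256]
        assert np.abs(mid).max() == pytest.approx(1.0, rel=0.01)
        assert out.rate == 512.0

    def test_constant_stays_constant(self):
        rec = make_recording(np.full(2048 * 2, 3.7), rate=2048.0)
        out = resample(rec, 512.0)
        assert np.allclose(out.samples[0, 10:-10], 3.7, atol=1e-6)

    def test_event_reindexing(self):
        ev = events_frame([2048], 2048.0, [75.0])
        out = reindex_events(ev, 2048.0, 512.0)
        assert out["onset_sample"].iloc[0] == 512
        # rounding half down: 2050/4 = 512.5 -> 512
        ev2 = events_frame([2050], 2048.0, [75.0])
        assert reindex_events(ev2, 2048.0, 512.0)["onset_sample"].iloc[0] \
            == 512

    def test_upsampling_rejected(self):
        rec = make_recording(np.zeros(512), rate=512.0)
        with pytest.raises(ValueError, match="upsampling"):
            resample(rec, 1024.0)


class TestFilter:
    def test_stopband_tone_suppressed(self):
        t = np.arange(512 * 10) / 512
        rec = make_recording(np.sin(2 * np.pi * 50 * t))
        out = filter_recording(rec, 1.0, 30.0)
        mid = out.samples[0, 1024:-1024]   # steady state, away from edges
        assert np.std(mid) < 0.01 * np.std(rec.samples[0])

    def test_passband_tone_kept(self):
        t = np.arange(512 * 10) / 512
        rec = make_recording(np.sin(2 * np.pi * 10 * t))
        out = filter_recording(rec, 1.0, 30.0)
        mid = out.samples[0, 512:-512]
        assert np.abs(mid).max() == pytest.approx(1.0, rel=0.05)

    def test_slow_drift_removed(self):
        # 0 -> 100 uV linear drift over 60 s; residual slope < 1 uV
        n = 512 * 60
        rec = make_recording(np.linspace(0.0, 100.0, n))
        out = filter_recording(rec, 1.0, 30.0)
        mid = out.samples[0, 512 * 2:-512 * 2]
        assert np.abs(mid).max() < 1.0

    def test_notch_removes_line_frequency(self):
        t = np.arange(512 * 10) / 512
        sig = np.sin(2 * np.pi * 10 * t) + 2 * np.sin(2 * np.pi * 25 * t)
        rec = make_recording(sig)
        out = filter_recording(rec, 1.0, 30.0, notch_hz=25.0)
        spec = np.abs(np.fft.rfft(out.samples[0]))
        freqs = np.fft.rfftfreq(out.n_samples, 1 / 512)
        assert spec[np.argmin(np.abs(freqs - 25))] < \
            0.05 * spec[np.argmin(np.abs(freqs - 10))]

    def test_invalid_edges(self):
        rec = make_recording(np.zeros(512))
        with pytest.raises(ValueError):
            filter_recording(rec, 30.0, 1.0)


class TestRobustAverageReference:
    def test_clean_channels_plain_average(self, rng):
        data = rng.normal(0, 10, (6, 512 * 4))
        rec = make_recording(data)
        out = robust_average_reference(rec)
        assert not out.reference_excluded
        assert np.allclose(out.samples.mean(axis=0), 0.0, atol=1e-9)

    def test_flat_channel_excluded_but_rereferenced(self, rng):
        data = rng.normal(0, 10, (16, 512 * 4))
        data[3] = 0.0
        rec = make_recording(data)
        out = robust_average_reference(rec)
        assert "ch3" in out.reference_excluded
        # still re-referenced: flat channel now carries -reference
        ref = data[[i for i in range(16) if i != 3]].mean(axis=0)
        assert np.allclose(out.samples[3], -ref, atol=0.5)

    def test_fixed_point_matches_brute_force(self, rng):
        # 4-channel toy: the huge channel inflates the reference enough to
        # push a borderline channel out of bounds; once the huge channel is
        # excluded, the borderline channel is re-admitted. Compare the
        # converged set with an exhaustive fixed-point search.
        n = 512 * 30
        data = np.vstack([
            rng.normal(0, 8, n),
            rng.normal(0, 10, n),
            rng.normal(0, 24, n),
            rng.normal(0, 90, n),
        ])
        rec = make_recording(data)
        out = robust_average_reference(rec)
        included = {int(ch[2:])
                    for ch in set(rec.channel_labels)
                    - out.reference_excluded}

        fixed_points = []
        for r in range(2, 5):
            for combo in itertools.combinations(range(4), r):
                ref = data[list(combo)].mean(axis=0)
                sd = (data - ref).std(axis=1)
                implied = {i for i in range(4) if 1 <= sd[i] <= 25}
                if implied == set(combo):
                    fixed_points.append(set(combo))
        assert included in fixed_points
        assert included == {0, 1, 2}   # huge channel out, borderline back in

    def test_too_few_survivors(self):
        rec = make_recording(np.zeros((4, 512)))
        with pytest.raises(ValueError, match="fewer than 2"):
            robust_average_reference(rec)

    def test_plain_average_reference_zero_mean(self, rng):
        rec = make_recording(rng.normal(0, 1, (5, 256)))
        out = average_reference(rec)
        assert np.allclose(out.samples.mean(axis=0), 0.0, atol=1e-12)


class TestSegmentAndChannelRejection:
    def _burst_recording(self, n_bad_channels, rng):
        data = rng.normal(0, 5, (16, 512 * 5))
        data[:n_bad_channels, 512:1024] += np.resize(
            [200.0, -200.0], 512)
        return make_recording(data)

    def test_clean_recording_keeps_everything(self, rng):
        rec = make_recording(rng.normal(0, 5, (16, 512 * 5)))
        out = reject_noisy_intervals(rec, 0.5, 100.0)
        assert out.rejected_intervals == []

    def test_burst_on_majority_rejected(self, rng):
        out = reject_noisy_intervals(self._burst_recording(9, rng), 0.5,
                                     100.0)
        assert (512, 1024) in out.rejected_intervals

    def test_exact_half_is_retained(self, rng):
        # "more than 50%" is strict: 8 of 16 does not trigger
        out = reject_noisy_intervals(self._burst_recording(8, rng), 0.5,
                                     100.0)
        assert out.rejected_intervals == []

    def test_noisy_channel_flagging_boundary(self, rng):
        n = 512 * 10
        data = rng.normal(0, 5, (8, n))
        k15, k5 = int(0.15 * n), int(0.05 * n)
        data[0, :k15] = np.resize([150.0, -150.0], k15)
        data[1, :k5] = np.resize([150.0, -150.0], k5)
        out = drop_noisy_channels(make_recording(data), 0.1, 100.0)
        assert "ch0" in out.bad_channels
        assert "ch1" not in out.bad_channels

    def test_flag_fraction_matches_naive_count(self, rng):
        data = rng.normal(0, 60, (6, 2000))
        rec = make_recording(data)
        naive = {f"ch{i}"
                 for i in range(6)
                 if sum(1 for v in data[i] if abs(v) > 100) / 2000 > 0.1}
        if len(naive) <= 3:
            out = drop_noisy_channels(rec, 0.1, 100.0)
            assert out.bad_channels == naive

    def test_unusable_recording_aborts(self, rng):
        data = rng.normal(0, 200, (6, 2000))
        with pytest.raises(RuntimeError, match="unusable"):
            drop_noisy_channels(make_recording(data), 0.1, 100.0)


class TestEogRegression:
    def test_perfect_mixing_removed(self, rng):
        eog = rng.normal(0, 50, 512 * 4)
        data = np.vstack([0.3 * eog, 0.1 * eog, eog])
        rec = make_recording(data, labels=("Fz", "Cz", "EOG"))
        out = remove_eog_artifacts(rec)
        assert np.abs(out.samples[0]).max() < 1e-9
        assert np.abs(out.samples[1]).max() < 1e-9

    def test_independent_channel_untouched(self, rng):
        eeg = rng.normal(0, 5, 512 * 60)
        eog = rng.normal(0, 50, 512 * 60)
        rec = make_recording(np.vstack([eeg, eog]), labels=("Fz", "EOG"))
        out = remove_eog_artifacts(rec)
        assert np.allclose(out.samples[0], eeg, atol=0.5)

    def test_known_mixing_recovered(self, rng):
        # blink train mixed at known coefficient; 60 s of data
        n = 512 * 60
        eog = np.zeros(n)
        for start in range(512, n - 512, 2048):
            t = np.arange(154) / 512
            eog[start:start + 154] += 100 * np.sin(np.pi * t / 0.3) ** 2
        brain = rng.normal(0, 5, n)
        mixed = brain + 0.31 * eog
        rec = make_recording(np.vstack([mixed, eog]), labels=("Fz", "EOG"))
        out = remove_eog_artifacts(rec)
        residual_coef = np.polyfit(eog, out.samples[0], 1)[0]
        assert abs(residual_coef) < 0.02 * 0.31

    def test_flat_eog_rejected(self):
        rec = make_recording(np.vstack([np.ones(512), np.zeros(512)]),
                             labels=("Fz", "EOG"))
        with pytest.raises(ValueError, match="flat"):
            remove_eog_artifacts(rec)


class TestInterpolation:
    def _ring_positions(self, n=8, two_rings=False):
        # electrodes on a ring at 45 deg latitude plus the vertex
        pos = {"top": np.array([0.0, 0.0, 1.0])}
        for i in range(n):
            a = 2 * np.pi * i / n
            pos[f"r{i}"] = np.array([np.cos(a) / np.sqrt(2),
                                     np.sin(a) / np.sqrt(2),
                                     1 / np.sqrt(2)])
        if two_rings:
            for i in range(n):
                a = 2 * np.pi * (i + 0.5) / n
                pos[f"s{i}"] = np.array([np.cos(a) * np.sqrt(3) / 2,
                                         np.sin(a) * np.sqrt(3) / 2, 0.5])
        return pos

    def test_constant_field_reproduced(self, rng):
        pos = self._ring_positions()
        labels = tuple(pos)
        data = np.full((len(labels), 100), 4.2)
        rec = ContinuousRecording(data, 512.0, labels,
                                  bad_channels={"r3"})
        out = interpolate_bad_channels(rec, pos)
        assert np.allclose(out.samples[labels.index("r3")], 4.2, atol=1e-6)
        assert not out.bad_channels

    def test_symmetric_neighbors_average(self, rng):
        pos = self._ring_positions()
        labels = tuple(pos)
        sig = rng.normal(0, 3, 200)
        data = np.tile(sig, (len(labels), 1))
        rec = ContinuousRecording(data.copy(), 512.0, labels,
                                  bad_channels={"top"})
        rec.samples[0] = 999.0  # corrupt the vertex
        out = interpolate_bad_channels(rec, pos)
        assert np.allclose(out.samples[0], sig, atol=1e-6)

    def test_smooth_field_leave_one_out(self):
        # smooth dipolar topography: value = z-component of a tilted dipole
        pos = self._ring_positions(10, two_rings=True)
        labels = tuple(pos)
        moment = np.array([0.3, 0.2, 0.9])
        tops = {ch: float(pos[ch] @ moment) for ch in labels}
        t = np.sin(np.linspace(0, 6 * np.pi, 300))
        data = np.vstack([tops[ch] * t for ch in labels])
        for probe in ("r2", "top"):
            rec = ContinuousRecording(data.copy(), 512.0, labels,
                                      bad_channels={probe})
            idx = labels.index(probe)
            rec.samples[idx] = 0.0
            out = interpolate_bad_channels(rec, pos)
            err = np.sqrt(np.mean((out.samples[idx] - data[idx]) ** 2))
            true_rms = np.sqrt(np.mean(data[idx] ** 2))
            assert err < 0.1 * true_rms

    def test_missing_positions(self):
        rec = ContinuousRecording(np.zeros((5, 10)), 512.0,
                                  ("a", "b", "c", "d", "e"),
                                  bad_channels={"a"})
        with pytest.raises(ValueError, match="positions"):
            interpolate_bad_channels(rec, {"a": np.array([0, 0, 1.0])})


class TestEpoching:
    def test_epoch_count_and_length(self, rng):
        rate = 512.0
        rec = make_recording(rng.normal(0, 1, (3, 512 * 200)), rate)
        onsets = np.arange(512, 512 * 199, 254)[:400]
        ev = events_frame(onsets, rate)
        epochs, dropped = epoch(rec, ev)
        assert epochs.data.shape == (400, 3, 282)
        assert dropped == []

    def test_onset_alignment(self):
        offs = epoch_offsets((-100.0, 450.0), 512.0)
        assert offs[0] == -51 and offs[-1] == 230
        assert offs[51] == 0   # epoch sample 51 is stimulus onset

    def test_event_near_edge_dropped(self, rng):
        rec = make_recording(rng.normal(0, 1, (2, 512 * 4)))
        ev = events_frame([25, 1024], 512.0)   # 50 ms from start
        epochs, dropped = epoch(rec, ev)
        assert len(epochs.intensity) == 1
        assert dropped[0]["reason"] == "edge"

    def test_event_in_rejected_interval_dropped(self, rng):
        rec = make_recording(rng.normal(0, 1, (2, 512 * 6)))
        rec.rejected_intervals.append((1024, 1536))
        ev = events_frame([1100, 2560], 512.0)
        epochs, dropped = epoch(rec, ev)
        assert len(epochs.intensity) == 1
        assert dropped[0]["reason"] == "rejected_interval"


class TestEpochCorrections:
    def test_constant_epoch_zeroed(self, rng):
        epochs = make_epochs(rng, scale=0.0)
        epochs.data += 7.0
        out = baseline_correct(epochs)
        assert np.allclose(out.data, 0.0)

    def test_baseline_arithmetic(self, rng):
        epochs = make_epochs(rng, n_trials=1, scale=0.0)
        epochs.data[0, 0, epochs.offsets < 0] = 2.0
        epochs.data[0, 0, epochs.offsets >= 0] = 10.0
        out = baseline_correct(epochs)
        assert out.data[0, 0, -1] == pytest.approx(8.0)

    def test_baseline_idempotent(self, rng):
        once = baseline_correct(make_epochs(rng))
        twice = baseline_correct(once)
        assert np.allclose(once.data, twice.data)

    def test_mastoid_identity_when_mastoids_zero(self, rng):
        epochs = make_epochs(rng)
        epochs.data[:, 3:, :] = 0.0   # P9, P10
        out = rereference_linked_mastoid(epochs)
        assert np.allclose(out.data, epochs.data)
        assert out.reference == "linked_mastoid"

    def test_mastoid_arithmetic(self, rng):
        epochs = make_epochs(rng, n_trials=1, scale=0.0)
        epochs.data[0, 0, 0] = 5.0   # Fz
        epochs.data[0, 3, 0] = 1.0   # P9
        epochs.data[0, 4, 0] = 3.0   # P10
        out = rereference_linked_mastoid(epochs)
        assert out.data[0, 0, 0] == pytest.approx(3.0)

    def test_equal_channels_zeroed(self, rng):
        epochs = make_epochs(rng, n_trials=2, scale=0.0)
        epochs.data += 4.0
        out = rereference_linked_mastoid(epochs)
        assert np.allclose(out.data, 0.0)

    def test_corrections_commute(self, rng):
        epochs = make_epochs(rng)
        ab = rereference_linked_mastoid(baseline_correct(epochs))
        ba = baseline_correct(rereference_linked_mastoid(epochs))
        assert np.allclose(ab.data, ba.data, atol=1e-12)

    def test_rereference_preserves_channel_differences(self, rng):
        epochs = make_epochs(rng)
        out = rereference_linked_mastoid(epochs)
        assert np.allclose(out.data[:, 0] - out.data[:, 1],
                           epochs.data[:, 0] - epochs.data[:, 1],
                           atol=1e-12)


class TestAmplitudeRejection:
    def test_excursion_rejected_boundary_kept(self, rng):
        epochs = make_epochs(rng, n_trials=10, scale=1.0)
        epochs.data[0, 0, 100] = 60.0     # above threshold
        epochs.data[1, 1, 100] = 50.0     # exactly at threshold: retained
        out = reject_epochs_amplitude(epochs)
        assert not out.retained[0]
        assert out.retained[1]

    def test_matches_naive_scan(self, rng):
        epochs = make_epochs(rng, n_trials=20, scale=14.0)
        out = reject_epochs_amplitude(epochs)
        idx = [epochs.channel_labels.index(c) for c in ("Fz", "FCz", "Cz")]
        naive = np.array([
            not any(abs(v) > 50.0
                    for ci in idx for v in epochs.data[t, ci])
            for t in range(20)])
        assert np.array_equal(out.retained, naive)

    def test_empty_level_raises(self, rng):
        epochs = make_epochs(rng, n_trials=5, scale=0.0)
        epochs.data[epochs.intensity == 75.0] = 100.0
        with pytest.raises(ValueError, match="75"):
            reject_epochs_amplitude(epochs)
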