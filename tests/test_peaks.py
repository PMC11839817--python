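"""Evoked averaging and N1/P2 peak measurement."""

import numpy as np
import pytest

from conftest import make_epochs
from ldaep.peaks import average_by_intensity, find_peak, measure_components
from ldaep.preprocess import epoch_offsets


def gaussian_wave(times_ms, center, sigma, amp):
    return amp * np.exp(-0.5 * ((times_ms - center) / sigma) ** 2)


class TestAverageByIntensity:
    def test_identical_trials_average_to_any_trial(self, rng):
        epochs = make_epochs(rng, n_trials=10)
        epochs.data[:] = epochs.data[0]
        evoked = average_by_intensity(epochs)
        for li in range(len(evoked.intensities)):
            assert np.allclose(evoked.waveforms[li], epochs.data[0])

    def test_simple_mean(self, rng):
        epochs = make_epochs(rng, n_trials=10, scale=0.0)
        epochs.intensity[:] = 55.0
        epochs.data[:5] = 2.0
        epochs.data[5:] = 4.0
        evoked = average_by_intensity(epochs)
        assert np.allclose(evoked.waveforms[0], 3.0)

    def test_matches_loop_oracle(self, rng):
        epochs = make_epochs(rng, n_trials=23)
        epochs.retained[rng.random(23) < 0.3] = False
        if not all(epochs.retained[epochs.intensity == lvl].any()
                   for lvl in np.unique(epochs.intensity)):
            epochs.retained[:] = True
        evoked = average_by_intensity(epochs)
        for li, lvl in enumerate(evoked.intensities):
            acc, count = 0.0, 0
            for t in range(23):
                if epochs.intensity[t] == lvl and epochs.retained[t]:
                    acc = acc + epochs.data[t]
                    count += 1
            assert np.allclose(evoked.waveforms[li], acc / count)
            assert evoked.n_trials[li] == count

    def test_only_retained_trials_enter(self, rng):
        epochs = make_epochs(rng, n_trials=10)
        epochs.intensity[:] = 65.0
        epochs.data[0] = 1e6
        epochs.retained[0] = False
        evoked = average_by_intensity(epochs)
        assert np.abs(evoked.waveforms).max() < 1e3

    def test_empty_level_raises(self, rng):
        epochs = make_epochs(rng, n_trials=5)
        epochs.retained[epochs.intensity == 55.0] = False
        with pytest.raises(ValueError, match="55"):
            average_by_intensity(epochs)


class TestFindPeak:
    def setup_method(self):
        self.rate = 512.0
        self.offs = epoch_offsets((-100.0, 450.0), self.rate)
        self.t = self.offs * 1000.0 / self.rate

    def test_single_trough(self):
        wave = gaussian_wave(self.t, 100.0, 10.0, -5.0)
        amp, lat = find_peak(wave, self.t, (60.0, 140.0), "negative")
        assert amp == pytest.approx(-5.0, abs=0.01)
        assert abs(lat - 100.0) < 2.0

    def test_window_restriction(self):
        wave = (gaussian_wave(self.t, 50.0, 8.0, -10.0)
                + gaussian_wave(self.t, 100.0, 8.0, -6.0))
        amp, lat = find_peak(wave, self.t, (60.0, 140.0), "negative")
        assert amp == pytest.approx(-6.0, abs=0.05)
        assert abs(lat - 100.0) < 3.0

    def test_matches_exhaustive_scan(self, rng):
        for _ in range(20):
            wave = np.cumsum(rng.normal(0, 1, len(self.t)))
            for pol, fn in (("negative", np.argmin), ("positive", np.argmax)):
                amp, lat = find_peak(wave, self.t, (60.0, 140.0), pol)
                mask = (self.t >= 60.0) & (self.t <= 140.0)
                idx = np.flatnonzero(mask)[fn(wave[mask])]
                assert amp == wave[idx]
                assert lat == self.t[idx]

    def test_tie_breaks_earliest(self):
        wave = np.zeros(len(self.t))
        mask = (self.t >= 60.0) & (self.t <= 140.0)
        first, last = np.flatnonzero(mask)[[2, -3]]
        wave[first] = wave[last] = 7.0
        amp, lat = find_peak(wave, self.t, (60.0, 140.0), "positive")
        assert lat == self.t[first]

    def test_empty_window_raises(self):
        with pytest.raises(ValueError, match="no samples"):
            find_peak(np.zeros(10), np.arange(10.0), (60.0, 140.0),
                      "negative")


class TestMeasureComponents:
    def _evoked(self, rng, n1=-6.0, p2=4.0):
        epochs = make_epochs(rng, n_trials=5, scale=0.0)
        t = epochs.times_ms
        wave = (gaussian_wave(t, 100.0, 15.0, n1)
                + gaussian_wave(t, 180.0, 20.0, p2))
        epochs.data[:, :3, :] = wave
        return average_by_intensity(epochs)

    def test_peak_to_peak_definition(self, rng):
        table = measure_components(self._evoked(rng))
        row = table[(table.channel == "FCz")
                    & (table.intensity_db == 75.0)].iloc[0]
        assert row["n1p2"] == pytest.approx(
            row["p2_amplitude"] - row["n1_amplitude"])
        assert row["n1p2"] == pytest.approx(10.0, abs=0.1)
        assert not row["manual_override"]
        assert 60 <= row["n1_latency_ms"] <= 140
        assert 150 <= row["p2_latency_ms"] <= 250

    def test_override_reads_amplitude_at_latency(self, rng):
        evoked = self._evoked(rng)
        # move the P2 reading to 260 ms, outside the automatic window
        table = measure_components(
            evoked, overrides={("FCz", 75.0, "P2"): 260.0})
        row = table[(table.channel == "FCz")
                    & (table.intensity_db == 75.0)].iloc[0]
        ci = evoked.index("FCz")
        li = list(evoked.intensities).index(75.0)
        idx = int(np.argmin(np.abs(evoked.times_ms - 260.0)))
        assert row["p2_amplitude"] == evoked.waveforms[li, ci, idx]
        assert row["manual_override"]

    def test_override_outside_epoch_raises(self, rng):
        with pytest.raises(ValueError, match="outside epoch"):
            measure_components(self._evoked(rng),
                               overrides={("Fz", 55.0, "P2"): 900.0})

    def test_sign_convention_invariant(self, rng):
        # n1p2 >= 0 whenever P2 >= 0 >= N1
        table = measure_components(self._evoked(rng))
        ok = (table["p2_amplitude"] >= 0) & (table["n1_amplitude"] <= 0)
        assert (table.loc[ok, "n1p2"] >= 0).all()

    def test_constant_offset_removed_by_baseline(self, rng):
        # peak measures are invariant to adding a constant before baseline
        # correction (pipeline composition)
        from ldaep.preprocess import baseline_correct

        epochs = make_epochs(rng, n_trials=5, scale=0.0)
        t = epochs.times_ms
        wave = (gaussian_wave(t, 100.0, 15.0, -6.0)
                + gaussian_wave(t, 180.0, 20.0, 4.0))
        epochs.data[:, :3, :] = wave
        shifted = epochs.copy()
        shifted.data += 11.0
        a = measure_components(average_by_intensity(baseline_correct(epochs)))
        b = measure_components(average_by_intensity(baseline_correct(shifted)))
        cols = ["n1_amplitude", "p2_amplitude", "n1p2"]
        assert np.allclose(a[cols].to_numpy(), b[cols].to_numpy(),
                           atol=1e-10)


class TestGeneratorRoundTrip:
    def test_noise_free_template_measured_exactly(self, noise_free_tiny):
        # raw-template injection (no calibration), raw epoching at the
        # recording rate: the measured lobes equal construction values
        import dataclasses

        from ldaep.peaks import average_by_intensity, measure_components
        from ldaep.preprocess import baseline_correct, epoch
        from ldaep.recording import generate_recording, subject_rng, \
            nominal_lobe_amplitudes, target_amplitudes
        from ldaep.synthetic import cohort_with_sessions

        config = dataclasses.replace(noise_free_tiny,
                                     calibrate_injection=False)
        subject = cohort_with_sessions(config, 1)[0]
        rec, ev = generate_recording(subject, 1, config,
                                     subject_rng(config, 0, 1))
        epochs, _ = epoch(rec, ev)
        table = measure_components(
            average_by_intensity(baseline_correct(epochs)))
        targets = target_amplitudes(subject, 1, config)
        for _, row in table.iterrows():
            a = targets[row["channel"]][row["intensity_db"]]
            n1_nom, p2_nom = nominal_lobe_amplitudes(a, config.n1_fraction)
            assert row["n1_amplitude"] == pytest.approx(-n1_nom, abs=0.01)
            assert row["p2_amplitude"] == pytest.approx(p2_nom, abs=0.01)

    def test_monotone_amplitudes_give_monotone_n1p2(self, noise_free_tiny):
        import dataclasses

        from ldaep.peaks import average_by_intensity, measure_components
        from ldaep.preprocess import baseline_correct, epoch
        from ldaep.recording import generate_recording, subject_rng
        from ldaep.synthetic import cohort_with_sessions

        config = dataclasses.replace(noise_free_tiny,
                                     calibrate_injection=False)
        subject = cohort_with_sessions(config, 1)[0]
        rec, ev = generate_recording(subject, 1, config,
                                     subject_rng(config, 0, 1))
        epochs, _ = epoch(rec, ev)
        table = measure_components(
            average_by_intensity(baseline_correct(epochs)))
        for ch in ("Fz", "FCz", "Cz"):
            vals = table[table.channel == ch].sort_values("intensity_db")[
                "n1p2"].to_numpy()
            if subject.session_slopes[0][ch] > 0:
                assert np.all(np.diff(vals) > 0)
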