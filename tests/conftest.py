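import numpy as np
import pytest

from ldaep.config import GeneratorConfig
from ldaep.containers import EpochSet


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_config():
    """Small, fast cohort with the default paradigm."""
    return GeneratorConfig(n_subjects=4, trials_per_level=4, seed=7)


@pytest.fixture
def noise_free_tiny():
    return GeneratorConfig(n_subjects=2, trials_per_level=4,
                           noise_rms_uv=0.0, blink_rate_per_min=0.0,
                           bad_channel_prob=0.0,
                           line_noise_amplitude_uv=0.0, seed=11)


def make_epochs(rng, n_trials=6, labels=("Fz", "FCz", "Cz", "P9", "P10"),
                rate=512.0, window=(-100.0, 450.0), scale=5.0):
    """Random epochs helper shared across test modules."""
    from ldaep.preprocess import epoch_offsets

    offs = epoch_offsets(window, rate)
    data = rng.normal(0.0, scale, (n_trials, len(labels), len(offs)))
    intensity = np.resize([55.0, 65.0, 75.0, 85.0, 95.0], n_trials)
    return EpochSet(data, rate, labels, offs, intensity,
                    np.ones(n_trials, dtype=bool))
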