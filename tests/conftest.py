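import numpy as np
import pytest

from dfssmvep import SimulationConfig, assign_dual_frequencies


@pytest.fixture(scope="session")
def plan():
    """The canonical 5-target plan over 5-9 Hz base frequencies."""
    return assign_dual_frequencies([5, 6, 7, 8, 9])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def high_snr_config():
    return SimulationConfig(snr_db=20.0, seed=7)


def make_tone_trial(freqs_amps, fs=500.0, duration=3.5, n_channels=6,
                    noise=0.0, rng=None, labels=None):
    """Multi-channel trial made of pure sinusoids (plus optional noise)."""
    from dfssmvep import EEGTrial
    n = int(round(fs * duration))
    t = np.arange(n) / fs
    # distinct per-channel component weights keep the matrix full rank so
    # CCA can isolate individual components
    data = np.zeros((n_channels, n))
    for j, (f, a) in enumerate(freqs_amps):
        comp = a * np.sin(2 * np.pi * f * t + 0.3 * f)
        weights = 1.0 + 0.5 * np.cos(0.7 * np.arange(n_channels) + 1.3 * j)
        data += weights[:, None] * comp[None, :]
    if noise > 0:
        data = data + noise * rng.standard_normal(data.shape)
    labels = labels or [f"ch{i}" for i in range(n_channels)]
    return EEGTrial(data=data, fs=fs, channel_labels=labels)
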