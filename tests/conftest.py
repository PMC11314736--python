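import numpy as np
import pytest

from mibci import EpochedEEG, FeatureTable, SynthConfig, make_synthetic_mi


@pytest.fixture(scope="session")
def strong_effect_epochs():
    """Synthetic MI data with a clearly recoverable planted effect."""
    epochs, truth = make_synthetic_mi(SynthConfig(seed=7))
    return epochs, truth


@pytest.fixture(scope="session")
def small_epochs():
    """Quick 4-channel epochs for structural tests."""
    cfg = SynthConfig(n_trials_per_class=15, n_channels=4, duration=1.5, seed=11)
    epochs, _ = make_synthetic_mi(cfg)
    return epochs


@pytest.fixture
def tiny_table():
    rng = np.random.default_rng(0)
    values = rng.normal(size=(12, 5))
    labels = np.tile([1, 2], 6)
    return FeatureTable(values, labels)


def make_epochs(data, labels, fs=100.0):
    return EpochedEEG(np.asarray(data, dtype=float), labels, fs)
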