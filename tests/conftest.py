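import numpy as np
import pytest

from ssvepkit import EpochedEEG, SynthConfig, synth_dataset


@pytest.fixture(scope="session")
def small_synth():
    """12-class, 0.5 s, fs 250, 10 dB SNR synthetic dataset (session-cached)."""
    freqs = tuple(9.25 + 0.5 * i for i in range(12))
    phases = tuple((0.5 * np.pi * i) % (2 * np.pi) for i in range(12))
    cfg = SynthConfig(stim_freqs=freqs, stim_phases=phases, snr_db=10.0,
                      n_trials_per_class=6, trial_len=0.5,
                      mixing_seed=7, noise_seed=8)
    epochs, truth = synth_dataset(cfg)
    return epochs, truth, cfg


@pytest.fixture()
def tiny_noise_epochs():
    """4-class pure-noise dataset for algebraic/augmentation tests."""
    rng = np.random.default_rng(42)
    data = rng.standard_normal((20, 3, 16))
    labels = np.repeat(np.arange(4), 5)
    return EpochedEEG(data, labels, fs=32.0,
                      channel_names=("a", "b", "c"), subject_id="noise")
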