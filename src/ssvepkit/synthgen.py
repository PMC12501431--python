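"""Synthetic SSVEP generator with known ground truth.

Each class is a fixed sum of harmonic sinusoids (fundamental at the stimulus
frequency, harmonic k at k times it, phase k times the stimulus phase),
projected to the electrodes through a class-specific spatial pattern.  The
background is 1/f ("pink") noise generated independently per channel and
then smeared across channels by a random full-rank mixing matrix, so it is
spatially correlated — as real EEG background is — while the task signal
lives in a low-rank spatial subspace; a small white sensor-noise floor is
added on top.  Noise is rescaled per trial so that the realised
task-to-background power ratio equals ``snr_db`` exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .eeg_data import EpochedEEG

__all__ = ["SynthConfig", "pink_noise", "synth_dataset", "default_12class_config"]


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic SSVEP dataset.

    ``snr_db`` is the task-to-background power ratio per trial, averaged over
    channels; ``np.inf`` disables noise entirely.  ``latency_jitter_s``
    optionally breaks perfect phase locking (default off: template averaging
    presumes phase-locked task components).
    """

    stim_freqs: tuple[float, ...]
    stim_phases: tuple[float, ...]
    n_harmonics: int = 3
    harmonic_amps: tuple[float, ...] = (1.0, 0.5, 0.25)
    n_channels: int = 8
    n_trials_per_class: int = 6
    fs: float = 250.0
    trial_len: float = 1.0
    snr_db: float = 0.0
    sensor_noise_frac: float = 0.1
    latency_jitter_s: float = 0.0
    mixing_seed: int = 0
    noise_seed: int = 1

    @property
    def n_classes(self) -> int:
        return len(self.stim_freqs)

    @property
    def n_samples(self) -> int:
        return int(np.floor(self.trial_len * self.fs))

    def validate(self) -> None:
        if len(set(self.stim_freqs)) != len(self.stim_freqs):
            raise ValueError("stimulus frequencies must be distinct")
        if len(self.stim_phases) != len(self.stim_freqs):
            raise ValueError("need one phase per stimulus frequency")
        if self.n_harmonics < 1 or len(self.harmonic_amps) < self.n_harmonics:
            raise ValueError("need n_harmonics >= 1 amplitudes")
        fmax = max(self.stim_freqs) * self.n_harmonics
        if fmax >= self.fs / 2:
            raise ValueError(
                f"highest harmonic {fmax} Hz aliases at fs={self.fs} Hz"
            )


def default_12class_config(**overrides) -> SynthConfig:
    """12-target joint frequency-phase grid: 9.25-14.75 Hz in 0.5 Hz steps,
    phases stepping by 0.5*pi — the standard 12-class speller layout."""
    freqs = tuple(9.25 + 0.5 * i for i in range(12))
    phases = tuple((0.5 * np.pi * i) % (2 * np.pi) for i in range(12))
    cfg = SynthConfig(stim_freqs=freqs, stim_phases=phases)
    if overrides:
        import dataclasses
        cfg = dataclasses.replace(cfg, **overrides)
    return cfg


def pink_noise(n_samples: int, seed: int | np.random.Generator) -> np.ndarray:
    """Unit-variance 1/f noise via spectral shaping of white Gaussian noise.

    The rFFT of a white draw is weighted by 1/sqrt(f) (power density 1/f)
    over all non-DC bins, transformed back and standardised.
    """
    if n_samples < 2:
        raise ValueError("need at least 2 samples")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    white = rng.standard_normal(n_samples)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n_samples)
    scale = np.ones_like(f)
    scale[1:] = 1.0 / np.sqrt(f[1:])
    scale[0] = 0.0  # remove DC so the series is zero-mean by construction
    x = np.fft.irfft(spec * scale, n=n_samples)
    x -= x.mean()
    return x / x.std()


def class_signal(cfg: SynthConfig, m: int, t: np.ndarray | None = None) -> np.ndarray:
    """Noise-free task component of class ``m`` (single waveform, pre-mixing)."""
    if t is None:
        t = np.arange(cfg.n_samples) / cfg.fs
    f, phi = cfg.stim_freqs[m], cfg.stim_phases[m]
    sig = np.zeros_like(t)
    for k in range(1, cfg.n_harmonics + 1):
        sig += cfg.harmonic_amps[k - 1] * np.sin(2 * np.pi * k * f * t + k * phi)
    return sig


def synth_dataset(cfg: SynthConfig) -> tuple[EpochedEEG, dict]:
    """Generate an epoched dataset plus its ground truth.

    Returns ``(epochs, truth)`` where ``truth`` has the per-class source
    waveforms (``sources``), the spatial patterns (``patterns``), and the
    background mixing matrix (``mixing``).  Deterministic under the two
    seeds: ``mixing_seed`` fixes the subject's spatial structure,
    ``noise_seed`` the trial-varying noise.
    """
    cfg.validate()
    mix_rng = np.random.default_rng(cfg.mixing_seed)
    noise_rng = np.random.default_rng(cfg.noise_seed)
    ns, nc, nf = cfg.n_samples, cfg.n_channels, cfg.n_classes
    t = np.arange(ns) / cfg.fs

    # Subject-specific spatial structure: one unit-norm pattern per class,
    # and a full-rank mixing matrix for the background.
    patterns = mix_rng.standard_normal((nf, nc))
    patterns /= np.linalg.norm(patterns, axis=1, keepdims=True)
    mixing = mix_rng.standard_normal((nc, nc)) / np.sqrt(nc)
    mixing += 0.5 * np.eye(nc)  # keep it well-conditioned

    sources = np.stack([class_signal(cfg, m, t) for m in range(nf)])

    data = np.empty((nf * cfg.n_trials_per_class, nc, ns))
    labels = np.repeat(np.arange(nf), cfg.n_trials_per_class)
    noise_free = not np.isfinite(cfg.snr_db)

    i = 0
    for m in range(nf):
        task = np.outer(patterns[m], sources[m])  # (nc, ns)
        for _ in range(cfg.n_trials_per_class):
            if cfg.latency_jitter_s > 0:
                shift = noise_rng.uniform(-cfg.latency_jitter_s, cfg.latency_jitter_s)
                task = np.outer(patterns[m], class_signal(cfg, m, t - shift))
            task_power = float(np.mean(task ** 2))
            if noise_free:
                data[i] = task
            else:
                bg = np.stack([pink_noise(ns, noise_rng) for _ in range(nc)])
                bg = mixing @ bg
                bg += np.sqrt(cfg.sensor_noise_frac) * noise_rng.standard_normal((nc, ns))
                # exact per-trial SNR: scale realised noise power to target
                target_noise_power = task_power / (10.0 ** (cfg.snr_db / 10.0))
                bg *= np.sqrt(target_noise_power / np.mean(bg ** 2))
                data[i] = task + bg
            i += 1

    names = tuple(f"ch{j}" for j in range(nc))
    epochs = EpochedEEG(data, labels, cfg.fs, names,
                        subject_id=f"synth-m{cfg.mixing_seed}-n{cfg.noise_seed}")
    truth = {"sources": sources, "patterns": patterns, "mixing": mixing, "t": t}
    return epochs, truth
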