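"""Desk-scale study conditions: reusable end-to-end experiments.

These functions pin the synthetic study conditions used by the package's
own evaluation (and by ``scripts/acceptance.py``): a 12-class joint
frequency-phase grid at 10 dB SNR for the classical-decoder benchmark, and
a deliberately hard sparse-data condition (6 classes, 4 channels, 0.5 s
windows at 64 Hz, -8 dB SNR, 3 training trials per class) for the
augmentation experiments, where data sparsity - not signal quality - is
the binding constraint.  Held-out test trials come from the same subject
(same spatial mixing) with fresh background noise.
"""

from __future__ import annotations

import numpy as np

from . import synthgen
from .aetf import AETFConfig, AETFModel, make_student
from .bgmix import BGMixConfig, bgmix_generate, samples_to_arrays
from .classical import etrca_fit, etrca_predict, tdca_fit, tdca_predict
from .eeg_data import EpochedEEG, crop_window, kfold_trial_split
from .train_eval import TrainConfig, balanced_accuracy, train_model, distill_student

__all__ = [
    "classical_benchmark",
    "bgmix_benefit",
    "encoder_ablation",
    "sparse_synth_pair",
]


def classical_benchmark(seed: int = 0, snr_db: float = 10.0,
                        window_s: float = 0.5, n_folds: int = 2) -> dict:
    """eTRCA and TDCA held-out accuracy on the 12-class synthetic grid.

    Models are fitted on each fold's train+validation trials and tested on
    the fold's held-out trial per class.
    """
    cfg = synthgen.default_12class_config(
        snr_db=snr_db, mixing_seed=seed, noise_seed=seed + 1)
    epochs, _ = synthgen.synth_dataset(cfg)
    epochs = crop_window(epochs, 0.0, window_s)
    plan = kfold_trial_split(epochs, seed=seed)
    results = {"etrca": [], "tdca": []}
    n_test = 0
    for tr, va, te in plan.folds[:n_folds]:
        idx = np.concatenate([tr, va])
        train = epochs.replace(data=epochs.data[idx], labels=epochs.labels[idx])
        em = etrca_fit(train, n_bands=1)
        tm = tdca_fit(train, cfg.stim_freqs, n_bands=1)
        for i in te:
            results["etrca"].append(etrca_predict(em, epochs.data[i]) == epochs.labels[i])
            results["tdca"].append(tdca_predict(tm, epochs.data[i]) == epochs.labels[i])
            n_test += 1
    return {
        "etrca_accuracy": float(np.mean(results["etrca"])),
        "tdca_accuracy": float(np.mean(results["tdca"])),
        "n_test": n_test,
    }


def sparse_synth_pair(seed: int, n_test_per_class: int = 3
                      ) -> tuple[EpochedEEG, EpochedEEG, synthgen.SynthConfig]:
    """The hard sparse-data condition: (train/val epochs, held-out epochs, cfg).

    6 classes at 8-13 Hz (0.5*pi phase steps), 2 harmonics, 4 channels,
    fs 64 Hz, 0.5 s trials, -8 dB SNR; 5 trials/class for train+val+internal
    test and a fresh-noise held-out set from the same simulated subject.
    """
    freqs = tuple(8.0 + 1.0 * i for i in range(6))
    phases = tuple((0.5 * np.pi * i) % (2 * np.pi) for i in range(6))
    base = dict(stim_freqs=freqs, stim_phases=phases, n_harmonics=2,
                harmonic_amps=(1.0, 0.5), n_channels=4, fs=64.0,
                trial_len=0.5, snr_db=-8.0, mixing_seed=seed)
    cfg = synthgen.SynthConfig(n_trials_per_class=5, noise_seed=seed + 100, **base)
    train, _ = synthgen.synth_dataset(cfg)
    test_cfg = synthgen.SynthConfig(n_trials_per_class=n_test_per_class,
                                    noise_seed=seed + 900, **base)
    test, _ = synthgen.synth_dataset(test_cfg)
    return train, test, cfg


def _tiny_aetf(epochs: EpochedEEG, seed: int, use_encoder: bool = True) -> AETFModel:
    cfg = AETFConfig(n_channels=epochs.n_channels, n_samples=epochs.n_samples,
                     n_classes=epochs.n_classes, fs=epochs.fs,
                     n_spatial=8, n_freq_filters=4, n_layers=1, dropout=0.1,
                     use_encoder=use_encoder)
    return AETFModel(cfg, seed=seed)


def _held_out_ba(model: AETFModel, test: EpochedEEG) -> float:
    preds = model.predict(test.data)
    nf = test.n_classes
    conf = np.zeros((nf, nf), dtype=int)
    for t, p in zip(test.labels, preds):
        conf[t, p] += 1
    return balanced_accuracy(conf)


def _train_condition(seed: int, use_bgmix: bool, use_encoder: bool = True,
                     passes=((2, 8), (3, 8))) -> float:
    """Train the tiny decoder on 3 trials/class, with or without BGMix."""
    epochs, test, _ = sparse_synth_pair(seed)
    plan = kfold_trial_split(epochs, seed=seed)
    tr, va, _ = plan.folds[0]
    model = _tiny_aetf(epochs, seed, use_encoder)
    tc = TrainConfig(max_epochs=50, patience=8, batch_size=32, seed=seed)
    if use_bgmix:
        pool_idx = np.concatenate([tr, va])
        pool = epochs.replace(data=epochs.data[pool_idx],
                              labels=epochs.labels[pool_idx])
        Xa, ya, yp, lam, Xm = samples_to_arrays(
            bgmix_generate(pool, BGMixConfig(passes=passes, seed=seed)))
        train_model(model, (Xa, ya, yp, lam, Xm), (pool.data, pool.labels), tc)
    else:
        train_model(model, (epochs.data[tr], epochs.labels[tr]),
                    (epochs.data[va], epochs.labels[va]), tc)
    return _held_out_ba(model, test)


def bgmix_benefit(seed: int = 0, n_seeds: int = 5) -> dict:
    """Mean held-out BA of the tiny decoder with vs without BGMix.

    The central claim of the augmentation, checked directionally at desk
    scale: under data sparsity, swapping background EEG across classes
    improves the deep decoder's held-out balanced accuracy.
    """
    with_aug, without = [], []
    for s in range(n_seeds):
        without.append(_train_condition(seed + s, use_bgmix=False))
        with_aug.append(_train_condition(seed + s, use_bgmix=True))
    return {
        "ba_with_bgmix": float(np.mean(with_aug)),
        "ba_without_bgmix": float(np.mean(without)),
        "per_seed_with": with_aug,
        "per_seed_without": without,
        "n_seeds": n_seeds,
    }


def encoder_ablation(seed: int = 0) -> dict:
    """BA of the full tiny decoder vs the encoder-less variant (no margin
    asserted; both must train and evaluate without error)."""
    full = _train_condition(seed, use_bgmix=True, use_encoder=True)
    headless = _train_condition(seed, use_bgmix=True, use_encoder=False)
    return {"ba_full": full, "ba_no_encoder": headless}


def distillation_demo(seed: int = 0) -> dict:
    """Teacher -> 1-layer half-width student on the sparse condition."""
    epochs, test, _ = sparse_synth_pair(seed)
    plan = kfold_trial_split(epochs, seed=seed)
    tr, va, _ = plan.folds[0]
    teacher = _tiny_aetf(epochs, seed)
    tc = TrainConfig(max_epochs=50, patience=8, batch_size=32, seed=seed)
    pool_idx = np.concatenate([tr, va])
    pool = epochs.replace(data=epochs.data[pool_idx], labels=epochs.labels[pool_idx])
    Xa, ya, yp, lam, Xm = samples_to_arrays(
        bgmix_generate(pool, BGMixConfig(passes=((2, 8), (3, 8)), seed=seed)))
    train_model(teacher, (Xa, ya, yp, lam, Xm), (pool.data, pool.labels), tc)
    student = AETFModel(make_student(teacher.cfg), seed=seed)
    distill_student(teacher, student, (Xa, ya), (pool.data, pool.labels), tc)
    return {
        "teacher_ba": _held_out_ba(teacher, test),
        "student_ba": _held_out_ba(student, test),
        "teacher_params": teacher.n_parameters(),
        "student_params": student.n_parameters(),
    }
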