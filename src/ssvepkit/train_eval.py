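"""Two-stage training, augmentation-aware validation, early stopping,
knowledge distillation, and the balanced-accuracy / ITR metrics.

Stage 1 trains a single inter-subject model on data pooled across subjects
(no augmentation); stage 2 clones its weights per subject and fine-tunes on
that subject's trials, optionally expanding them with BGMix.  Under
augmentation the training set is the generated samples built from the
original train+validation trials, while the validation set becomes the
original (non-augmented) train+validation trials concatenated; the
checkpoint with the lowest validation loss is kept.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import nn
from .aetf import AETFModel
from .bgmix import BGMixConfig, bgmix_generate, samples_to_arrays
from .eeg_data import EpochedEEG, SplitPlan, kfold_trial_split

__all__ = [
    "TrainConfig",
    "EvalReport",
    "train_model",
    "train_two_stage",
    "early_stop_check",
    "distill_loss",
    "distill_student",
    "balanced_accuracy",
    "itr",
    "evaluate",
]


@dataclass(frozen=True)
class TrainConfig:
    """Optimiser and schedule settings (defaults are desk-scale sensible)."""

    lr: float = 1e-3
    weight_decay: float = 1e-2
    batch_size: int = 64
    max_epochs: int = 500
    patience: int = 20
    seed: int = 0
    distill_temperature: float = 5.0
    distill_hard_weight: float = 0.7

    def __post_init__(self):
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if self.distill_temperature <= 0:
            raise ValueError("temperature must be positive")
        if not 0.0 <= self.distill_hard_weight <= 1.0:
            raise ValueError("hard_weight must lie in [0, 1]")


@dataclass(frozen=True)
class EvalReport:
    """Aggregated held-out performance."""

    confusion: np.ndarray          # (N_f, N_f) counts, rows = truth
    balanced_accuracy: float
    itr_bits_per_min: float
    selection_time_s: float
    per_fold: tuple[dict, ...] = ()


# ---------------------------------------------------------------------------
# Loss helpers
# ---------------------------------------------------------------------------

def _ce_per_sample(logits: nn.Tensor, labels: np.ndarray) -> nn.Tensor:
    return -nn.gather_rows(nn.log_softmax(logits, axis=-1), labels)


def batch_loss(model: AETFModel, X: np.ndarray, y: np.ndarray,
               y_prime: np.ndarray | None = None,
               lam: np.ndarray | None = None,
               X_mirror: np.ndarray | None = None) -> nn.Tensor:
    """Mean loss over a batch with two-term label fusion for mixed samples.

    Background-swapped pairs supply a mirror waveform: the loss is
    ``lam * CE(x, y) + (1 - lam) * CE(x_mirror, y')`` per pair.  Mixup
    samples blend both classes into one waveform, so both terms score the
    same logits: ``lam * CE(x, y) + (1 - lam) * CE(x, y')``.
    """
    if y_prime is None:
        return _ce_per_sample(model.forward(X), y).mean()
    lam = np.asarray(lam, dtype=float)
    if X_mirror is None:
        logits = model.forward(X)
        ce_y = _ce_per_sample(logits, y)
        ce_yp = _ce_per_sample(logits, y_prime)
        lam_t = nn.Tensor(lam)
        return (lam_t * ce_y + (1.0 - lam_t) * ce_yp).mean()
    # pair loss in one forward: weights [lam...] on x, [1-lam...] on mirrors
    n = len(y)
    logits = model.forward(np.concatenate([X, X_mirror]))
    ce = _ce_per_sample(logits, np.concatenate([y, y_prime]))
    w = nn.Tensor(np.concatenate([lam, 1.0 - lam]))
    return (w * ce).sum() * (1.0 / n)


def early_stop_check(val_losses, patience: int) -> tuple[bool, int]:
    """Stop once the running minimum has gone ``patience`` consecutive epochs
    without improving.  Returns ``(stop, best_epoch)`` with ``best_epoch``
    the first index attaining the minimum (0-based)."""
    val_losses = list(val_losses)
    if not val_losses:
        raise ValueError("need at least one validation loss")
    best = int(np.argmin(val_losses))
    stall = len(val_losses) - 1 - best
    return stall >= patience, best


def _dataset_loss(model: AETFModel, X, y, chunk: int = 256) -> float:
    was = model.training
    model.eval()
    total, n = 0.0, len(y)
    for s in range(0, n, chunk):
        sl = slice(s, s + chunk)
        total += batch_loss(model, X[sl], y[sl]).item() * (min(s + chunk, n) - s)
    model.training = was
    return total / n


def train_model(model: AETFModel, train_data, val_data, cfg: TrainConfig,
                teacher: AETFModel | None = None,
                log: list | None = None) -> AETFModel:
    """Mini-batch Adam training with early stopping on validation loss.

    ``train_data`` is ``(X, y)`` or ``(X, y, y_prime, lam[, X_mirror])`` for
    mixed-label sets; ``val_data`` is ``(X, y)``.  If ``teacher`` is given
    the loss is the distillation objective instead of plain cross-entropy.
    The weights of the best-validation epoch are restored before returning.
    """
    X, y = train_data[0], train_data[1]
    y_prime = train_data[2] if len(train_data) > 2 else None
    lam = train_data[3] if len(train_data) > 3 else None
    X_mirror = train_data[4] if len(train_data) > 4 else None
    Xv, yv = val_data
    rng = np.random.default_rng(cfg.seed)
    opt = nn.Adam(model.parameters(), lr=cfg.lr, weight_decay=cfg.weight_decay)
    val_losses: list[float] = []
    best_state = model.state_dict()
    teacher_soft = None
    if teacher is not None:
        teacher.eval()
    for epoch in range(cfg.max_epochs):
        model.train()
        order = rng.permutation(len(y))
        for s in range(0, len(order), cfg.batch_size):
            idx = order[s:s + cfg.batch_size]
            opt.zero_grad()
            if teacher is None:
                loss = batch_loss(model, X[idx], y[idx],
                                  None if y_prime is None else y_prime[idx],
                                  None if lam is None else lam[idx],
                                  None if X_mirror is None else X_mirror[idx])
            else:
                t_logits = teacher.forward(X[idx]).data
                s_logits = model.forward(X[idx])
                loss = distill_loss(s_logits, t_logits, y[idx],
                                    cfg.distill_temperature,
                                    cfg.distill_hard_weight)
            loss.backward()
            opt.step()
        vl = _dataset_loss(model, Xv, yv)
        val_losses.append(vl)
        if log is not None:
            log.append({"epoch": epoch, "val_loss": vl})
        stop, best = early_stop_check(val_losses, cfg.patience)
        if best == len(val_losses) - 1:
            best_state = model.state_dict()
        if stop:
            break
    model.load_state_dict(best_state)
    model.eval()
    return model


def distill_loss(student_logits, teacher_logits, hard_labels,
                 temperature: float, hard_weight: float) -> nn.Tensor:
    """``w * CE(student, hard) + (1-w) * T^2 * KL(soft_teacher || soft_student)``.

    The teacher distribution is ``softmax(teacher / T)`` (constant); the
    ``T^2`` factor keeps soft-target gradients on the hard-loss scale.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    if not 0.0 <= hard_weight <= 1.0:
        raise ValueError("hard_weight must lie in [0, 1]")
    s = nn._wrap(student_logits)
    t = np.asarray(teacher_logits, dtype=float)
    if s.data.ndim == 1:
        s = s.reshape(1, -1)
        t = t[None]
        hard_labels = np.atleast_1d(hard_labels)
    hard = _ce_per_sample(s, np.asarray(hard_labels, dtype=int)).mean()
    tz = t / temperature - (t / temperature).max(axis=-1, keepdims=True)
    p_t = np.exp(tz) / np.exp(tz).sum(axis=-1, keepdims=True)
    log_p_s = nn.log_softmax(s * (1.0 / temperature), axis=-1)
    # KL(p_t || p_s) = sum p_t log p_t - sum p_t log p_s
    const = float((p_t * np.log(np.maximum(p_t, 1e-300))).sum(axis=-1).mean())
    cross = (nn.Tensor(p_t) * log_p_s).sum(axis=-1).mean()
    kl = const - cross
    return hard * hard_weight + kl * (temperature ** 2 * (1.0 - hard_weight))


def distill_student(teacher: AETFModel, student: AETFModel, train_data,
                    val_data, cfg: TrainConfig) -> AETFModel:
    """Train a student against ground truth plus the teacher's soft targets."""
    return train_model(student, train_data, val_data, cfg, teacher=teacher)


# ---------------------------------------------------------------------------
# Two-stage protocol
# ---------------------------------------------------------------------------

def train_two_stage(model_factory, all_subjects: list[EpochedEEG],
                    cfg: TrainConfig, aug: BGMixConfig | None = None,
                    splits: list[tuple[np.ndarray, np.ndarray]] | None = None,
                    ) -> tuple[AETFModel, list[AETFModel]]:
    """Two-stage protocol: pooled inter-subject model, then per-subject
    fine-tuning (BGMix applied only in stage 2).

    ``splits`` optionally gives per-subject ``(train_idx, val_idx)`` index
    pairs (test trials excluded by the caller); by default fold 0 of the
    seeded trial-level K-fold plan is used.  Returns the stage-1 model and
    one independently-stored fine-tuned model per subject.
    """
    if not all_subjects:
        raise ValueError("need at least one subject")
    if splits is None:
        plans = [kfold_trial_split(s, seed=cfg.seed) for s in all_subjects]
        splits = [(p.folds[0][0], p.folds[0][1]) for p in plans]

    # Stage 1: pooled training, no augmentation.
    Xtr = np.concatenate([s.data[tr] for s, (tr, _) in zip(all_subjects, splits)])
    ytr = np.concatenate([s.labels[tr] for s, (tr, _) in zip(all_subjects, splits)])
    Xva = np.concatenate([s.data[va] for s, (_, va) in zip(all_subjects, splits)])
    yva = np.concatenate([s.labels[va] for s, (_, va) in zip(all_subjects, splits)])
    stage1 = model_factory()
    train_model(stage1, (Xtr, ytr), (Xva, yva), cfg)

    # Stage 2: per-subject fine-tune from the stage-1 weights.
    finetuned = []
    for i, (subject, (tr, va)) in enumerate(zip(all_subjects, splits)):
        model = stage1.clone()
        sub_cfg = replace(cfg, seed=cfg.seed + 1000 + i)
        if aug is None:
            train_model(model, (subject.data[tr], subject.labels[tr]),
                        (subject.data[va], subject.labels[va]), sub_cfg)
        else:
            pool_idx = np.concatenate([tr, va])
            pool = subject.replace(data=subject.data[pool_idx],
                                   labels=subject.labels[pool_idx])
            aug_i = replace(aug, seed=aug.seed + i)
            Xa, ya, yp, lam, Xm = samples_to_arrays(bgmix_generate(pool, aug_i))
            train_model(model, (Xa, ya, yp, lam, Xm),
                        (pool.data, pool.labels), sub_cfg)
        finetuned.append(model)
    return stage1, finetuned


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def balanced_accuracy(confusion: np.ndarray) -> float:
    """Mean per-class recall from a (K, K) confusion matrix (rows = truth)."""
    confusion = np.asarray(confusion)
    if np.any(confusion < 0):
        raise ValueError("confusion counts must be non-negative")
    row_sums = confusion.sum(axis=1)
    if np.any(row_sums == 0):
        raise ValueError("every class needs at least one test sample")
    return float(np.mean(np.diag(confusion) / row_sums))


def itr(N: int, P: float, T: float) -> float:
    """Information transfer rate in bits/min.

    ``(60/T) * [log2 N + P log2 P + (1-P) log2((1-P)/(N-1))]`` with the
    ``0 * log 0 := 0`` convention; below-chance accuracies (P < 1/N) are
    floored to 0 bits/min.
    """
    if N < 2:
        raise ValueError("need at least 2 stimuli")
    if not 0.0 <= P <= 1.0:
        raise ValueError("accuracy must lie in [0, 1]")
    if T <= 0:
        raise ValueError("selection time must be positive")
    if P < 1.0 / N:
        return 0.0
    bits = math.log2(N)
    if P > 0:
        bits += P * math.log2(P)
    if P < 1:
        bits += (1 - P) * math.log2((1 - P) / (N - 1))
    return max(60.0 / T * bits, 0.0)


def evaluate(predict_fns, split: SplitPlan, data: EpochedEEG,
             selection_time_overhead: float = 0.5) -> EvalReport:
    """Accumulate per-fold confusions and report BA and ITR.

    ``predict_fns`` is one callable (trial -> label) per fold.  The ITR
    selection time is the trial window length plus the gaze-shift overhead.
    """
    if len(predict_fns) != split.n_folds:
        raise ValueError(f"{split.n_folds} folds but {len(predict_fns)} models")
    nf = data.n_classes
    confusion = np.zeros((nf, nf), dtype=int)
    per_fold = []
    for fold, (fn, (_, _, test)) in enumerate(zip(predict_fns, split.folds)):
        fold_conf = np.zeros((nf, nf), dtype=int)
        for i in test:
            pred = int(fn(data.data[i]))
            fold_conf[data.labels[i], pred] += 1
        confusion += fold_conf
        per_fold.append({"fold": fold,
                         "accuracy": float(np.trace(fold_conf) / fold_conf.sum())})
    ba = balanced_accuracy(confusion)
    T = data.n_samples / data.fs + selection_time_overhead
    overall_acc = float(np.trace(confusion) / confusion.sum())
    return EvalReport(confusion, ba, itr(nf, overall_acc, T), T, tuple(per_fold))
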