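"""Background-EEG mixing (BGMix) augmentation, plus the Mixup comparator.

An SSVEP trial is modelled as a phase-locked task-related component plus
task-unrelated background activity.  Averaging trials of a class estimates
the task component (the *template*); subtracting the template from a single
trial leaves its *background residual*.  BGMix manufactures new trials by
pairing a target class's template with background residuals donated by a
different class:

    x_new = template(target class) + residual(donor class)

Every swap is symmetric: the same draw also yields the *mirror* sample
``template(donor) + residual(target)``.  The mixing weight
``lam ~ Beta(alpha, beta)`` plays no role in either waveform — each is a
plain sum — it only distributes the training loss across the swap pair:
``lam * loss(y, x_new) + (1 - lam) * loss(y', x_mirror)``.  Each waveform is
thus supervised only by the label whose task component it actually
contains.  This is the point where BGMix departs from Mixup, which
interpolates the signals themselves and therefore weighs both labels
against the one blended waveform.

Templates here follow the operational subset convention: each generated
batch draws ``n`` trials of the target class for the template and ``n``
trials of the donor class whose own ``n``-trial template is subtracted to
yield ``n`` residuals, giving ``n`` new samples per draw.  A switch
(``template_scope="all"``) instead uses the full class average on both
sides.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .eeg_data import EpochedEEG

__all__ = [
    "TemplateSet",
    "BackgroundSet",
    "MixedSample",
    "BGMixConfig",
    "compute_template",
    "compute_background",
    "bgmix_generate",
    "mixup_generate",
    "mixed_loss",
    "samples_to_arrays",
]


@dataclass(frozen=True)
class TemplateSet:
    """Per-class trial-averaged task components."""

    templates: np.ndarray          # (n_classes, n_channels, n_samples)
    source_trial_ids: tuple[tuple[int, ...], ...]


@dataclass(frozen=True)
class BackgroundSet:
    """Per-trial background residuals with the class they were donated by."""

    residuals: np.ndarray          # (n, n_channels, n_samples)
    donor_class: np.ndarray        # (n,)


@dataclass(frozen=True)
class MixedSample:
    """One generated trial with its label pair and loss-mixing weight.

    ``x_mirror`` is the symmetric swap (donor template + target-class
    residual) that carries the ``(1 - lam)`` loss term; Mixup samples,
    which blend both classes into the single ``x_tilde``, have none.
    """

    x_tilde: np.ndarray
    y_template: int
    y_background: int
    lam: float
    x_mirror: np.ndarray | None = None

    def __post_init__(self):
        if not 0.0 <= self.lam <= 1.0:
            raise ValueError(f"lam must lie in [0, 1], got {self.lam}")
        if self.y_template == self.y_background:
            raise ValueError("template and background classes must differ")


@dataclass(frozen=True)
class BGMixConfig:
    """Augmentation schedule.

    ``passes`` is a list of ``(n_trials_per_template, factor)`` pairs; each
    pass generates ``factor`` samples per original training trial using
    ``n``-trial templates.  The published schedules are ``[(2, 40), (3, 40)]``
    (80x overall) and ``[(2, 40), (3, 40), (4, 40)]`` (120x overall).
    """

    passes: tuple[tuple[int, int], ...] = ((2, 40), (3, 40))
    lam_beta_alpha: float = 1.0
    lam_beta_beta: float = 1.0
    template_scope: str = "subset"   # or "all"
    seed: int = 0

    def __post_init__(self):
        for n, factor in self.passes:
            if n < 2:
                raise ValueError("template size n must be >= 2")
            if factor < 1:
                raise ValueError("factor must be >= 1")
        if self.template_scope not in ("subset", "all"):
            raise ValueError("template_scope must be 'subset' or 'all'")


def compute_template(trials: np.ndarray) -> np.ndarray:
    """Elementwise mean over the trial axis (axis 0)."""
    trials = np.asarray(trials, dtype=float)
    if trials.ndim < 1 or trials.shape[0] == 0:
        raise ValueError("need at least one trial")
    return trials.mean(axis=0)


def compute_background(trial: np.ndarray, template: np.ndarray) -> np.ndarray:
    """Background residual: trial minus its class template."""
    trial = np.asarray(trial, dtype=float)
    template = np.asarray(template, dtype=float)
    if trial.shape != template.shape:
        raise ValueError(f"shape mismatch {trial.shape} vs {template.shape}")
    return trial - template


def class_templates(e: EpochedEEG) -> TemplateSet:
    """Full-class-average templates for every class in the dataset."""
    nf = e.n_classes
    templates = np.stack([compute_template(e.class_trials(m)) for m in range(nf)])
    ids = tuple(tuple(np.flatnonzero(e.labels == m)) for m in range(nf))
    return TemplateSet(templates, ids)


def bgmix_generate(train: EpochedEEG, cfg: BGMixConfig) -> list[MixedSample]:
    """Generate the BGMix-augmented sample set for a training split.

    Per pass ``(n, factor)`` and per original trial, ``factor`` samples are
    emitted (draws of ``n`` are truncated on the last draw so the
    generated:original ratio is exactly the sum of the factors).  The donor
    class is uniform over classes other than the target.  Deterministic
    under ``cfg.seed``; per-class output counts scale the per-class input
    counts by the same factor, so class balance is preserved.
    """
    classes = np.unique(train.labels)
    if len(classes) < 2:
        raise ValueError("BGMix needs at least 2 classes")
    per_class = {int(c): np.flatnonzero(train.labels == c) for c in classes}
    min_count = min(len(v) for v in per_class.values())
    max_n = max(n for n, _ in cfg.passes)
    if max_n > min_count:
        raise ValueError(
            f"template size {max_n} exceeds the smallest class count {min_count}"
        )
    rng = np.random.default_rng(cfg.seed)
    full = class_templates(train) if cfg.template_scope == "all" else None

    samples: list[MixedSample] = []
    for n, factor in cfg.passes:
        for i in range(train.n_trials):
            y = int(train.labels[i])
            emitted = 0
            while emitted < factor:
                pick = rng.choice(per_class[y], size=n, replace=False)
                target_trials = train.data[pick]
                template = (full.templates[y] if cfg.template_scope == "all"
                            else compute_template(target_trials))
                target_residuals = target_trials - template
                y_donor = int(rng.choice(classes[classes != y]))
                donor_pick = rng.choice(per_class[y_donor], size=n, replace=False)
                donor_trials = train.data[donor_pick]
                donor_template = (full.templates[y_donor] if cfg.template_scope == "all"
                                  else compute_template(donor_trials))
                residuals = donor_trials - donor_template
                take = min(n, factor - emitted)
                for j in range(take):
                    lam = float(rng.beta(cfg.lam_beta_alpha, cfg.lam_beta_beta))
                    samples.append(MixedSample(
                        template + residuals[j], y, y_donor, lam,
                        x_mirror=donor_template + target_residuals[j]))
                emitted += take
    return samples


def mixup_generate(train: EpochedEEG, alpha: float, factor: int,
                   seed: int) -> list[MixedSample]:
    """Classic Mixup on raw trials: ``x = lam*x_i + (1-lam)*x_j`` across classes.

    Unlike BGMix the weight shapes the signal itself; the same ``lam`` mixes
    the two labels in the loss.
    """
    classes = np.unique(train.labels)
    if len(classes) < 2:
        raise ValueError("Mixup needs at least 2 classes")
    rng = np.random.default_rng(seed)
    per_class = {int(c): np.flatnonzero(train.labels == c) for c in classes}
    samples: list[MixedSample] = []
    for i in range(train.n_trials):
        y = int(train.labels[i])
        for _ in range(factor):
            y_j = int(rng.choice(classes[classes != y]))
            j = int(rng.choice(per_class[y_j]))
            lam = float(rng.beta(alpha, alpha))
            x = lam * train.data[i] + (1.0 - lam) * train.data[j]
            samples.append(MixedSample(x, y, y_j, lam))
    return samples


def mixed_loss(loss_y: float, loss_y_prime: float, lam: float) -> float:
    """Two-term label fusion: ``lam * loss_y + (1 - lam) * loss_y_prime``."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lam must lie in [0, 1], got {lam}")
    return lam * loss_y + (1.0 - lam) * loss_y_prime


def samples_to_arrays(samples: list[MixedSample]):
    """Stack a generated sample list into (X, y, y_prime, lam, X_mirror).

    ``X_mirror`` is None for sample sets without mirrors (Mixup)."""
    X = np.stack([s.x_tilde for s in samples])
    y = np.array([s.y_template for s in samples], dtype=int)
    y_prime = np.array([s.y_background for s in samples], dtype=int)
    lam = np.array([s.lam for s in samples], dtype=float)
    if all(s.x_mirror is not None for s in samples):
        Xm = np.stack([s.x_mirror for s in samples])
    else:
        Xm = None
    return X, y, y_prime, lam, Xm
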