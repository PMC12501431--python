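"""Classical SSVEP decoders: ensemble TRCA and TDCA.

TRCA finds, per class, the channel-weight vector w maximising the
reproducibility of the projected signal across trials: the Rayleigh
quotient w' S w / w' Q w, where S sums the cross-trial covariances over all
ordered trial pairs (h1 != h2) and Q pools the within-trial covariances.
eTRCA stacks the per-class filters into one ensemble matrix W and classifies
a trial by the correlation between W-projected trial and W-projected class
template, combined over a filter bank of sub-bands (m*8 to 90 Hz).

TDCA delay-embeds each trial (l extra lagged copies, zero-padded), augments
it with its projection onto the sinusoidal reference subspace of the
candidate class, and learns Fisher-criterion discriminant directions from
between-/within-class scatter; classification again correlates projected
trial against projected class centres.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg as sla

from .eeg_data import EpochedEEG, FilterSpec, bandpass

__all__ = [
    "ETRCAModel",
    "TDCAModel",
    "trca_spatial_filter",
    "etrca_fit",
    "etrca_predict",
    "tdca_delay_embed",
    "tdca_reference_projection",
    "tdca_fit",
    "tdca_predict",
    "filter_bank_weights",
]

RIDGE_SCALE = 1e-8


def filter_bank_weights(n_bands: int, uniform: bool = False) -> np.ndarray:
    """Sub-band combination weights; default ``m^-1.25 + 0.25``."""
    if uniform:
        return np.ones(n_bands)
    m = np.arange(1, n_bands + 1, dtype=float)
    return m ** -1.25 + 0.25


def _bank_specs(n_bands: int, fs: float, high_hz: float = 90.0) -> list[FilterSpec]:
    specs = []
    for m in range(1, n_bands + 1):
        low = 8.0 * m
        if low >= high_hz:
            raise ValueError(f"sub-band {m} lower edge {low} Hz reaches {high_hz} Hz")
        specs.append(FilterSpec(low, min(high_hz, 0.99 * fs / 2)))
    return specs


def _ridge(mat: np.ndarray) -> np.ndarray:
    eps = RIDGE_SCALE * np.trace(mat) / mat.shape[0]
    return mat + eps * np.eye(mat.shape[0])


def _lead_gev(S: np.ndarray, Q: np.ndarray, k: int = 1) -> np.ndarray:
    """Top-k generalized eigenvectors of (S, Q), ridge-regularised if needed."""
    S = 0.5 * (S + S.T)
    Q = 0.5 * (Q + Q.T)
    try:
        vals, vecs = sla.eigh(S, Q)
    except (np.linalg.LinAlgError, sla.LinAlgError):
        vals, vecs = sla.eigh(S, _ridge(Q))
    order = np.argsort(vals)[::-1]
    return vecs[:, order[:k]]


def _fix_sign(w: np.ndarray) -> np.ndarray:
    w = w / np.linalg.norm(w)
    if w[np.argmax(np.abs(w))] < 0:
        w = -w
    return w


# ---------------------------------------------------------------------------
# TRCA / eTRCA
# ---------------------------------------------------------------------------

def trca_spatial_filter(class_trials: np.ndarray) -> np.ndarray:
    """TRCA filter for one class: leading generalized eigenvector of (S, Q).

    ``class_trials``: (N_t, N_c, N_s), N_t >= 2.  Covariances use 1/N_s
    normalisation; S sums over ordered pairs h1 != h2.  The returned vector
    is unit-norm with its largest-magnitude entry positive.
    """
    X = np.asarray(class_trials, dtype=float)
    if X.ndim != 3 or X.shape[0] < 2:
        raise ValueError("need a (N_t >= 2, N_c, N_s) trial stack")
    nt, nc, ns = X.shape
    Xc = X - X.mean(axis=2, keepdims=True)
    # sum over all ordered pairs = total minus the diagonal (within-trial) part
    total = Xc.sum(axis=0)
    Q = np.einsum("hcs,hds->cd", Xc, Xc) / ns
    S = (total @ total.T) / ns - Q
    w = _lead_gev(S, _ridge(Q) if np.linalg.cond(Q) > 1e10 else Q)[:, 0]
    return _fix_sign(w)


@dataclass(frozen=True)
class ETRCAModel:
    filters: np.ndarray          # (n_bands, N_c, N_f)
    class_templates: np.ndarray  # (n_bands, N_f, N_c, N_s)
    bank: tuple[tuple[float, float], ...]
    bank_weights: np.ndarray
    fs: float


def etrca_fit(train: EpochedEEG, n_bands: int = 3,
              uniform_weights: bool = False) -> ETRCAModel:
    """Fit the filter-bank ensemble TRCA model (one filter column per class)."""
    classes = np.unique(train.labels)
    nf = len(classes)
    if any((train.labels == c).sum() < 2 for c in classes):
        raise ValueError("every class needs at least 2 training trials")
    specs = _bank_specs(n_bands, train.fs)
    filters = np.empty((n_bands, train.n_channels, nf))
    templates = np.empty((n_bands, nf, train.n_channels, train.n_samples))
    for b, spec in enumerate(specs):
        sub = bandpass(train, spec)
        for k, c in enumerate(classes):
            trials = sub.class_trials(c)
            filters[b, :, k] = trca_spatial_filter(trials)
            templates[b, k] = trials.mean(axis=0)
    return ETRCAModel(
        filters, templates,
        tuple((s.low_hz, s.high_hz) for s in specs),
        filter_bank_weights(n_bands, uniform_weights),
        train.fs,
    )


def _corr(a: np.ndarray, b: np.ndarray) -> float:
    a = a.ravel() - a.ravel().mean()
    b = b.ravel() - b.ravel().mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(a @ b / (na * nb))


def etrca_scores(model: ETRCAModel, x: np.ndarray) -> np.ndarray:
    """Per-class band-combined correlation scores for one trial."""
    x = np.asarray(x, dtype=float)
    nf = model.filters.shape[2]
    scores = np.zeros(nf)
    for b, (low, high) in enumerate(model.bank):
        spec = FilterSpec(low, high)
        xb = bandpass(EpochedEEG(x[None], np.zeros(1, int), model.fs,
                                 tuple(f"c{i}" for i in range(x.shape[0]))), spec).data[0]
        W = model.filters[b]
        proj = W.T @ xb
        for k in range(nf):
            scores[k] += model.bank_weights[b] * _corr(proj, W.T @ model.class_templates[b, k])
    return scores


def etrca_predict(model: ETRCAModel, x: np.ndarray,
                  return_scores: bool = False):
    """Argmax of the per-class scores; ties break to the lowest class index."""
    scores = etrca_scores(model, x)
    label = int(np.argmax(scores))
    return (label, scores) if return_scores else label


# ---------------------------------------------------------------------------
# TDCA
# ---------------------------------------------------------------------------

def tdca_delay_embed(X: np.ndarray, l: int, n_samples: int | None = None) -> np.ndarray:
    """Stack X with l left-shifted copies; vacated trailing columns are zero.

    If ``X`` carries more than ``n_samples`` columns the shifts use the real
    extra data (training-trial convention); otherwise they are zero-padded
    (test-trial convention).
    """
    X = np.asarray(X, dtype=float)
    nc, total = X.shape
    ns = n_samples if n_samples is not None else total
    if l < 0 or l >= ns:
        raise ValueError(f"delay count l={l} must satisfy 0 <= l < n_samples={ns}")
    out = np.zeros(((l + 1) * nc, ns))
    for d in range(l + 1):
        avail = min(ns, total - d)
        out[d * nc:(d + 1) * nc, :avail] = X[:, d:d + avail]
    return out


def tdca_reference_projection(f_i: float, N_h: int, N_s: int, fs: float) -> np.ndarray:
    """Orthogonal projector onto the span of the first N_h sine/cosine
    harmonics of ``f_i`` sampled at ``t = 1/fs .. N_s/fs``."""
    if N_h * f_i >= fs / 2:
        raise ValueError(f"harmonic {N_h}*{f_i} Hz aliases at fs={fs}")
    t = np.arange(1, N_s + 1) / fs
    rows = []
    for k in range(1, N_h + 1):
        rows.append(np.sin(2 * np.pi * k * f_i * t))
        rows.append(np.cos(2 * np.pi * k * f_i * t))
    Y = np.stack(rows)                       # (2*N_h, N_s)
    Qmat, _ = np.linalg.qr(Y.T)              # (N_s, 2*N_h)
    return Qmat @ Qmat.T


@dataclass(frozen=True)
class TDCAModel:
    l: int
    N_h: int
    stim_freqs: tuple[float, ...]
    projections: np.ndarray      # (N_f, N_s, N_s)
    W_lda: np.ndarray            # per band: (n_bands, (l+1)N_c, K_dims)
    class_centers: np.ndarray    # (n_bands, N_f, (l+1)N_c, 2*N_s)
    bank: tuple[tuple[float, float], ...]
    bank_weights: np.ndarray
    fs: float


def _secondary_augment(Xe: np.ndarray, P: np.ndarray) -> np.ndarray:
    """[X_embedded, X_embedded @ P] — width doubles to 2*N_s."""
    return np.concatenate([Xe, Xe @ P], axis=1)


def tdca_fit(train: EpochedEEG, stim_freqs, l: int = 5, N_h: int = 5,
             K_dims: int = 8, n_bands: int = 1,
             uniform_weights: bool = False) -> TDCAModel:
    """Fit TDCA: delay embedding, reference-subspace augmentation, Fisher LDA."""
    classes = np.unique(train.labels)
    nf = len(classes)
    if len(stim_freqs) != nf:
        raise ValueError("need one stimulus frequency per class")
    ns = train.n_samples
    projections = np.stack([
        tdca_reference_projection(f, N_h, ns, train.fs) for f in stim_freqs
    ])
    specs = _bank_specs(n_bands, train.fs)
    rows = (l + 1) * train.n_channels
    K_dims = min(K_dims, rows)
    W_all = np.empty((n_bands, rows, K_dims))
    centers = np.empty((n_bands, nf, rows, 2 * ns))
    for b, spec in enumerate(specs):
        sub = bandpass(train, spec)
        aug = []  # per class: (n_trials, rows, 2*ns)
        for k, c in enumerate(classes):
            trials = sub.class_trials(c)
            Xa = np.stack([
                _secondary_augment(tdca_delay_embed(x, l), projections[k])
                for x in trials
            ])
            aug.append(Xa)
            centers[b, k] = Xa.mean(axis=0)
        grand = centers[b].mean(axis=0)
        Hb = np.concatenate([(centers[b, k] - grand) for k in range(nf)],
                            axis=1) / np.sqrt(nf)
        Hw_parts = [aug[k] - centers[b, k] for k in range(nf)]
        Hw = np.concatenate(
            [np.concatenate(list(h), axis=1) for h in Hw_parts], axis=1)
        Hw /= np.sqrt(sum(h.shape[0] for h in Hw_parts) * nf)
        Sb = Hb @ Hb.T
        Sw = Hw @ Hw.T
        W_all[b] = _lead_gev(Sb, _ridge(Sw), k=K_dims)
    return TDCAModel(l, N_h, tuple(float(f) for f in stim_freqs), projections,
                     W_all, centers,
                     tuple((s.low_hz, s.high_hz) for s in specs),
                     filter_bank_weights(n_bands, uniform_weights), train.fs)


def tdca_scores(model: TDCAModel, x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    nf = len(model.stim_freqs)
    ns = model.projections.shape[1]
    scores = np.zeros(nf)
    for b, (low, high) in enumerate(model.bank):
        spec = FilterSpec(low, high)
        xb = bandpass(EpochedEEG(x[None], np.zeros(1, int), model.fs,
                                 tuple(f"c{i}" for i in range(x.shape[0]))), spec).data[0]
        Xe = tdca_delay_embed(xb, model.l, n_samples=ns)
        W = model.W_lda[b]
        for k in range(nf):
            Xa = _secondary_augment(Xe, model.projections[k])
            scores[k] += model.bank_weights[b] * _corr(
                W.T @ Xa, W.T @ model.class_centers[b, k])
    return scores


def tdca_predict(model: TDCAModel, x: np.ndarray, return_scores: bool = False):
    scores = tdca_scores(model, x)
    label = int(np.argmax(scores))
    return (label, scores) if return_scores else label


# ---------------------------------------------------------------------------
# Serialization (HDF5 container with the bank settings embedded)
# ---------------------------------------------------------------------------

def save_classical(model: ETRCAModel | TDCAModel, path) -> None:
    import h5py

    kind = "etrca" if isinstance(model, ETRCAModel) else "tdca"
    with h5py.File(path, "w") as f:
        f.attrs["kind"] = kind
        f.attrs["fs"] = model.fs
        f.create_dataset("bank", data=np.asarray(model.bank))
        f.create_dataset("bank_weights", data=model.bank_weights)
        if kind == "etrca":
            f.create_dataset("filters", data=model.filters)
            f.create_dataset("class_templates", data=model.class_templates)
        else:
            f.attrs["l"] = model.l
            f.attrs["N_h"] = model.N_h
            f.create_dataset("stim_freqs", data=np.asarray(model.stim_freqs))
            f.create_dataset("projections", data=model.projections)
            f.create_dataset("W_lda", data=model.W_lda)
            f.create_dataset("class_centers", data=model.class_centers)


def load_classical(path) -> ETRCAModel | TDCAModel:
    import h5py

    with h5py.File(path, "r") as f:
        bank = tuple((float(lo), float(hi)) for lo, hi in f["bank"][()])
        weights = f["bank_weights"][()]
        fs = float(f.attrs["fs"])
        if f.attrs["kind"] == "etrca":
            return ETRCAModel(f["filters"][()], f["class_templates"][()],
                              bank, weights, fs)
        return TDCAModel(int(f.attrs["l"]), int(f.attrs["N_h"]),
                         tuple(float(x) for x in f["stim_freqs"][()]),
                         f["projections"][()], f["W_lda"][()],
                         f["class_centers"][()], bank, weights, fs)
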