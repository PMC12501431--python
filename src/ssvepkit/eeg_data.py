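"""Epoched-EEG data model, file I/O, preprocessing and trial-level splitting.

The universal currency of the toolkit is :class:`EpochedEEG`: a
``trials x channels x samples`` array with integer class labels, a sampling
rate and channel names.  Readers normalise external layouts (MATLAB arrays,
EDF recordings, the internal HDF5 container) into this shape; all sample
indices and time windows are 0-based and half-open.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
from scipy import io as sio
from scipy import signal as ssig

__all__ = [
    "EpochedEEG",
    "FilterSpec",
    "SplitPlan",
    "MatLayout",
    "load_epochs",
    "save_epochs",
    "bandpass",
    "select_channels",
    "crop_window",
    "kfold_trial_split",
]


@dataclass(frozen=True)
class EpochedEEG:
    """Epoched multichannel EEG.

    Parameters
    ----------
    data:
        Array of shape ``(n_trials, n_channels, n_samples)``.
    labels:
        Integer class label per trial, 0-based, in ``[0, n_classes)``.
    fs:
        Sampling rate in Hz.
    channel_names:
        One electrode label per channel.
    subject_id:
        Opaque identifier, carried through transformations.
    """

    data: np.ndarray
    labels: np.ndarray
    fs: float
    channel_names: tuple[str, ...]
    subject_id: str = "S0"

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        labels = np.asarray(self.labels, dtype=int)
        if data.ndim != 3:
            raise ValueError(f"data must be 3-D (trials, channels, samples), got {data.shape}")
        if labels.ndim != 1 or labels.shape[0] != data.shape[0]:
            raise ValueError("labels must be 1-D with one entry per trial")
        if labels.size and labels.min() < 0:
            raise ValueError("labels must be non-negative (0-based)")
        if len(self.channel_names) != data.shape[1]:
            raise ValueError("channel_names length must equal the channel axis")
        if not np.all(np.isfinite(data)):
            raise ValueError("data contains non-finite values")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "channel_names", tuple(str(c) for c in self.channel_names))

    # ---- convenience views -------------------------------------------------
    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def n_classes(self) -> int:
        return int(self.labels.max()) + 1 if self.labels.size else 0

    def class_trials(self, label: int) -> np.ndarray:
        """All trials of one class, shape ``(n, n_channels, n_samples)``."""
        return self.data[self.labels == label]

    def replace(self, **kwargs) -> "EpochedEEG":
        return dataclasses.replace(self, **kwargs)


@dataclass(frozen=True)
class FilterSpec:
    """Chebyshev type-I band-pass specification.

    ``zero_phase`` applies the filter forward-backward (``sosfiltfilt``),
    doubling the effective order but leaving templates latency-free.
    """

    low_hz: float
    high_hz: float
    order: int = 4
    ripple_db: float = 0.5
    zero_phase: bool = True

    def validate(self, fs: float) -> None:
        if not 0 < self.low_hz < self.high_hz:
            raise ValueError(f"need 0 < low_hz < high_hz, got ({self.low_hz}, {self.high_hz})")
        if self.high_hz >= fs / 2:
            raise ValueError(f"high_hz={self.high_hz} must be below Nyquist {fs / 2}")

    def sos(self, fs: float) -> np.ndarray:
        self.validate(fs)
        return ssig.cheby1(
            self.order, self.ripple_db, [self.low_hz, self.high_hz],
            btype="bandpass", fs=fs, output="sos",
        )


@dataclass(frozen=True)
class SplitPlan:
    """Trial-level cross-validation plan: one (train, val, test) triple per fold."""

    folds: tuple[tuple[np.ndarray, np.ndarray, np.ndarray], ...]

    @property
    def n_folds(self) -> int:
        return len(self.folds)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MatLayout:
    """Declarative description of a MATLAB epoch array.

    ``axes`` names the meaning of each array axis in order, drawn from
    ``{"channels", "samples", "classes", "blocks", "trials"}``.  When a
    ``classes`` axis is present the class index along it becomes the label;
    otherwise ``label_key`` names a label vector (``label_base`` subtracted,
    so 1-based MATLAB labels become 0-based).
    """

    key: str
    axes: tuple[str, ...]
    fs: float
    channel_names: tuple[str, ...] | None = None
    label_key: str | None = None
    label_base: int = 0

    def __post_init__(self) -> None:
        allowed = {"channels", "samples", "classes", "blocks", "trials"}
        unknown = set(self.axes) - allowed
        if unknown:
            raise ValueError(f"unknown axis names {sorted(unknown)}")
        if "channels" not in self.axes or "samples" not in self.axes:
            raise ValueError("layout must declare channels and samples axes")


def _load_mat_var(path: Path, key: str) -> np.ndarray:
    try:
        mat = sio.loadmat(path)
        if key not in mat:
            raise KeyError(key)
        return np.asarray(mat[key])
    except NotImplementedError:
        # v7.3 files are HDF5; MATLAB stores arrays with reversed axis order.
        with h5py.File(path, "r") as f:
            if key not in f:
                raise KeyError(key) from None
            return np.asarray(f[key]).T


def _epochs_from_array(arr: np.ndarray, layout: MatLayout, subject_id: str) -> EpochedEEG:
    if arr.ndim != len(layout.axes):
        raise ValueError(
            f"array has {arr.ndim} axes but layout declares {len(layout.axes)} ({layout.axes})"
        )
    order = {name: i for i, name in enumerate(layout.axes)}
    if "classes" in order:
        trial_axes = [order[a] for a in ("classes", "blocks", "trials") if a in order]
        perm = trial_axes + [order["channels"], order["samples"]]
        arr = np.transpose(arr, perm)
        trial_shape = arr.shape[: len(trial_axes)]
        n_classes = trial_shape[0]
        n_rep = int(np.prod(trial_shape[1:], dtype=int)) if len(trial_shape) > 1 else 1
        data = arr.reshape(n_classes * n_rep, arr.shape[-2], arr.shape[-1])
        labels = np.repeat(np.arange(n_classes), n_rep)
    else:
        trial_axes = [order[a] for a in ("blocks", "trials") if a in order]
        if not trial_axes:
            raise ValueError("layout needs a classes, trials or blocks axis")
        perm = trial_axes + [order["channels"], order["samples"]]
        arr = np.transpose(arr, perm)
        data = arr.reshape(-1, arr.shape[-2], arr.shape[-1])
        if layout.label_key is None:
            raise ValueError("layout without a classes axis must give label_key")
        raise _NeedLabels(data)  # resolved by caller which holds the file handle
    names = layout.channel_names or tuple(f"ch{i}" for i in range(data.shape[1]))
    return EpochedEEG(data, labels, layout.fs, names, subject_id)


class _NeedLabels(Exception):
    def __init__(self, data: np.ndarray):
        self.data = data


def load_epochs(path, format: str, layout: MatLayout | None = None,
                subject_id: str | None = None, **edf_kwargs) -> EpochedEEG:
    """Read epoched EEG from ``mat``, ``edf`` or the internal ``hdf5`` container.

    ``mat`` requires a :class:`MatLayout`; ``edf`` accepts ``trial_len``
    (seconds per epoch, cut from annotation onsets whose description is an
    integer class) via keyword arguments.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    subject_id = subject_id or path.stem
    if format == "hdf5":
        return _load_hdf5(path)
    if format == "mat":
        if layout is None:
            raise ValueError("mat format requires a MatLayout")
        arr = _load_mat_var(path, layout.key)
        try:
            epochs = _epochs_from_array(arr, layout, subject_id)
        except _NeedLabels as need:
            labels = _load_mat_var(path, layout.label_key).ravel().astype(int) - layout.label_base
            names = layout.channel_names or tuple(f"ch{i}" for i in range(need.data.shape[1]))
            epochs = EpochedEEG(need.data, labels, layout.fs, names, subject_id)
        _check_labels(epochs)
        return epochs
    if format == "edf":
        return _load_edf(path, subject_id, **edf_kwargs)
    raise ValueError(f"unknown format {format!r}; expected mat, edf or hdf5")


def _check_labels(e: EpochedEEG) -> None:
    n_classes = int(e.labels.max()) + 1
    if e.labels.min() < 0:
        raise ValueError("parsed labels fall outside [0, n_classes)")
    counts = np.bincount(e.labels, minlength=n_classes)
    if np.any(counts == 0):
        raise ValueError("parsed labels skip a class index; labels must cover [0, n_classes)")


def _load_edf(path: Path, subject_id: str, trial_len: float = 1.0) -> EpochedEEG:
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    fs = float(raw.info["sfreq"])
    n_per = int(np.floor(trial_len * fs))
    onsets, labels = [], []
    for onset, _dur, desc in zip(
        raw.annotations.onset, raw.annotations.duration, raw.annotations.description
    ):
        try:
            labels.append(int(str(desc).strip()))
        except ValueError:
            continue
        onsets.append(int(round(onset * fs)))
    if not onsets:
        raise ValueError(f"{path}: no integer-class annotations found to epoch on")
    sigs = raw.get_data()
    trials = []
    for start in onsets:
        if start + n_per > sigs.shape[1]:
            raise ValueError("annotation window exceeds recording length")
        trials.append(sigs[:, start:start + n_per])
    labels = np.asarray(labels)
    labels -= labels.min()  # normalise to 0-based
    return EpochedEEG(np.stack(trials), labels, fs, tuple(raw.ch_names), subject_id)


def save_epochs(e: EpochedEEG, path, extra: dict[str, np.ndarray] | None = None) -> None:
    """Write the internal HDF5 epochs container (``/data``, ``/labels``)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=e.data)
        f.create_dataset("labels", data=e.labels)
        f.attrs["fs"] = e.fs
        f.attrs["channel_names"] = json.dumps(list(e.channel_names))
        f.attrs["subject_id"] = e.subject_id
        for key, val in (extra or {}).items():
            f.create_dataset(key, data=val)


def _load_hdf5(path: Path) -> EpochedEEG:
    with h5py.File(path, "r") as f:
        e = EpochedEEG(
            f["data"][()],
            f["labels"][()],
            float(f.attrs["fs"]),
            tuple(json.loads(f.attrs["channel_names"])),
            str(f.attrs.get("subject_id", path.stem)),
        )
    _check_labels(e)
    return e


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def bandpass(e: EpochedEEG, spec: FilterSpec) -> EpochedEEG:
    """Band-pass every channel of every trial identically along the time axis."""
    sos = spec.sos(e.fs)
    if spec.zero_phase:
        out = ssig.sosfiltfilt(sos, e.data, axis=-1)
    else:
        out = ssig.sosfilt(sos, e.data, axis=-1)
    return e.replace(data=out)


def select_channels(e: EpochedEEG, names: Sequence[str]) -> EpochedEEG:
    """Keep (and reorder to) the requested channels; names match case-insensitively."""
    lookup = {c.lower(): i for i, c in enumerate(e.channel_names)}
    idx = []
    for name in names:
        i = lookup.get(str(name).lower())
        if i is None:
            raise KeyError(f"channel {name!r} not present in {list(e.channel_names)}")
        idx.append(i)
    idx = np.asarray(idx, dtype=int)
    return e.replace(data=e.data[:, idx, :],
                     channel_names=tuple(e.channel_names[i] for i in idx))


def crop_window(e: EpochedEEG, t_start: float, t_len: float) -> EpochedEEG:
    """Crop each trial to the half-open window ``[t_start, t_start + t_len)``.

    Sample counts use the floor convention: ``n = floor(t_len * fs)``.
    """
    start = int(np.floor(t_start * e.fs))
    n = int(np.floor(t_len * e.fs))
    if n < 1:
        raise ValueError("window shorter than one sample")
    if start < 0 or start + n > e.n_samples:
        raise ValueError(
            f"window [{t_start}, {t_start + t_len}) s exceeds trial of "
            f"{e.n_samples / e.fs} s"
        )
    return e.replace(data=e.data[:, :, start:start + n])


# ---------------------------------------------------------------------------
# Splitting
# ---------------------------------------------------------------------------

def kfold_trial_split(e: EpochedEEG, seed: int, n_val_per_class: int = 1) -> SplitPlan:
    """Trial-level K-fold plan: per fold, one test and one validation trial per class.

    The number of folds equals the smallest per-class trial count.  Within a
    class the shuffled trials rotate through the test role; the validation
    trial is the cyclically next one, so train/val/test are disjoint and
    exhaustive in every fold.  Deterministic under ``seed``.
    """
    rng = np.random.default_rng(seed)
    classes = np.unique(e.labels)
    per_class = {c: np.flatnonzero(e.labels == c) for c in classes}
    min_count = min(len(v) for v in per_class.values())
    if min_count < 2 + n_val_per_class:
        raise ValueError(
            f"need at least {2 + n_val_per_class} trials per class, got {min_count}"
        )
    shuffled = {c: rng.permutation(idx) for c, idx in per_class.items()}
    folds = []
    for k in range(min_count):
        train, val, test = [], [], []
        for c in classes:
            idx = shuffled[c]
            m = len(idx)
            test_i = {k % m}
            val_i = {(k + 1 + j) % m for j in range(n_val_per_class)}
            rest = [i for i in range(m) if i not in test_i and i not in val_i]
            test.extend(idx[sorted(test_i)])
            val.extend(idx[sorted(val_i)])
            train.extend(idx[rest])
        folds.append((np.sort(train), np.sort(val), np.sort(test)))
    return SplitPlan(tuple(folds))
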