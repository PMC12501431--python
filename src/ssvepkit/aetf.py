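"""Transformer decoder for epoched SSVEP trials.

Architecture (one trial ``(N_c, N_s)`` in, ``N_f`` logits out):

1. a fully connected layer across channels at every time point, tanh
   activation — a bank of ``N_sp`` learned nonlinear spatial filters;
2. a 'same'-padded convolution along time with ``N_fr`` kernels of length
   ``floor(fs/2)`` (long enough to resolve 2 Hz), ELU, then batch
   normalisation per feature map — learned frequency filters;
3. the ``(N_fr, N_sp, N_s)`` stack is read as a sequence of ``N_s`` time
   tokens with embedding dimension ``d_model = N_fr * N_sp``, summed with a
   sinusoidal positional encoding and passed through ``N_layer`` Transformer
   encoder layers (multihead self-attention with ``N_fr`` heads +
   position-wise feed-forward, residual connections and layer norm,
   leaky-ReLU activation);
4. the whole sequence is flattened and a linear layer produces the class
   logits — no pooling, so no temporal information is discarded.

The distilled student variant keeps the same front end but uses a single
encoder layer at half the embedding width.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict, replace

import h5py
import numpy as np

from . import nn
from .nn import Tensor, Parameter

__all__ = [
    "AETFConfig",
    "AETFModel",
    "positional_encoding",
    "scaled_dot_attention",
    "multihead_attention",
    "make_student",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class AETFConfig:
    """Architecture hyperparameters.

    Defaults follow the published configuration: ``n_spatial`` twice the
    electrode count, 8 frequency filters, a 2-layer encoder with embedding
    width ``n_spatial * n_freq_filters`` and one attention head per
    frequency filter.  ``use_encoder=False`` removes the positional encoding
    and encoder stack entirely (ablation variant).
    """

    n_channels: int
    n_samples: int
    n_classes: int
    fs: float
    n_spatial: int = 0            # 0 -> 2 * n_channels
    n_freq_filters: int = 8
    n_layers: int = 2
    n_heads: int = 0              # 0 -> n_freq_filters
    ff_dim: int = 0               # 0 -> 2 * d_model
    dropout: float = 0.1
    leaky_slope: float = 0.01
    use_encoder: bool = True

    def __post_init__(self):
        if self.n_spatial == 0:
            object.__setattr__(self, "n_spatial", 2 * self.n_channels)
        if self.n_heads == 0:
            object.__setattr__(self, "n_heads", self.n_freq_filters)
        if self.ff_dim == 0:
            object.__setattr__(self, "ff_dim", 2 * self.d_model)
        if self.d_model % self.n_heads:
            raise ValueError(
                f"d_model={self.d_model} not divisible by n_heads={self.n_heads}"
            )
        if self.ff_dim < self.d_model:
            raise ValueError("ff_dim must be >= d_model")

    @property
    def d_model(self) -> int:
        return self.n_spatial * self.n_freq_filters

    @property
    def kernel_len(self) -> int:
        k = int(math.floor(self.fs / 2))
        if k > self.n_samples:
            warnings.warn(
                f"conv kernel floor(fs/2)={k} exceeds n_samples={self.n_samples}; "
                "clipping to the window length"
            )
            k = self.n_samples
        return max(k, 1)


def make_student(cfg: AETFConfig) -> AETFConfig:
    """Distillation student: one encoder layer, embedding width halved.

    The width is halved by halving the spatial-filter count.  If the head
    count no longer divides the halved width it is reduced to the largest
    divisor, with a warning.
    """
    n_spatial = max(cfg.n_spatial // 2, 1)
    d_model = n_spatial * cfg.n_freq_filters
    n_heads = cfg.n_heads
    if d_model % n_heads:
        while d_model % n_heads:
            n_heads -= 1
        warnings.warn(f"student head count reduced to {n_heads} to divide d_model={d_model}")
    return replace(cfg, n_layers=1, n_spatial=n_spatial, n_heads=n_heads, ff_dim=0)


# ---------------------------------------------------------------------------
# Functional building blocks (also exposed for direct inspection/testing)
# ---------------------------------------------------------------------------

def positional_encoding(n_pos: int, d_model: int, base: float = 10000.0) -> np.ndarray:
    """Sinusoidal position code: ``PE[p, 2i] = sin(p / base^(2i/d))``, cos on odd."""
    if d_model % 2:
        raise ValueError("d_model must be even")
    pos = np.arange(n_pos)[:, None]
    i = np.arange(d_model // 2)[None, :]
    arg = pos / base ** (2 * i / d_model)
    pe = np.empty((n_pos, d_model))
    pe[:, 0::2] = np.sin(arg)
    pe[:, 1::2] = np.cos(arg)
    return pe


def scaled_dot_attention(Q, K, V, return_weights: bool = False):
    """``softmax(Q K^T / sqrt(d_k)) V`` with row-wise softmax.

    Accepts ndarrays or autodiff tensors; supports leading batch/head axes.
    """
    q, k, v = nn._wrap(Q), nn._wrap(K), nn._wrap(V)
    d_k = q.shape[-1]
    if k.shape[-1] != d_k:
        raise ValueError("query/key dimensions differ")
    if k.shape[-2] != v.shape[-2]:
        raise ValueError("key/value counts differ")
    scores = (q @ k.transpose(*range(k.data.ndim - 2), k.data.ndim - 1, k.data.ndim - 2)) \
        * (1.0 / math.sqrt(d_k))
    w = nn.softmax(scores, axis=-1)
    out = w @ v
    if return_weights:
        return out, w
    return out


def multihead_attention(X, n_heads: int, Wq, Wk, Wv, Wo,
                        return_weights: bool = False):
    """Multihead self-attention on a (..., n, d_model) input.

    The projections are (d_model, d_model) matrices; heads are the split of
    the projected dimension into ``n_heads`` blocks of ``d_model/n_heads``.
    """
    x = nn._wrap(X)
    *lead, n, d_model = x.shape
    if d_model % n_heads:
        raise ValueError(f"d_model={d_model} not divisible by {n_heads} heads")
    d_k = d_model // n_heads

    def split(t):  # (..., n, d_model) -> (..., h, n, d_k)
        t = t.reshape(*lead, n, n_heads, d_k)
        axes = list(range(t.data.ndim))
        axes[-3], axes[-2] = axes[-2], axes[-3]
        return t.transpose(*axes)

    q = split(x @ nn._wrap(Wq))
    k = split(x @ nn._wrap(Wk))
    v = split(x @ nn._wrap(Wv))
    heads, w = scaled_dot_attention(q, k, v, return_weights=True)
    axes = list(range(heads.data.ndim))
    axes[-3], axes[-2] = axes[-2], axes[-3]
    merged = heads.transpose(*axes).reshape(*lead, n, d_model)
    out = merged @ nn._wrap(Wo)
    if return_weights:
        return out, w
    return out


def _layer_norm(x: Tensor, gamma: Parameter, beta: Parameter, eps=1e-5) -> Tensor:
    mu = x.mean(axis=-1, keepdims=True)
    d = x - mu
    var = (d * d).mean(axis=-1, keepdims=True)
    return d * (var + eps) ** -0.5 * gamma + beta


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

class AETFModel:
    """The learnable decoder.  Construction is deterministic under ``seed``."""

    def __init__(self, cfg: AETFConfig, seed: int = 0):
        self.cfg = cfg
        self.training = True
        self._rng = np.random.default_rng(seed)
        self.attention_weights: list[np.ndarray] = []
        self.collect_attention = False
        p: dict[str, Parameter] = {}
        r = self._rng

        def glorot(n_in, n_out, shape=None):
            s = math.sqrt(6.0 / (n_in + n_out))
            return Parameter(r.uniform(-s, s, shape or (n_in, n_out)))

        c = cfg
        p["fc_w"] = glorot(c.n_channels, c.n_spatial)
        p["fc_b"] = Parameter(np.zeros(c.n_spatial))
        L = c.kernel_len
        p["conv_k"] = Parameter(r.standard_normal((c.n_freq_filters, L)) / math.sqrt(L))
        p["conv_b"] = Parameter(np.zeros(c.n_freq_filters))
        p["bn_gamma"] = Parameter(np.ones(c.n_freq_filters))
        p["bn_beta"] = Parameter(np.zeros(c.n_freq_filters))
        self.bn_mean = np.zeros(c.n_freq_filters)
        self.bn_var = np.ones(c.n_freq_filters)
        self.bn_momentum = 0.1
        d = c.d_model
        if c.use_encoder:
            for layer in range(c.n_layers):
                for name in ("wq", "wk", "wv", "wo"):
                    p[f"enc{layer}_{name}"] = glorot(d, d)
                p[f"enc{layer}_ff1_w"] = glorot(d, c.ff_dim)
                p[f"enc{layer}_ff1_b"] = Parameter(np.zeros(c.ff_dim))
                p[f"enc{layer}_ff2_w"] = glorot(c.ff_dim, d)
                p[f"enc{layer}_ff2_b"] = Parameter(np.zeros(d))
                for ln in ("ln1", "ln2"):
                    p[f"enc{layer}_{ln}_g"] = Parameter(np.ones(d))
                    p[f"enc{layer}_{ln}_b"] = Parameter(np.zeros(d))
        p["head_w"] = glorot(d * c.n_samples, c.n_classes)
        p["head_b"] = Parameter(np.zeros(c.n_classes))
        self.params = p
        self.pe = positional_encoding(c.n_samples, d) if c.use_encoder else None

    # -- mode & bookkeeping -------------------------------------------------
    def train(self):
        self.training = True
        return self

    def eval(self):
        self.training = False
        return self

    def parameters(self) -> list[Parameter]:
        return list(self.params.values())

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.parameters()))

    def state_dict(self) -> dict[str, np.ndarray]:
        d = {k: v.data.copy() for k, v in self.params.items()}
        d["__bn_mean"] = self.bn_mean.copy()
        d["__bn_var"] = self.bn_var.copy()
        return d

    def load_state_dict(self, state: dict[str, np.ndarray]):
        for k, v in self.params.items():
            v.data = state[k].copy()
        self.bn_mean = state["__bn_mean"].copy()
        self.bn_var = state["__bn_var"].copy()
        return self

    def clone(self) -> "AETFModel":
        m = AETFModel(self.cfg, seed=0)
        m.load_state_dict(self.state_dict())
        return m

    # -- forward ------------------------------------------------------------
    def forward(self, x: np.ndarray | Tensor) -> Tensor:
        """Batch forward: ``(B, N_c, N_s)`` (or a single trial) -> ``(B, N_f)``."""
        x = nn._wrap(x)
        single = x.data.ndim == 2
        if single:
            x = x.reshape(1, *x.shape)
        c, p = self.cfg, self.params
        B = x.shape[0]
        self.attention_weights = []

        # 1. spatial filtering: affine across channels at each time point
        h = x.transpose(0, 2, 1) @ p["fc_w"] + p["fc_b"]
        h = h.tanh().transpose(0, 2, 1)                      # (B, N_sp, N_s)

        # 2. frequency filtering + batch norm over (batch, space, time)
        h = nn.conv1d_same(h, p["conv_k"], p["conv_b"])      # (B, N_fr, N_sp, N_s)
        h = h.elu()
        h = self._batch_norm(h)

        # 3. tokens: one per time point, embedding dim N_fr * N_sp
        h = h.reshape(B, c.d_model, c.n_samples).transpose(0, 2, 1)  # (B, N_s, d)
        if c.use_encoder:
            h = h + Tensor(self.pe)
            for layer in range(c.n_layers):
                h = self._encoder_layer(h, layer)

        # 4. flatten the full sequence and classify
        h = h.reshape(B, c.d_model * c.n_samples)
        logits = h @ p["head_w"] + p["head_b"]
        return logits.reshape(c.n_classes) if single else logits

    __call__ = forward

    def _batch_norm(self, h: Tensor) -> Tensor:
        gamma = self.params["bn_gamma"].reshape(1, -1, 1, 1)
        beta = self.params["bn_beta"].reshape(1, -1, 1, 1)
        if self.training:
            mu = h.mean(axis=(0, 2, 3), keepdims=True)
            d = h - mu
            var = (d * d).mean(axis=(0, 2, 3), keepdims=True)
            self.bn_mean = ((1 - self.bn_momentum) * self.bn_mean
                            + self.bn_momentum * mu.data.ravel())
            self.bn_var = ((1 - self.bn_momentum) * self.bn_var
                           + self.bn_momentum * var.data.ravel())
            return d * (var + 1e-5) ** -0.5 * gamma + beta
        mu = Tensor(self.bn_mean.reshape(1, -1, 1, 1))
        var = Tensor(self.bn_var.reshape(1, -1, 1, 1))
        return (h - mu) * (var + 1e-5) ** -0.5 * gamma + beta

    def _dropout(self, h: Tensor) -> Tensor:
        rate = self.cfg.dropout
        if not self.training or rate <= 0:
            return h
        mask = (self._rng.random(h.shape) >= rate) / (1.0 - rate)
        return h * Tensor(mask)

    def _encoder_layer(self, h: Tensor, layer: int) -> Tensor:
        p, c = self.params, self.cfg
        attn, w = multihead_attention(
            h, c.n_heads,
            p[f"enc{layer}_wq"], p[f"enc{layer}_wk"],
            p[f"enc{layer}_wv"], p[f"enc{layer}_wo"],
            return_weights=True,
        )
        if self.collect_attention:
            self.attention_weights.append(w.data.copy())
        h = _layer_norm(h + self._dropout(attn),
                        p[f"enc{layer}_ln1_g"], p[f"enc{layer}_ln1_b"])
        ff = (h @ p[f"enc{layer}_ff1_w"] + p[f"enc{layer}_ff1_b"]) \
            .leaky_relu(c.leaky_slope)
        ff = ff @ p[f"enc{layer}_ff2_w"] + p[f"enc{layer}_ff2_b"]
        return _layer_norm(h + self._dropout(ff),
                           p[f"enc{layer}_ln2_g"], p[f"enc{layer}_ln2_b"])

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Class labels for a batch, in evaluation mode."""
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            X = X[None]
        was_training = self.training
        self.eval()
        out = self.forward(X).data.argmax(axis=-1)
        self.training = was_training
        return out


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(model: AETFModel, path) -> None:
    """HDF5 checkpoint: the config as a JSON attribute, one dataset per array."""
    with h5py.File(path, "w") as f:
        f.attrs["config"] = json.dumps(asdict(model.cfg))
        for k, v in model.state_dict().items():
            f.create_dataset(k, data=v)


def load_checkpoint(path) -> AETFModel:
    with h5py.File(path, "r") as f:
        cfg = AETFConfig(**json.loads(f.attrs["config"]))
        state = {k: f[k][()] for k in f.keys()}
    model = AETFModel(cfg, seed=0)
    model.load_state_dict(state)
    return model
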