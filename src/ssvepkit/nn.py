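"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Float64 tensors, dynamic graph, exactly the primitives the decoder needs:
broadcasted arithmetic, (batched) matmul, reshape/transpose, tanh / ELU /
leaky-ReLU, exp/log/pow, axis sums, softmax / log-softmax, row gathering for
cross-entropy, and a 'same'-padded 1-D convolution along the last axis.
Gradient correctness is pinned by finite-difference tests.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Parameter", "conv1d_same", "softmax", "log_softmax",
           "gather_rows", "Adam"]


class Tensor:
    """A node in the autodiff graph wrapping a float64 ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad=False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=float)
        self.grad = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    # -- graph machinery ----------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(node):
            if id(node) in seen or not node.requires_grad:
                return
            seen.add(id(node))
            for p in node._parents:
                visit(p)
            topo.append(node)

        visit(self)
        for node in topo:
            node.grad = None
        self.grad = np.asarray(grad, dtype=float)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, grad):
        self.grad = grad if self.grad is None else self.grad + grad

    @property
    def shape(self):
        return self.data.shape

    @property
    def size(self):
        return self.data.size

    def detach(self):
        return Tensor(self.data)

    def item(self):
        return float(self.data)

    # -- arithmetic ---------------------------------------------------------
    def __add__(self, other):
        other = _wrap(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def bwd(g):
            self._accum(_unbroadcast(g, self.data.shape))
            other._accum(_unbroadcast(g, other.data.shape))
        out._backward = bwd if out.requires_grad else None
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))
        out._backward = (lambda g: self._accum(-g)) if out.requires_grad else None
        return out

    def __sub__(self, other):
        return self + (-_wrap(other))

    def __rsub__(self, other):
        return _wrap(other) + (-self)

    def __mul__(self, other):
        other = _wrap(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def bwd(g):
            self._accum(_unbroadcast(g * other.data, self.data.shape))
            other._accum(_unbroadcast(g * self.data, other.data.shape))
        out._backward = bwd if out.requires_grad else None
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self * _wrap(other) ** -1.0

    def __rtruediv__(self, other):
        return _wrap(other) * self ** -1.0

    def __pow__(self, p: float):
        out = Tensor(self.data ** p, parents=(self,))

        def bwd(g):
            self._accum(g * p * self.data ** (p - 1))
        out._backward = bwd if out.requires_grad else None
        return out

    def __matmul__(self, other):
        other = _wrap(other)
        out = Tensor(self.data @ other.data, parents=(self, other))

        def bwd(g):
            a, b = self.data, other.data
            ga = g @ np.swapaxes(b, -1, -2)
            gb = np.swapaxes(a, -1, -2) @ g
            self._accum(_unbroadcast(ga, a.shape))
            other._accum(_unbroadcast(gb, b.shape))
        out._backward = bwd if out.requires_grad else None
        return out

    # -- shape ops ----------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape
        out = Tensor(self.data.reshape(shape), parents=(self,))
        out._backward = (lambda g: self._accum(g.reshape(old))) if out.requires_grad else None
        return out

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(axes), parents=(self,))
        out._backward = (lambda g: self._accum(g.transpose(inv))) if out.requires_grad else None
        return out

    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))

        def bwd(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape).copy())
        out._backward = bwd if out.requires_grad else None
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else (
            np.prod([self.data.shape[a] for a in np.atleast_1d(axis)]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -- nonlinearities -----------------------------------------------------
    def tanh(self):
        y = np.tanh(self.data)
        out = Tensor(y, parents=(self,))
        out._backward = (lambda g: self._accum(g * (1 - y * y))) if out.requires_grad else None
        return out

    def elu(self, alpha: float = 1.0):
        x = self.data
        y = np.where(x > 0, x, alpha * np.expm1(x))
        out = Tensor(y, parents=(self,))

        def bwd(g):
            self._accum(g * np.where(x > 0, 1.0, y + alpha))
        out._backward = bwd if out.requires_grad else None
        return out

    def leaky_relu(self, slope: float = 0.01):
        x = self.data
        out = Tensor(np.where(x > 0, x, slope * x), parents=(self,))

        def bwd(g):
            self._accum(g * np.where(x > 0, 1.0, slope))
        out._backward = bwd if out.requires_grad else None
        return out

    def exp(self):
        y = np.exp(self.data)
        out = Tensor(y, parents=(self,))
        out._backward = (lambda g: self._accum(g * y)) if out.requires_grad else None
        return out

    def log(self):
        out = Tensor(np.log(self.data), parents=(self,))
        out._backward = (lambda g: self._accum(g / self.data)) if out.requires_grad else None
        return out


class Parameter(Tensor):
    """A leaf tensor that the optimiser updates."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum a broadcasted gradient back down to ``shape``."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for i, s in enumerate(shape):
        if s == 1 and grad.shape[i] != 1:
            grad = grad.sum(axis=i, keepdims=True)
    return grad


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    y = e / e.sum(axis=axis, keepdims=True)
    out = Tensor(y, parents=(x,))

    def bwd(g):
        x._accum((g - (g * y).sum(axis=axis, keepdims=True)) * y)
    out._backward = bwd if out.requires_grad else None
    return out


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    ls = z - np.log(np.exp(z).sum(axis=axis, keepdims=True))
    out = Tensor(ls, parents=(x,))

    def bwd(g):
        x._accum(g - np.exp(ls) * g.sum(axis=axis, keepdims=True))
    out._backward = bwd if out.requires_grad else None
    return out


def gather_rows(x: Tensor, idx: np.ndarray) -> Tensor:
    """``out[i] = x[i, idx[i]]`` for a 2-D tensor; backward scatter-adds."""
    idx = np.asarray(idx, dtype=int)
    rows = np.arange(x.data.shape[0])
    out = Tensor(x.data[rows, idx], parents=(x,))

    def bwd(g):
        gx = np.zeros_like(x.data)
        np.add.at(gx, (rows, idx), g)
        x._accum(gx)
    out._backward = bwd if out.requires_grad else None
    return out


def conv1d_same(x: Tensor, kernels: Tensor, bias: Tensor) -> Tensor:
    """'Same'-padded correlation along the last axis.

    ``x``: (B, C, S); ``kernels``: (F, L); ``bias``: (F,) ->
    output (B, F, C, S).  Every row of every input map is correlated with
    each of the F kernels.  For even L the zero padding is asymmetric with
    the extra zero on the right.
    """
    B, C, S = x.data.shape
    F, L = kernels.data.shape
    pl = (L - 1) // 2
    pr = L - 1 - pl
    xp = np.pad(x.data, ((0, 0), (0, 0), (pl, pr)))
    win = np.lib.stride_tricks.sliding_window_view(xp, L, axis=-1)  # (B,C,S,L)
    out_data = np.einsum("bcsl,fl->bfcs", win, kernels.data) + \
        bias.data[None, :, None, None]
    out = Tensor(out_data, parents=(x, kernels, bias))

    def bwd(g):
        kernels._accum(np.einsum("bcsl,bfcs->fl", win, g))
        bias._accum(g.sum(axis=(0, 2, 3)))
        gxp = np.zeros_like(xp)
        for l in range(L):
            gxp[:, :, l:l + S] += np.einsum("bfcs,f->bcs", g, kernels.data[:, l])
        x._accum(gxp[:, :, pl:pl + S])
    out._backward = bwd if out.requires_grad else None
    return out


class Adam:
    """Standard Adam with decoupled L2 via ``weight_decay`` added to gradients."""

    def __init__(self, params: list[Parameter], lr=1e-3, betas=(0.9, 0.999),
                 eps=1e-8, weight_decay=0.0):
        self.params = list(params)
        self.lr, self.betas, self.eps, self.weight_decay = lr, betas, eps, weight_decay
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad + self.weight_decay * p.data
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
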