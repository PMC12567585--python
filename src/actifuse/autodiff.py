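"""Minimal reverse-mode automatic differentiation on numpy arrays.

Implements exactly the tensor operations the multimodal network needs
(broadcast-aware arithmetic, batched matmul, reductions, reshapes, indexing,
softmax / log-softmax, elementwise nonlinearities). Gradients are accumulated
by a topological sweep over the recorded tape. Every primitive's vector-
Jacobian product is checked against central finite differences in the test
suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "stack", "no_grad", "set_default_dtype", "get_default_dtype"]

_grad_enabled = True
_DTYPE = np.float32


def set_default_dtype(dtype):
    """Set the engine's floating dtype (float32 default; float64 for
    high-precision derivative checks)."""
    global _DTYPE
    if np.dtype(dtype) not in (np.dtype(np.float32), np.dtype(np.float64)):
        raise ValueError("dtype must be float32 or float64")
    _DTYPE = np.dtype(dtype).type


def get_default_dtype():
    return _DTYPE


class no_grad:
    """Context manager disabling tape recording (eval-mode forward passes)."""

    def __enter__(self):
        global _grad_enabled
        self._prev = _grad_enabled
        _grad_enabled = False
        return self

    def __exit__(self, *exc):
        global _grad_enabled
        _grad_enabled = self._prev
        return False


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


def _as_tensor(x) -> "Tensor":
    return x if isinstance(x, Tensor) else Tensor(x)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_vjps")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=_DTYPE)
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._vjps = []  # list of (parent Tensor, fn(grad_out) -> grad_parent)

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    @staticmethod
    def _make(data, vjps):
        vjps = [(p, fn) for p, fn in vjps if p.requires_grad]
        out = Tensor(data, requires_grad=bool(vjps) and _grad_enabled)
        if out.requires_grad:
            out._vjps = vjps
        return out

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        # topological order over the tape
        topo, seen = [], set()
        stack_ = [(self, False)]
        while stack_:
            node, processed = stack_.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack_.append((node, True))
            for parent, _ in node._vjps:
                if id(parent) not in seen:
                    stack_.append((parent, False))
        grads = {id(self): np.asarray(grad, dtype=self.data.dtype)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if not node._vjps:  # leaf
                node.grad = g if node.grad is None else node.grad + g
                continue
            for parent, fn in node._vjps:
                pg = fn(g)
                if id(parent) in grads:
                    grads[id(parent)] = grads[id(parent)] + pg
                else:
                    grads[id(parent)] = pg

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        a, b = self, _as_tensor(other)
        return Tensor._make(
            a.data + b.data,
            [(a, lambda g: _unbroadcast(g, a.data.shape)),
             (b, lambda g: _unbroadcast(g, b.data.shape))],
        )

    __radd__ = __add__

    def __neg__(self):
        return Tensor._make(-self.data, [(self, lambda g: -g)])

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __mul__(self, other):
        a, b = self, _as_tensor(other)
        return Tensor._make(
            a.data * b.data,
            [(a, lambda g: _unbroadcast(g * b.data, a.data.shape)),
             (b, lambda g: _unbroadcast(g * a.data, b.data.shape))],
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        a, b = self, _as_tensor(other)
        return Tensor._make(
            a.data / b.data,
            [(a, lambda g: _unbroadcast(g / b.data, a.data.shape)),
             (b, lambda g: _unbroadcast(-g * a.data / (b.data ** 2), b.data.shape))],
        )

    def __rtruediv__(self, other):
        return _as_tensor(other) / self

    def __pow__(self, p: float):
        if p == 0:
            return Tensor._make(np.ones_like(self.data), [(self, lambda g: np.zeros_like(self.data))])
        return Tensor._make(
            self.data ** p,
            [(self, lambda g: g * p * self.data ** (p - 1))],
        )

    def __matmul__(self, other):
        a, b = self, _as_tensor(other)
        return Tensor._make(
            a.data @ b.data,
            [(a, lambda g: _unbroadcast(g @ np.swapaxes(b.data, -1, -2), a.data.shape)),
             (b, lambda g: _unbroadcast(np.swapaxes(a.data, -1, -2) @ g, b.data.shape))],
        )

    # -------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims=False):
        out = self.data.sum(axis=axis, keepdims=keepdims)

        def vjp(g):
            if axis is None:
                return np.broadcast_to(g, self.data.shape).copy()
            if not keepdims:
                g = np.expand_dims(g, axis)
            return np.broadcast_to(g, self.data.shape).copy()

        return Tensor._make(out, [(self, vjp)])

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[ax] for ax in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # ------------------------------------------------------------ shape moves
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape
        return Tensor._make(self.data.reshape(shape), [(self, lambda g: g.reshape(old))])

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        return Tensor._make(self.data.transpose(axes), [(self, lambda g: g.transpose(inv))])

    def __getitem__(self, idx):
        def vjp(g):
            out = np.zeros_like(self.data)
            np.add.at(out, idx, g)
            return out

        return Tensor._make(self.data[idx], [(self, vjp)])

    # --------------------------------------------------------- nonlinearities
    def exp(self):
        out = np.exp(self.data)
        return Tensor._make(out, [(self, lambda g: g * out)])

    def log(self):
        return Tensor._make(np.log(self.data), [(self, lambda g: g / self.data)])

    def sqrt(self):
        return self ** 0.5

    def tanh(self):
        out = np.tanh(self.data)
        return Tensor._make(out, [(self, lambda g: g * (1.0 - out ** 2))])

    def sigmoid(self):
        out = 1.0 / (1.0 + np.exp(-self.data))
        return Tensor._make(out, [(self, lambda g: g * out * (1.0 - out))])

    def relu(self):
        mask = self.data > 0
        return Tensor._make(self.data * mask, [(self, lambda g: g * mask)])

    def gelu(self):
        # tanh approximation, with its exact analytic derivative
        c = float(np.sqrt(2.0 / np.pi))
        x = self.data
        u = c * (x + 0.044715 * x ** 3)
        t = np.tanh(u)
        out = 0.5 * x * (1.0 + t)

        def vjp(g):
            du = c * (1.0 + 3 * 0.044715 * x ** 2)
            return g * (0.5 * (1.0 + t) + 0.5 * x * (1.0 - t ** 2) * du)

        return Tensor._make(out, [(self, vjp)])

    def clip(self, lo: float, hi: float):
        mask = (self.data > lo) & (self.data < hi)
        return Tensor._make(np.clip(self.data, lo, hi), [(self, lambda g: g * mask)])

    def softmax(self, axis=-1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        s = e / e.sum(axis=axis, keepdims=True)

        def vjp(g):
            return s * (g - (g * s).sum(axis=axis, keepdims=True))

        return Tensor._make(s, [(self, vjp)])

    def log_softmax(self, axis=-1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        ls = z - np.log(np.exp(z).sum(axis=axis, keepdims=True))

        def vjp(g):
            return g - np.exp(ls) * g.sum(axis=axis, keepdims=True)

        return Tensor._make(ls, [(self, vjp)])


def layernorm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Fused layer normalisation over the last axis (one tape node)."""
    mu = x.data.mean(axis=-1, keepdims=True)
    xc = x.data - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    out = gamma.data * xhat + beta.data

    def vjp_x(g):
        gh = g * gamma.data
        return inv * (gh - gh.mean(axis=-1, keepdims=True)
                      - xhat * (gh * xhat).mean(axis=-1, keepdims=True))

    def vjp_gamma(g):
        return _unbroadcast(g * xhat, gamma.data.shape)

    def vjp_beta(g):
        return _unbroadcast(g, beta.data.shape)

    return Tensor._make(out, [(x, vjp_x), (gamma, vjp_gamma), (beta, vjp_beta)])


def concat(tensors, axis=0):
    tensors = [_as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)
    data = np.concatenate([t.data for t in tensors], axis=axis)

    def make_vjp(i):
        def vjp(g):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(offsets[i], offsets[i + 1])
            return g[tuple(sl)]

        return vjp

    return Tensor._make(data, [(t, make_vjp(i)) for i, t in enumerate(tensors)])


def stack(tensors, axis=0):
    tensors = [_as_tensor(t) for t in tensors]
    data = np.stack([t.data for t in tensors], axis=axis)

    def make_vjp(i):
        def vjp(g):
            return np.take(g, i, axis=axis)

        return vjp

    return Tensor._make(data, [(t, make_vjp(i)) for i, t in enumerate(tensors)])
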