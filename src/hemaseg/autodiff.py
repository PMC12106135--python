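"""Minimal reverse-mode automatic differentiation on numpy arrays.

Supports exactly the operations the segmentation model and its losses need:
broadcasting arithmetic, matmul (incl. batched), reductions, elementwise
nonlinearities, reshaping/transposition, concatenation, basic indexing and
nearest-neighbour upsampling.  Everything is float64; gradients accumulate
into ``Tensor.grad`` after calling :meth:`Tensor.backward` on a scalar.

The engine is deliberately tiny: no views, no in-place ops, no dtype zoo.
Determinism is exact — the same inputs produce bit-identical outputs.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Parameter", "Buffer", "concat", "softmax",
           "layer_norm", "gelu_tanh", "AdamW"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents = _parents
        self._backward = _backward

    # -- plumbing ---------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.grad is not None})"

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def _accum(self, g: np.ndarray) -> None:
        self.grad = g if self.grad is None else self.grad + g

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other):
        other = self._wrap(other)
        out_data = self.data + other.data

        def back(g):
            self._accum(_unbroadcast(g, self.data.shape))
            other._accum(_unbroadcast(g, other.data.shape))

        return Tensor(out_data, _parents=(self, other), _backward=back)

    __radd__ = __add__

    def __mul__(self, other):
        other = self._wrap(other)
        out_data = self.data * other.data

        def back(g):
            self._accum(_unbroadcast(g * other.data, self.data.shape))
            other._accum(_unbroadcast(g * self.data, other.data.shape))

        return Tensor(out_data, _parents=(self, other), _backward=back)

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __truediv__(self, other):
        return self * self._wrap(other) ** (-1.0)

    def __rtruediv__(self, other):
        return self._wrap(other) * self ** (-1.0)

    def __pow__(self, exponent: float):
        e = float(exponent)
        out_data = self.data**e

        def back(g):
            self._accum(g * e * self.data ** (e - 1.0))

        return Tensor(out_data, _parents=(self,), _backward=back)

    def __matmul__(self, other):
        other = self._wrap(other)
        out_data = self.data @ other.data

        def back(g):
            ga = g @ np.swapaxes(other.data, -1, -2)
            gb = np.swapaxes(self.data, -1, -2) @ g
            self._accum(_unbroadcast(ga, self.data.shape))
            other._accum(_unbroadcast(gb, other.data.shape))

        return Tensor(out_data, _parents=(self, other), _backward=back)

    # -- nonlinearities ---------------------------------------------------
    def relu(self):
        mask = self.data > 0
        out_data = self.data * mask

        def back(g):
            self._accum(g * mask)

        return Tensor(out_data, _parents=(self,), _backward=back)

    def sigmoid(self):
        out_data = 0.5 * (1.0 + np.tanh(0.5 * self.data))  # stable logistic

        def back(g):
            self._accum(g * out_data * (1.0 - out_data))

        return Tensor(out_data, _parents=(self,), _backward=back)

    def tanh(self):
        out_data = np.tanh(self.data)

        def back(g):
            self._accum(g * (1.0 - out_data**2))

        return Tensor(out_data, _parents=(self,), _backward=back)

    def exp(self):
        out_data = np.exp(self.data)

        def back(g):
            self._accum(g * out_data)

        return Tensor(out_data, _parents=(self,), _backward=back)

    def log(self):
        out_data = np.log(self.data)

        def back(g):
            self._accum(g / self.data)

        return Tensor(out_data, _parents=(self,), _backward=back)

    def clamp(self, lo: float, hi: float):
        out_data = np.clip(self.data, lo, hi)
        inside = (self.data > lo) & (self.data < hi)

        def back(g):
            self._accum(g * inside)

        return Tensor(out_data, _parents=(self,), _backward=back)

    # -- reductions -------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def back(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape).copy())

        return Tensor(out_data, _parents=(self,), _backward=back)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- shape ops --------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape
        out_data = self.data.reshape(shape)

        def back(g):
            self._accum(g.reshape(old))

        return Tensor(out_data, _parents=(self,), _backward=back)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inverse = np.argsort(axes)
        out_data = self.data.transpose(axes)

        def back(g):
            self._accum(g.transpose(inverse))

        return Tensor(out_data, _parents=(self,), _backward=back)

    def __getitem__(self, idx):
        out_data = self.data[idx]

        def back(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accum(full)

        return Tensor(out_data, _parents=(self,), _backward=back)

    def upsample2d(self, factor: int):
        """Nearest-neighbour upsampling of the two leading axes of (H, W[, C])."""
        k = int(factor)
        out_data = np.repeat(np.repeat(self.data, k, axis=0), k, axis=1)
        h, w = self.data.shape[:2]
        rest = self.data.shape[2:]

        def back(g):
            g = g.reshape((h, k, w, k) + rest)
            self._accum(g.sum(axis=(1, 3)))

        return Tensor(out_data, _parents=(self,), _backward=back)

    # -- backward ---------------------------------------------------------
    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


class Parameter(Tensor):
    """Trainable tensor; ``requires_grad`` may be toggled by freeze policies."""

    __slots__ = ()

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Buffer(Tensor):
    """Persistent non-trainable state (saved in checkpoints, never optimised)."""

    __slots__ = ()

    def __init__(self, data):
        super().__init__(data, requires_grad=False)


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [Tensor._wrap(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def back(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            t._accum(g[tuple(sl)])

    return Tensor(out_data, _parents=tuple(tensors), _backward=back)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Fused softmax (numerically shifted) with the standard Jacobian-vector
    backward ``s · (g − Σ g·s)``."""
    shifted = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    out_data = e / e.sum(axis=axis, keepdims=True)

    def back(g):
        x._accum(out_data * (g - (g * out_data).sum(axis=axis, keepdims=True)))

    return Tensor(out_data, _parents=(x,), _backward=back)


def layer_norm(x: Tensor, weight: Tensor, bias: Tensor, eps: float = 1e-6) -> Tensor:
    """Fused last-axis layer normalisation ``w · (x−μ)/σ + b``."""
    mu = x.data.mean(axis=-1, keepdims=True)
    var = x.data.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    out_data = weight.data * xhat + bias.data
    d = x.data.shape[-1]

    def back(g):
        reduce_axes = tuple(range(g.ndim - 1))
        weight._accum((g * xhat).sum(axis=reduce_axes).reshape(weight.data.shape))
        bias._accum(g.sum(axis=reduce_axes).reshape(bias.data.shape))
        gx = g * weight.data
        x._accum(inv * (gx - gx.mean(axis=-1, keepdims=True)
                        - xhat * (gx * xhat).mean(axis=-1, keepdims=True)))

    return Tensor(out_data, _parents=(x, weight, bias), _backward=back)


_GELU_C = 0.7978845608028654  # sqrt(2/pi)


def gelu_tanh(x: Tensor) -> Tensor:
    """Fused tanh-approximate GELU."""
    u = _GELU_C * (x.data + 0.044715 * x.data**3)
    t = np.tanh(u)
    out_data = 0.5 * x.data * (1.0 + t)

    def back(g):
        du = _GELU_C * (1.0 + 3 * 0.044715 * x.data**2)
        x._accum(g * (0.5 * (1.0 + t) + 0.5 * x.data * (1.0 - t**2) * du))

    return Tensor(out_data, _parents=(x,), _backward=back)


class AdamW:
    """Decoupled-weight-decay Adam over the trainable parameters of a module.

    Frozen parameters (``requires_grad == False``) are skipped entirely, so a
    freeze policy guarantees them bit-identical across steps.
    """

    def __init__(self, params, lr: float = 5e-5, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.1):
        self.params = list(params)
        self.lr = float(lr)
        self.beta1, self.beta2 = betas
        self.eps = float(eps)
        self.weight_decay = float(weight_decay)
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if not p.requires_grad or p.grad is None:
                continue
            g = p.grad
            self._m[i] = b1 * self._m[i] + (1 - b1) * g
            self._v[i] = b2 * self._v[i] + (1 - b2) * g * g
            m_hat = self._m[i] / (1 - b1**self.t)
            v_hat = self._v[i] / (1 - b2**self.t)
            p.data = p.data - self.lr * (
                m_hat / (np.sqrt(v_hat) + self.eps) + self.weight_decay * p.data
            )
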