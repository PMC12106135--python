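"""Neural-network building blocks on top of :mod:`hemaseg.autodiff`.

Module tree with recursive parameter discovery, plus the layers needed for a
ViT encoder with bottleneck adapters and a two-way mask decoder.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Buffer, Parameter, Tensor, gelu_tanh, layer_norm, softmax

__all__ = [
    "Module", "ModuleList", "Linear", "LayerNorm", "Mlp",
    "MultiHeadAttention", "CrossAttention", "Adapter", "gelu",
]


class Module:
    """Base class; children and parameters are discovered from attributes."""

    def named_parameters(self, prefix: str = "", buffers: bool = False):
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, Buffer):
                if buffers:
                    yield full, value
            elif isinstance(value, Parameter):
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_parameters(f"{full}.", buffers=buffers)
            elif isinstance(value, ModuleList):
                for i, sub in enumerate(value):
                    yield from sub.named_parameters(f"{full}.{i}.", buffers=buffers)

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def state_dict(self) -> dict:
        return {name: t.data.copy() for name, t in self.named_parameters(buffers=True)}

    def load_state_dict(self, state: dict) -> None:
        own = dict(self.named_parameters(buffers=True))
        missing = sorted(set(own) - set(state))
        extra = sorted(set(state) - set(own))
        if missing or extra:
            raise ValueError(f"state mismatch; missing={missing}, unexpected={extra}")
        for name, tensor in own.items():
            arr = np.asarray(state[name], dtype=np.float64)
            if arr.shape != tensor.data.shape:
                raise ValueError(f"shape mismatch for {name}: {arr.shape} vs {tensor.data.shape}")
            tensor.data = arr.copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class ModuleList(list):
    pass


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator,
                 bias: bool = True, scale: float | None = None, zero_init: bool = False):
        if zero_init:
            w = np.zeros((in_features, out_features))
        else:
            s = scale if scale is not None else 1.0 / np.sqrt(in_features)
            w = rng.normal(0.0, s, size=(in_features, out_features))
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(out_features)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-6):
        self.weight = Parameter(np.ones(dim))
        self.bias = Parameter(np.zeros(dim))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        return layer_norm(x, self.weight, self.bias, self.eps)


def gelu(x: Tensor) -> Tensor:
    """tanh-approximate GELU (fused primitive)."""
    return gelu_tanh(x)


class Mlp(Module):
    def __init__(self, dim: int, hidden: int, rng: np.random.Generator,
                 out_scale: float = 1.0):
        self.fc1 = Linear(dim, hidden, rng)
        self.fc2 = Linear(hidden, dim, rng, scale=out_scale / np.sqrt(hidden))

    def forward(self, x: Tensor) -> Tensor:
        return self.fc2(gelu(self.fc1(x)))


def _split_heads(x: Tensor, heads: int) -> Tensor:
    b, n, d = x.shape
    dh = d // heads
    return x.reshape(b, n, heads, dh).transpose(0, 2, 1, 3)


def _merge_heads(x: Tensor) -> Tensor:
    b, h, n, dh = x.shape
    return x.transpose(0, 2, 1, 3).reshape(b, n, h * dh)


class MultiHeadAttention(Module):
    """Self-attention on (B, N, d) token stacks."""

    def __init__(self, dim: int, heads: int, rng: np.random.Generator,
                 out_scale: float = 1.0):
        if dim % heads:
            raise ValueError(f"dim {dim} not divisible by heads {heads}")
        self.heads = heads
        self.scale = (dim // heads) ** -0.5
        self.qkv = Linear(dim, 3 * dim, rng)
        self.proj = Linear(dim, dim, rng, scale=out_scale / np.sqrt(dim))

    def forward(self, x: Tensor) -> Tensor:
        b, n, d = x.shape
        qkv = self.qkv(x)
        q = _split_heads(qkv[:, :, :d], self.heads)
        k = _split_heads(qkv[:, :, d:2 * d], self.heads)
        v = _split_heads(qkv[:, :, 2 * d:], self.heads)
        attn = softmax((q @ k.transpose(0, 1, 3, 2)) * self.scale, axis=-1)
        return self.proj(_merge_heads(attn @ v))


class CrossAttention(Module):
    """Queries from one token stack attend to keys/values from another."""

    def __init__(self, dim: int, heads: int, rng: np.random.Generator):
        if dim % heads:
            raise ValueError(f"dim {dim} not divisible by heads {heads}")
        self.heads = heads
        self.scale = (dim // heads) ** -0.5
        self.q_proj = Linear(dim, dim, rng)
        self.k_proj = Linear(dim, dim, rng)
        self.v_proj = Linear(dim, dim, rng)
        self.out_proj = Linear(dim, dim, rng)

    def forward(self, queries: Tensor, keys_values: Tensor) -> Tensor:
        q = _split_heads(self.q_proj(queries), self.heads)
        k = _split_heads(self.k_proj(keys_values), self.heads)
        v = _split_heads(self.v_proj(keys_values), self.heads)
        attn = softmax((q @ k.transpose(0, 1, 3, 2)) * self.scale, axis=-1)
        return self.out_proj(_merge_heads(attn @ v))


class Adapter(Module):
    """Bottleneck adapter: ``W_up · ReLU(W_down · x + b_down) + b_up + x``.

    ``W_up`` is zero-initialised so a freshly inserted adapter is exactly the
    identity map; ``W_down`` gets a small random init.
    """

    def __init__(self, dim: int, bottleneck: int, rng: np.random.Generator,
                 include_bias: bool = True):
        if not 0 < bottleneck <= dim:
            raise ValueError(f"bottleneck m={bottleneck} must satisfy 0 < m <= d={dim}")
        self.down = Linear(dim, bottleneck, rng, bias=include_bias, scale=0.02)
        self.up = Linear(bottleneck, dim, rng, bias=include_bias, zero_init=True)

    def forward(self, x: Tensor) -> Tensor:
        return self.up(self.down(x).relu()) + x
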