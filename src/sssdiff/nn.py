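"""Minimal neural-network layers on numpy with hand-written reverse-mode gradients.

Every layer caches what its backward pass needs during ``forward`` and releases
it in ``backward``; a layer instance therefore supports exactly one in-flight
forward/backward pair (fine for the batch-at-a-time training loop used here).
Arrays are NCHW ``float32`` by default; tests switch to ``float64`` for
finite-difference gradient checks.
"""

from __future__ import annotations

import math

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Parameter",
    "Module",
    "ModuleList",
    "Conv2d",
    "Linear",
    "GroupNorm",
    "SiLU",
    "SelfAttention2d",
    "silu",
    "silu_grad",
]


class Parameter:
    """A trainable array together with its accumulated gradient."""

    __slots__ = ("data", "grad", "name")

    def __init__(self, data: np.ndarray, name: str = "") -> None:
        self.data = np.ascontiguousarray(data)
        self.grad = np.zeros_like(self.data)
        self.name = name

    @property
    def shape(self):
        return self.data.shape


class Module:
    """Base class: tracks parameters and child modules for traversal."""

    def __init__(self) -> None:
        self._params: dict[str, Parameter] = {}
        self._children: dict[str, Module] = {}

    def __setattr__(self, key, value):
        if isinstance(value, Parameter):
            self.__dict__.setdefault("_params", {})[key] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_children", {})[key] = value
        object.__setattr__(self, key, value)

    def parameters(self) -> list[Parameter]:
        out = list(self._params.values())
        for child in self._children.values():
            out.extend(child.parameters())
        return out

    def named_parameters(self, prefix: str = "") -> list[tuple[str, Parameter]]:
        out = [(prefix + k, p) for k, p in self._params.items()]
        for name, child in self._children.items():
            out.extend(child.named_parameters(prefix + name + "."))
        return out

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0.0

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())


class ModuleList(Module):
    """A registered, indexable sequence of child modules."""

    def __init__(self, mods=()) -> None:
        super().__init__()
        self._items: list[Module] = []
        for m in mods:
            self.append(m)

    def append(self, mod: Module) -> None:
        setattr(self, f"m{len(self._items)}", mod)
        self._items.append(mod)

    def __iter__(self):
        return iter(self._items)

    def __getitem__(self, i):
        return self._items[i]

    def __len__(self):
        return len(self._items)


def silu(x: np.ndarray) -> np.ndarray:
    return x / (1.0 + np.exp(-x))


def silu_grad(x: np.ndarray) -> np.ndarray:
    s = 1.0 / (1.0 + np.exp(-x))
    return s * (1.0 + x * (1.0 - s))


class SiLU(Module):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return silu(x)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx = dy * silu_grad(self._x)
        self._x = None
        return dx


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 dtype=np.float32, zero_init: bool = False) -> None:
        super().__init__()
        if zero_init:
            w = np.zeros((n_out, n_in))
        else:
            # Kaiming-uniform, the DDPM-codebase default for dense layers.
            bound = 1.0 / math.sqrt(n_in)
            w = rng.uniform(-bound, bound, size=(n_out, n_in))
        self.w = Parameter(w.astype(dtype), "w")
        self.b = Parameter(np.zeros(n_out, dtype=dtype), "b")

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.w.data.T + self.b.data

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.w.grad += dy.T @ self._x
        self.b.grad += dy.sum(axis=0)
        dx = dy @ self.w.data
        self._x = None
        return dx


def _im2col(x: np.ndarray, k: int, stride: int, pad: int):
    """(N,C,H,W) -> column matrix (N*Ho*Wo, C*k*k) plus output spatial dims."""
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = sliding_window_view(x, (k, k), axis=(2, 3))[:, :, ::stride, ::stride]
    ho, wo = win.shape[2], win.shape[3]
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5))
    return cols.reshape(n * ho * wo, c * k * k), ho, wo


def _col2im(dcols: np.ndarray, x_shape, k: int, stride: int, pad: int) -> np.ndarray:
    n, c, h, w = x_shape
    hp, wp = h + 2 * pad, w + 2 * pad
    ho = (hp - k) // stride + 1
    wo = (wp - k) // stride + 1
    d6 = dcols.reshape(n, ho, wo, c, k, k).transpose(0, 3, 1, 2, 4, 5)
    dxp = np.zeros((n, c, hp, wp), dtype=dcols.dtype)
    for ki in range(k):
        for kj in range(k):
            dxp[:, :, ki:ki + stride * ho:stride, kj:kj + stride * wo:stride] += d6[..., ki, kj]
    if pad:
        return dxp[:, :, pad:hp - pad, pad:wp - pad]
    return dxp


class Conv2d(Module):
    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator,
                 stride: int = 1, pad: int | None = None, dtype=np.float32,
                 zero_init: bool = False) -> None:
        super().__init__()
        self.c_in, self.c_out, self.k = c_in, c_out, k
        self.stride = stride
        self.pad = k // 2 if pad is None else pad
        fan_in = c_in * k * k
        if zero_init:
            w = np.zeros((c_out, c_in, k, k))
        else:
            bound = 1.0 / math.sqrt(fan_in)
            w = rng.uniform(-bound, bound, size=(c_out, c_in, k, k))
        self.w = Parameter(w.astype(dtype), "w")
        self.b = Parameter(np.zeros(c_out, dtype=dtype), "b")

    def forward(self, x: np.ndarray) -> np.ndarray:
        cols, ho, wo = _im2col(x, self.k, self.stride, self.pad)
        self._cols, self._x_shape = cols, x.shape
        w2 = self.w.data.reshape(self.c_out, -1)
        y = cols @ w2.T + self.b.data
        n = x.shape[0]
        return y.reshape(n, ho, wo, self.c_out).transpose(0, 3, 1, 2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, co, ho, wo = dy.shape
        dy2 = np.ascontiguousarray(dy.transpose(0, 2, 3, 1)).reshape(-1, co)
        self.w.grad += (dy2.T @ self._cols).reshape(self.w.data.shape)
        self.b.grad += dy2.sum(axis=0)
        dcols = dy2 @ self.w.data.reshape(co, -1)
        dx = _col2im(dcols, self._x_shape, self.k, self.stride, self.pad)
        self._cols = None
        return dx


class GroupNorm(Module):
    """Group normalisation with affine scale/shift, eps=1e-5."""

    def __init__(self, channels: int, groups: int = 32, dtype=np.float32) -> None:
        super().__init__()
        while channels % groups:
            groups //= 2
        self.groups = max(groups, 1)
        self.channels = channels
        self.eps = 1e-5
        self.gamma = Parameter(np.ones(channels, dtype=dtype), "gamma")
        self.beta = Parameter(np.zeros(channels, dtype=dtype), "beta")

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        g = self.groups
        xg = x.reshape(n, g, -1)
        mu = xg.mean(axis=2, keepdims=True)
        var = xg.var(axis=2, keepdims=True)
        self._inv = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (xg - mu) * self._inv
        xh = self._xhat.reshape(n, c, h, w)
        self._shape = (n, c, h, w)
        return xh * self.gamma.data[None, :, None, None] + self.beta.data[None, :, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        g = self.groups
        xh = self._xhat.reshape(n, c, h, w)
        self.gamma.grad += (dy * xh).sum(axis=(0, 2, 3))
        self.beta.grad += dy.sum(axis=(0, 2, 3))
        dxh = (dy * self.gamma.data[None, :, None, None]).reshape(n, g, -1)
        xhg = self._xhat
        m = dxh.shape[2]
        term = dxh - dxh.mean(axis=2, keepdims=True) - xhg * (dxh * xhg).sum(axis=2, keepdims=True) / m
        dx = (term * self._inv).reshape(n, c, h, w)
        self._xhat = self._inv = None
        return dx


class SelfAttention2d(Module):
    """Multi-head self-attention over spatial positions with residual output.

    Follows the DDPM attention block: GroupNorm, 1x1 qkv projection, scaled
    dot-product attention per head, zero-initialised 1x1 output projection,
    plus skip.
    """

    def __init__(self, channels: int, heads: int, rng: np.random.Generator,
                 dtype=np.float32) -> None:
        super().__init__()
        if channels % heads:
            raise ValueError(f"channels {channels} not divisible by heads {heads}")
        self.channels, self.heads = channels, heads
        self.norm = GroupNorm(channels, dtype=dtype)
        self.qkv = Conv2d(channels, 3 * channels, 1, rng, dtype=dtype)
        self.proj = Conv2d(channels, channels, 1, rng, dtype=dtype, zero_init=True)

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        nh, dh, ln = self.heads, c // self.heads, h * w
        qkv = self.qkv.forward(self.norm.forward(x))
        qkv = qkv.reshape(n, 3, nh, dh, ln)
        q, k, v = qkv[:, 0], qkv[:, 1], qkv[:, 2]  # (n, nh, dh, L)
        scale = 1.0 / math.sqrt(dh)
        logits = np.einsum("nhdi,nhdj->nhij", q, k) * scale
        logits -= logits.max(axis=-1, keepdims=True)
        att = np.exp(logits)
        att /= att.sum(axis=-1, keepdims=True)
        out = np.einsum("nhij,nhdj->nhdi", att, v)
        self._cache = (q, k, v, att, (n, c, h, w))
        y = self.proj.forward(out.reshape(n, c, h, w))
        return x + y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        q, k, v, att, (n, c, h, w) = self._cache
        nh, dh = self.heads, c // self.heads
        dout = self.proj.backward(dy).reshape(n, nh, dh, h * w)
        datt = np.einsum("nhdi,nhdj->nhij", dout, v)
        dv = np.einsum("nhij,nhdi->nhdj", att, dout)
        dlogits = att * (datt - (datt * att).sum(axis=-1, keepdims=True))
        scale = 1.0 / math.sqrt(dh)
        dq = np.einsum("nhij,nhdj->nhdi", dlogits, k) * scale
        dk = np.einsum("nhij,nhdi->nhdj", dlogits, q) * scale
        dqkv = np.stack([dq, dk, dv], axis=1).reshape(n, 3 * c, h, w)
        dx_inner = self.norm.backward(self.qkv.backward(dqkv))
        self._cache = None
        return dy + dx_inner


def upsample_nearest2(x: np.ndarray) -> np.ndarray:
    return x.repeat(2, axis=2).repeat(2, axis=3)


def upsample_nearest2_grad(dy: np.ndarray) -> np.ndarray:
    n, c, h, w = dy.shape
    return dy.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))
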