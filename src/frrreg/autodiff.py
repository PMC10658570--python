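"""Minimal reverse-mode automatic differentiation on NumPy arrays.

This module provides exactly the differentiable operations the registration
networks need — 3D convolution, 2x max-pooling, nearest-neighbour unpooling,
batch normalization, ReLU, slicing/concatenation and reductions — plus a
``Module`` container and an Adam optimizer.  Volumes are stored channel-first
without a batch axis, i.e. ``(C, D, H, W)``; training always uses batch size 1
so the batch axis would be dead weight.

Gradients are accumulated into ``Tensor.grad`` as plain ndarrays.  Every op
here is checked against central finite differences in the test suite.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Iterable, Sequence

import numpy as np

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable graph construction (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def grad_enabled() -> bool:
    return _GRAD_ENABLED


class Tensor:
    """An ndarray plus the backward closure that produced it."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        if not np.issubdtype(self.data.dtype, np.floating):
            self.data = self.data.astype(np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward: Callable[[np.ndarray], None] | None = None

    # -- graph plumbing ----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def dtype(self):
        return self.data.dtype

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=self.data.dtype, copy=True)
        else:
            self.grad += g

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a seed gradient requires a scalar")
            grad = np.ones_like(self.data)
        # iterative topological sort
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
                if id(p) not in seen:
                    stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- operator sugar ----------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    def __radd__(self, other):
        return add(self, other)

    def __sub__(self, other):
        return add(self, mul(other, -1.0))

    def __rsub__(self, other):
        return add(mul(self, -1.0), other)

    def __mul__(self, other):
        return mul(self, other)

    def __rmul__(self, other):
        return mul(self, other)

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            raise TypeError("tensor/tensor division not supported")
        return mul(self, 1.0 / float(other))

    def __neg__(self):
        return mul(self, -1.0)

    def __getitem__(self, key):
        return getitem(self, key)

    def sum(self):
        return reduce_sum(self)

    def mean(self):
        return reduce_mean(self)

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def as_tensor(x, dtype=None) -> Tensor:
    if isinstance(x, Tensor):
        return x
    arr = np.asarray(x, dtype=dtype)
    return Tensor(arr)


def _make(data: np.ndarray, parents: Sequence[Tensor], backward) -> Tensor:
    out = Tensor(data)
    if _GRAD_ENABLED and any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = tuple(parents)
        out._backward = backward
    return out


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum gradient ``g`` down to ``shape`` (inverse of NumPy broadcasting)."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


# -- elementwise / structural ops ------------------------------------------

def add(a, b) -> Tensor:
    a = a if isinstance(a, Tensor) else Tensor(np.asarray(a, dtype=np.float64))
    b = b if isinstance(b, Tensor) else Tensor(np.asarray(b, dtype=np.float64))
    data = a.data + b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.data.shape))

    return _make(data, (a, b), backward)


def mul(a, b) -> Tensor:
    a = a if isinstance(a, Tensor) else Tensor(np.asarray(a, dtype=np.float64))
    b = b if isinstance(b, Tensor) else Tensor(np.asarray(b, dtype=np.float64))
    data = a.data * b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * a.data, b.data.shape))

    return _make(data, (a, b), backward)


def square(a: Tensor) -> Tensor:
    return mul(a, a)


def relu(a: Tensor) -> Tensor:
    mask = a.data > 0
    data = np.where(mask, a.data, 0.0)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * mask)

    return _make(data, (a,), backward)


def getitem(a: Tensor, key) -> Tensor:
    data = a.data[key]

    def backward(g):
        if a.requires_grad:
            full = np.zeros_like(a.data)
            np.add.at(full, key, g)
            a._accumulate(full)

    return _make(data, (a,), backward)


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [t if isinstance(t, Tensor) else Tensor(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]

    def backward(g):
        offs = np.cumsum([0] + sizes)
        for t, lo, hi in zip(tensors, offs[:-1], offs[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t._accumulate(g[tuple(idx)])

    return _make(data, tensors, backward)


def reshape(a: Tensor, shape) -> Tensor:
    data = a.data.reshape(shape)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g.reshape(a.data.shape))

    return _make(data, (a,), backward)


def reduce_sum(a: Tensor) -> Tensor:
    data = np.asarray(a.data.sum())

    def backward(g):
        if a.requires_grad:
            a._accumulate(np.broadcast_to(g, a.data.shape).astype(a.data.dtype))

    return _make(data, (a,), backward)


def reduce_mean(a: Tensor) -> Tensor:
    n = a.data.size
    data = np.asarray(a.data.mean())

    def backward(g):
        if a.requires_grad:
            a._accumulate(np.broadcast_to(g / n, a.data.shape).astype(a.data.dtype))

    return _make(data, (a,), backward)


# -- 3D convolution ---------------------------------------------------------

def _conv3d_forward(xd: np.ndarray, wd: np.ndarray, bd: np.ndarray | None) -> np.ndarray:
    """Same-padded conv as a sum of k^3 shifted channel matmuls."""
    C, D, H, W = xd.shape
    O, Cw, k, _, _ = wd.shape
    if Cw != C:
        raise ValueError(f"conv3d channel mismatch: input {C}, weight expects {Cw}")
    p = k // 2
    N = D * H * W
    if k == 1:
        out = (wd.reshape(O, C) @ xd.reshape(C, N)).reshape(O, D, H, W).copy()
    else:
        xp = np.pad(xd, ((0, 0), (p, p), (p, p), (p, p)))
        acc = np.zeros((O, N), dtype=xd.dtype)
        for i in range(k):
            for j in range(k):
                for l in range(k):
                    xs = np.ascontiguousarray(xp[:, i:i + D, j:j + H, l:l + W]).reshape(C, N)
                    acc += wd[:, :, i, j, l] @ xs
        out = acc.reshape(O, D, H, W)
    if bd is not None:
        out += bd[:, None, None, None]
    return out


def conv3d(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Same-padded 3D convolution; ``x`` is ``(C,D,H,W)``, ``w`` is ``(O,C,k,k,k)``."""
    bd = None if b is None else b.data
    data = _conv3d_forward(x.data, w.data, bd)
    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        C, D, H, W = x.data.shape
        O, _, k, _, _ = w.data.shape
        p = k // 2
        N = D * H * W
        need_x = x.requires_grad
        need_w = w.requires_grad
        g2 = np.ascontiguousarray(g).reshape(O, N)
        if k == 1:
            if need_w:
                w._accumulate((g2 @ x.data.reshape(C, N).T).reshape(w.data.shape))
            if need_x:
                x._accumulate((w.data.reshape(O, C).T @ g2).reshape(C, D, H, W))
        else:
            xp = np.pad(x.data, ((0, 0), (p, p), (p, p), (p, p))) if need_w else None
            dxp = (np.zeros((C, D + 2 * p, H + 2 * p, W + 2 * p), dtype=g.dtype)
                   if need_x else None)
            dw = np.zeros_like(w.data) if need_w else None
            for i in range(k):
                for j in range(k):
                    for l in range(k):
                        if need_w:
                            xs = np.ascontiguousarray(
                                xp[:, i:i + D, j:j + H, l:l + W]).reshape(C, N)
                            dw[:, :, i, j, l] = g2 @ xs.T
                        if need_x:
                            dxp[:, i:i + D, j:j + H, l:l + W] += (
                                w.data[:, :, i, j, l].T @ g2).reshape(C, D, H, W)
            if need_w:
                w._accumulate(dw)
            if need_x:
                x._accumulate(dxp[:, p:p + D, p:p + H, p:p + W])
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(1, 2, 3)))

    return _make(data, parents, backward)


# -- pooling / unpooling -----------------------------------------------------

def maxpool2(x: Tensor) -> Tensor:
    """2x2x2 max pooling with stride 2; spatial dims must be even."""
    C, D, H, W = x.data.shape
    if D % 2 or H % 2 or W % 2:
        raise ValueError(f"maxpool2 needs even spatial dims, got {(D, H, W)}")
    xr = (x.data.reshape(C, D // 2, 2, H // 2, 2, W // 2, 2)
          .transpose(0, 1, 3, 5, 2, 4, 6)
          .reshape(C, D // 2, H // 2, W // 2, 8))
    idx = xr.argmax(axis=-1)
    data = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        if not x.requires_grad:
            return
        g8 = np.zeros((C, D // 2, H // 2, W // 2, 8), dtype=g.dtype)
        np.put_along_axis(g8, idx[..., None], g[..., None], axis=-1)
        gx = (g8.reshape(C, D // 2, H // 2, W // 2, 2, 2, 2)
              .transpose(0, 1, 4, 2, 5, 3, 6)
              .reshape(C, D, H, W))
        x._accumulate(gx)

    return _make(data, (x,), backward)


def upsample2(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x unpooling along all three spatial axes."""
    data = x.data.repeat(2, axis=1).repeat(2, axis=2).repeat(2, axis=3)

    def backward(g):
        if not x.requires_grad:
            return
        C, D, H, W = x.data.shape
        gx = g.reshape(C, D, 2, H, 2, W, 2).sum(axis=(2, 4, 6))
        x._accumulate(gx)

    return _make(data, (x,), backward)


# -- modules -----------------------------------------------------------------

class Module:
    """Container of parameters and sub-modules with train/eval state."""

    def __init__(self):
        self.training = True

    def named_parameters(self, prefix: str = "") -> Iterable[tuple[str, Tensor]]:
        for name, val in vars(self).items():
            full = f"{prefix}{name}" if not prefix else f"{prefix}.{name}"
            if isinstance(val, Tensor) and val.requires_grad:
                yield full, val
            elif isinstance(val, Module):
                yield from val.named_parameters(full)
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{i}")

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def modules(self) -> Iterable["Module"]:
        yield self
        for val in vars(self).values():
            if isinstance(val, Module):
                yield from val.modules()
            elif isinstance(val, (list, tuple)):
                for item in val:
                    if isinstance(item, Module):
                        yield from item.modules()

    def train(self):
        for m in self.modules():
            m.training = True
        return self

    def eval(self):
        for m in self.modules():
            m.training = False
        return self

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def state_arrays(self) -> dict[str, np.ndarray]:
        """All parameters plus batch-norm running statistics, by name."""
        out = {name: p.data for name, p in self.named_parameters()}
        for i, m in enumerate(self.modules()):
            if isinstance(m, BatchNorm3d):
                out[f"__bn{i}.running_mean"] = m.running_mean
                out[f"__bn{i}.running_var"] = m.running_var
        return out

    def load_state_arrays(self, arrays: dict[str, np.ndarray]) -> None:
        for name, p in self.named_parameters():
            p.data = np.array(arrays[name], dtype=p.data.dtype)
        for i, m in enumerate(self.modules()):
            if isinstance(m, BatchNorm3d):
                m.running_mean = np.array(arrays[f"__bn{i}.running_mean"])
                m.running_var = np.array(arrays[f"__bn{i}.running_var"])

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Conv3d(Module):
    """Same-padded 3D convolution layer with He or zero initialization."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, dtype=np.float64, zero_init: bool = False):
        super().__init__()
        k = kernel_size
        fan_in = in_channels * k ** 3
        if zero_init:
            w = np.zeros((out_channels, in_channels, k, k, k), dtype=dtype)
        else:
            std = np.sqrt(2.0 / fan_in)
            w = rng.normal(0.0, std, size=(out_channels, in_channels, k, k, k)).astype(dtype)
        self.weight = Tensor(w, requires_grad=True)
        self.bias = Tensor(np.zeros(out_channels, dtype=dtype), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return conv3d(x, self.weight, self.bias)


class BatchNorm3d(Module):
    """Per-channel spatial batch normalization (batch size 1).

    With batch size 1 this is instance normalization: each volume is normalized
    by its own per-channel spatial statistics.  By default the same per-volume
    statistics are used at inference (``use_running_stats=False``), because
    single-volume exponential running estimates are unreliable — at the deepest
    ladder levels the spatial extent can be a handful of voxels (variance near
    zero), and normalizing unseen volumes by such estimates diverges.  Running
    estimates are still tracked (momentum configurable) and can be opted into.
    """

    def __init__(self, channels: int, dtype=np.float64, momentum: float = 0.1,
                 eps: float = 1e-5, use_running_stats: bool = False):
        super().__init__()
        self.gamma = Tensor(np.ones(channels, dtype=dtype), requires_grad=True)
        self.beta = Tensor(np.zeros(channels, dtype=dtype), requires_grad=True)
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)
        self.momentum = momentum
        self.eps = eps
        self.use_running_stats = use_running_stats

    def forward(self, x: Tensor) -> Tensor:
        C = x.data.shape[0]
        sp = (1, 2, 3)
        if self.training or not self.use_running_stats:
            mu = x.data.mean(axis=sp)
            var = x.data.var(axis=sp)
            if self.training:
                self.running_mean = ((1 - self.momentum) * self.running_mean
                                     + self.momentum * mu)
                self.running_var = ((1 - self.momentum) * self.running_var
                                    + self.momentum * var)
            std = np.sqrt(var + self.eps)
            xhat = (x.data - mu[:, None, None, None]) / std[:, None, None, None]
            data = (self.gamma.data[:, None, None, None] * xhat
                    + self.beta.data[:, None, None, None])
            gamma, beta = self.gamma, self.beta
            n = x.data[0].size

            def backward(g):
                if gamma.requires_grad:
                    gamma._accumulate((g * xhat).sum(axis=sp))
                if beta.requires_grad:
                    beta._accumulate(g.sum(axis=sp))
                if x.requires_grad:
                    dxhat = g * gamma.data[:, None, None, None]
                    s1 = dxhat.sum(axis=sp, keepdims=True)
                    s2 = (dxhat * xhat).sum(axis=sp, keepdims=True)
                    dx = (dxhat - s1 / n - xhat * s2 / n) / std[:, None, None, None]
                    x._accumulate(dx)

            return _make(data, (x, self.gamma, self.beta), backward)
        # eval mode: affine map with frozen statistics
        std = np.sqrt(self.running_var + self.eps)
        scale = self.gamma.data / std
        shift = self.beta.data - self.running_mean * scale
        data = x.data * scale[:, None, None, None] + shift[:, None, None, None]
        gamma, beta = self.gamma, self.beta
        rm, inv = self.running_mean, 1.0 / std

        def backward(g):
            if x.requires_grad:
                x._accumulate(g * scale[:, None, None, None])
            if gamma.requires_grad:
                xhat = (x.data - rm[:, None, None, None]) * inv[:, None, None, None]
                gamma._accumulate((g * xhat).sum(axis=(1, 2, 3)))
            if beta.requires_grad:
                beta._accumulate(g.sum(axis=(1, 2, 3)))

        return _make(data, (x, self.gamma, self.beta), backward)


class Adam:
    """Adam optimizer over a list of parameter tensors."""

    def __init__(self, params: Sequence[Tensor], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.betas = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()

    def step(self, lr: float | None = None):
        if lr is None:
            lr = self.lr
        b1, b2 = self.betas
        self.t += 1
        bc1 = 1 - b1 ** self.t
        bc2 = 1 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.data -= lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
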