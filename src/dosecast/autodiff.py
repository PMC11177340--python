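"""Reverse-mode automatic differentiation over numpy arrays.

A deliberately small tape-based engine: each :class:`Tensor` wraps an
``ndarray`` and records the closure needed to push gradients back to its
parents.  Only the operations the dose-prediction network needs are
implemented (broadcast arithmetic, batched matmul, 2-D convolution,
pooling/upsampling, the usual nonlinearities, reductions, gather/roll).
Gradients are checked against central finite differences in the test suite.

Shapes follow the NCHW convention for image maps and ``(..., N, C)`` for
token sequences; ``np.matmul`` batching over leading dimensions is relied on
throughout.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "Module",
    "Linear",
    "Conv2d",
    "BatchNorm2d",
    "LayerNorm",
    "Adam",
    "no_grad",
    "as_tensor",
    "concat",
    "stack",
    "mish",
    "softplus",
    "sigmoid",
    "tanh",
    "exp",
    "log",
    "relu",
    "softmax",
    "upsample_bilinear_2x",
    "avg_pool2d",
]

_grad_enabled = True

#: accepted as non-promoting scalars in arithmetic fast paths
_SCALARS = (int, float, np.integer, np.floating)


@contextlib.contextmanager
def no_grad():
    """Disable tape recording within the block (inference mode)."""
    global _grad_enabled
    prev = _grad_enabled
    _grad_enabled = False
    try:
        yield
    finally:
        _grad_enabled = prev


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndim_extra = grad.ndim - len(shape)
    if ndim_extra > 0:
        grad = grad.sum(axis=tuple(range(ndim_extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) and _grad_enabled
        self._backward: Callable[[np.ndarray], None] | None = None
        self._parents: tuple[Tensor, ...] = ()

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

    @property
    def dtype(self):
        return self.data.dtype

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.shape}, grad={self.requires_grad})"

    def zero_grad(self):
        self.grad = None

    def backward(self, grad: np.ndarray | None = None):
        if grad is None:
            grad = np.ones_like(self.data)
        # iterative post-order DFS: inputs appear before their consumers
        topo: list[Tensor] = []
        visited: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in visited:
                    stack.append((p, False))
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=self.data.dtype)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.grad is None:
                node.grad = g.copy()
            else:
                node.grad = node.grad + g
            if node._backward is not None:
                node._backward(g, grads)

    # -- operator sugar ---------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        if isinstance(other, _SCALARS):
            return add(self, -other)
        return add(self, -as_tensor(other))

    def __rsub__(self, other):
        if isinstance(other, _SCALARS):
            return add(-self, other)
        return add(as_tensor(other), -self)

    def __truediv__(self, other):
        if isinstance(other, _SCALARS):
            return mul(self, 1.0 / other)
        return mul(self, power(other, -1.0))

    def __rtruediv__(self, other):
        return mul(as_tensor(other), power(self, -1.0))

    def __pow__(self, p):
        return power(self, p)

    def __matmul__(self, other):
        return matmul(self, other)

    def __getitem__(self, idx):
        return take(self, idx)

    def reshape(self, *shape):
        return reshape(self, shape if len(shape) > 1 else shape[0])

    def transpose(self, axes):
        return transpose(self, axes)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis, keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis, keepdims)

    def max(self, axis=None, keepdims=False):
        return tmax(self, axis, keepdims)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def _make(data: np.ndarray, parents: Sequence[Tensor], backward) -> Tensor:
    out = Tensor(data)
    if _grad_enabled and any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = tuple(parents)
        out._backward = backward
    return out


def _accum(grads: dict, t: Tensor, g: np.ndarray):
    if not t.requires_grad:
        return
    key = id(t)
    if key in grads:
        grads[key] = grads[key] + g
    else:
        grads[key] = g


# -- arithmetic -----------------------------------------------------------

def add(a, b) -> Tensor:
    if isinstance(b, _SCALARS):
        a = as_tensor(a)
        b = float(b)        # python scalars do not promote float32
        data = a.data + b

        def backward_s(g, grads):
            _accum(grads, a, g)

        return _make(data, (a,), backward_s)
    if isinstance(a, _SCALARS):
        return add(b, a)
    a, b = as_tensor(a), as_tensor(b)
    data = a.data + b.data

    def backward(g, grads):
        _accum(grads, a, _unbroadcast(g, a.shape))
        _accum(grads, b, _unbroadcast(g, b.shape))

    return _make(data, (a, b), backward)


def mul(a, b) -> Tensor:
    if isinstance(b, _SCALARS):
        a = as_tensor(a)
        b = float(b)
        data = a.data * b

        def backward_s(g, grads):
            _accum(grads, a, g * b)

        return _make(data, (a,), backward_s)
    a, b = as_tensor(a), as_tensor(b)
    data = a.data * b.data

    def backward(g, grads):
        _accum(grads, a, _unbroadcast(g * b.data, a.shape))
        _accum(grads, b, _unbroadcast(g * a.data, b.shape))

    return _make(data, (a, b), backward)


def power(a, p: float) -> Tensor:
    a = as_tensor(a)
    data = a.data ** p

    def backward(g, grads):
        _accum(grads, a, g * p * a.data ** (p - 1.0))

    return _make(data, (a,), backward)


def matmul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    data = np.matmul(a.data, b.data)

    def backward(g, grads):
        ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
        gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
        if a.ndim >= 2:
            ga = _unbroadcast(ga, a.shape)
        if b.ndim >= 2:
            gb = _unbroadcast(gb, b.shape)
        _accum(grads, a, ga)
        _accum(grads, b, gb)

    return _make(data, (a, b), backward)


# -- shape ops ------------------------------------------------------------

def reshape(a: Tensor, shape) -> Tensor:
    a = as_tensor(a)
    data = a.data.reshape(shape)

    def backward(g, grads):
        _accum(grads, a, g.reshape(a.shape))

    return _make(data, (a,), backward)


def transpose(a: Tensor, axes) -> Tensor:
    a = as_tensor(a)
    data = a.data.transpose(axes)
    inv = np.argsort(axes)

    def backward(g, grads):
        _accum(grads, a, g.transpose(inv))

    return _make(data, (a,), backward)


def take(a: Tensor, idx) -> Tensor:
    """Basic or integer-array indexing with gradient scatter."""
    a = as_tensor(a)
    data = a.data[idx]

    def backward(g, grads):
        ga = np.zeros_like(a.data)
        np.add.at(ga, idx, g)
        _accum(grads, a, ga)

    return _make(data, (a,), backward)


def concat(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    ts = [as_tensor(t) for t in tensors]
    data = np.concatenate([t.data for t in ts], axis=axis)
    sizes = [t.shape[axis] for t in ts]
    offsets = np.cumsum([0] + sizes)

    def backward(g, grads):
        for t, lo, hi in zip(ts, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            _accum(grads, t, g[tuple(sl)])

    return _make(data, ts, backward)


def stack(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    ts = [as_tensor(t) for t in tensors]
    data = np.stack([t.data for t in ts], axis=axis)

    def backward(g, grads):
        for i, t in enumerate(ts):
            _accum(grads, t, np.take(g, i, axis=axis))

    return _make(data, ts, backward)


def roll(a: Tensor, shift, axis) -> Tensor:
    a = as_tensor(a)
    data = np.roll(a.data, shift, axis=axis)
    neg = tuple(-s for s in shift) if isinstance(shift, tuple) else -shift

    def backward(g, grads):
        _accum(grads, a, np.roll(g, neg, axis=axis))

    return _make(data, (a,), backward)


# -- nonlinearities -------------------------------------------------------

def tanh(a) -> Tensor:
    a = as_tensor(a)
    data = np.tanh(a.data)

    def backward(g, grads):
        _accum(grads, a, g * (1.0 - data * data))

    return _make(data, (a,), backward)


def sigmoid(a) -> Tensor:
    a = as_tensor(a)
    data = 0.5 * (1.0 + np.tanh(0.5 * a.data))  # overflow-safe logistic

    def backward(g, grads):
        _accum(grads, a, g * data * (1.0 - data))

    return _make(data, (a,), backward)


def exp(a) -> Tensor:
    a = as_tensor(a)
    data = np.exp(a.data)

    def backward(g, grads):
        _accum(grads, a, g * data)

    return _make(data, (a,), backward)


def log(a) -> Tensor:
    a = as_tensor(a)
    data = np.log(a.data)

    def backward(g, grads):
        _accum(grads, a, g / a.data)

    return _make(data, (a,), backward)


def softplus(a) -> Tensor:
    a = as_tensor(a)
    x = a.data
    data = np.logaddexp(0.0, x)

    def backward(g, grads):
        _accum(grads, a, g / (1.0 + np.exp(-x)))

    return _make(data, (a,), backward)


def mish(a) -> Tensor:
    """x * tanh(softplus(x)); self-regularizing smooth activation."""
    a = as_tensor(a)
    return mul(a, tanh(softplus(a)))


def relu(a) -> Tensor:
    a = as_tensor(a)
    data = np.maximum(a.data, 0.0)

    def backward(g, grads):
        _accum(grads, a, g * (a.data > 0))

    return _make(data, (a,), backward)


def softmax(a: Tensor, axis: int = -1) -> Tensor:
    a = as_tensor(a)
    shifted = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    data = e / e.sum(axis=axis, keepdims=True)

    def backward(g, grads):
        dot = (g * data).sum(axis=axis, keepdims=True)
        _accum(grads, a, data * (g - dot))

    return _make(data, (a,), backward)


# -- reductions -----------------------------------------------------------

def tsum(a: Tensor, axis=None, keepdims=False) -> Tensor:
    a = as_tensor(a)
    data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g, grads):
        gg = g
        if axis is not None and not keepdims:
            gg = np.expand_dims(gg, axis)
        _accum(grads, a, np.broadcast_to(gg, a.shape).copy())

    return _make(data, (a,), backward)


def tmean(a: Tensor, axis=None, keepdims=False) -> Tensor:
    a = as_tensor(a)
    n = a.size if axis is None else np.prod([a.shape[ax] for ax in np.atleast_1d(axis)])
    return mul(tsum(a, axis, keepdims), 1.0 / float(n))


def tmax(a: Tensor, axis=None, keepdims=False) -> Tensor:
    a = as_tensor(a)
    data = a.data.max(axis=axis, keepdims=keepdims)

    def backward(g, grads):
        full = data if keepdims or axis is None else np.expand_dims(data, axis)
        mask = (a.data == full).astype(a.data.dtype)
        mask /= mask.sum(axis=axis, keepdims=True) if axis is not None else mask.sum()
        gg = g
        if axis is not None and not keepdims:
            gg = np.expand_dims(gg, axis)
        _accum(grads, a, mask * gg)

    return _make(data, (a,), backward)


# -- image ops ------------------------------------------------------------

def conv2d(x: Tensor, w: Tensor, b: Tensor | None, padding: int = 0) -> Tensor:
    """2-D convolution (stride 1, NCHW).  Kernel loops stay small (3x3/7x7)."""
    x, w = as_tensor(x), as_tensor(w)
    B, C, H, W = x.shape
    O, Cw, kh, kw = w.shape
    assert C == Cw, "channel mismatch"
    p = padding
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p))) if p else x.data
    Ho, Wo = H + 2 * p - kh + 1, W + 2 * p - kw + 1
    out = np.zeros((B, O, Ho, Wo), dtype=x.dtype)
    for di in range(kh):
        for dj in range(kw):
            out += np.einsum(
                "oc,bcyx->boyx", w.data[:, :, di, dj], xp[:, :, di:di + Ho, dj:dj + Wo],
                optimize=True,
            )
    if b is not None:
        out += b.data.reshape(1, O, 1, 1)

    def backward(g, grads):
        gxp = np.zeros_like(xp)
        gw = np.zeros_like(w.data)
        for di in range(kh):
            for dj in range(kw):
                patch = xp[:, :, di:di + Ho, dj:dj + Wo]
                gw[:, :, di, dj] = np.einsum("boyx,bcyx->oc", g, patch, optimize=True)
                gxp[:, :, di:di + Ho, dj:dj + Wo] += np.einsum(
                    "oc,boyx->bcyx", w.data[:, :, di, dj], g, optimize=True
                )
        gx = gxp[:, :, p:p + H, p:p + W] if p else gxp
        _accum(grads, x, gx)
        _accum(grads, w, gw)
        if b is not None:
            _accum(grads, b, g.sum(axis=(0, 2, 3)))

    parents = (x, w) if b is None else (x, w, b)
    return _make(out, parents, backward)


def avg_pool2d(x: Tensor, k: int) -> Tensor:
    """Area-average pooling by an integer factor (NCHW or HW trailing axes)."""
    x = as_tensor(x)
    *lead, H, W = x.shape
    assert H % k == 0 and W % k == 0, "pooling factor must divide the grid"
    r = reshape(x, (*lead, H // k, k, W // k, k))
    nd = len(lead)
    return tmean(tmean(r, axis=nd + 3), axis=nd + 1)


_bilinear_cache: dict[tuple[int, int], tuple] = {}


def _bilinear_2x_weights(H: int, W: int):
    """Gather indices/weights for a x2 bilinear upsample, half-pixel centers."""
    key = (H, W)
    if key not in _bilinear_cache:
        def axis_weights(n):
            src = (np.arange(2 * n) + 0.5) / 2.0 - 0.5
            i0 = np.clip(np.floor(src).astype(int), 0, n - 1)
            i1 = np.clip(i0 + 1, 0, n - 1)
            t = np.clip(src - np.floor(src), 0.0, 1.0)
            t[src < 0] = 0.0
            t[src > n - 1] = 0.0
            return i0, i1, t

        i0, i1, ti = axis_weights(H)
        j0, j1, tj = axis_weights(W)
        _bilinear_cache[key] = (i0, i1, ti, j0, j1, tj)
    return _bilinear_cache[key]


def upsample_bilinear_2x(x: Tensor) -> Tensor:
    """Bilinear x2 upsampling on the trailing two axes."""
    x = as_tensor(x)
    *lead, H, W = x.shape
    i0, i1, ti, j0, j1, tj = _bilinear_2x_weights(H, W)
    ti_c = ti.reshape(-1, 1).astype(x.dtype, copy=False)
    tj_c = tj.reshape(1, -1).astype(x.dtype, copy=False)
    d = x.data
    top = d[..., i0, :] * (1 - ti_c) + d[..., i1, :] * ti_c
    out = top[..., :, j0] * (1 - tj_c) + top[..., :, j1] * tj_c

    def backward(g, grads):
        gtop = np.zeros((*lead, 2 * H, W), dtype=g.dtype)
        np.add.at(gtop, (..., slice(None), j0), g * (1 - tj_c))
        np.add.at(gtop, (..., slice(None), j1), g * tj_c)
        gx = np.zeros_like(d)
        np.add.at(gx, (..., i0, slice(None)), gtop * (1 - ti_c))
        np.add.at(gx, (..., i1, slice(None)), gtop * ti_c)
        _accum(grads, x, gx)

    return _make(out, (x,), backward)


# -- modules --------------------------------------------------------------

class Module:
    """Parameter container with recursive discovery, in the familiar style."""

    training = True

    def parameters(self) -> list[Tensor]:
        return [t for _, t in self.named_parameters()]

    def named_parameters(self, prefix: str = ""):
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
                    elif isinstance(item, Tensor) and item.requires_grad:
                        yield f"{full}.{i}", item

    def modules(self):
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

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]):
        own = dict(self.named_parameters())
        missing = set(own) ^ set(state)
        if missing:
            raise KeyError(f"state dict mismatch: {sorted(missing)[:5]}")
        for name, p in own.items():
            p.data = np.asarray(state[name], dtype=p.data.dtype).reshape(p.shape)

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _param(rng: np.random.Generator, shape, fan_in: int | None = None) -> Tensor:
    fan = fan_in if fan_in is not None else shape[0]
    scale = np.sqrt(2.0 / max(fan, 1))
    return Tensor(rng.normal(0.0, scale, size=shape).astype(np.float32), requires_grad=True)


class Linear(Module):
    def __init__(self, rng, in_f: int, out_f: int, bias: bool = True):
        self.weight = _param(rng, (in_f, out_f), fan_in=in_f)
        self.bias = Tensor(np.zeros(out_f, dtype=np.float32), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = matmul(x, self.weight)
        if self.bias is not None:
            out = add(out, self.bias)
        return out


class Conv2d(Module):
    def __init__(self, rng, in_c: int, out_c: int, k: int, padding: int = 0, bias: bool = True):
        self.weight = _param(rng, (out_c, in_c, k, k), fan_in=in_c * k * k)
        self.bias = Tensor(np.zeros(out_c, dtype=np.float32), requires_grad=True) if bias else None
        self.padding = padding

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, padding=self.padding)


class BatchNorm2d(Module):
    """Batch normalization over (B, H, W) per channel, with running stats."""

    def __init__(self, num_c: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(num_c, dtype=np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(num_c, dtype=np.float32), requires_grad=True)
        self.running_mean = np.zeros(num_c, dtype=np.float32)
        self.running_var = np.ones(num_c, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = tmean(x, axis=(0, 2, 3), keepdims=True)
            var = tmean(power(add(x, mul(mu, -1.0)), 2.0), axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu.data.reshape(-1)
            self.running_var = (1 - m) * self.running_var + m * var.data.reshape(-1)
        else:
            mu = Tensor(self.running_mean.reshape(1, -1, 1, 1))
            var = Tensor(self.running_var.reshape(1, -1, 1, 1))
        inv = power(add(var, self.eps), -0.5)
        xn = mul(add(x, mul(mu, -1.0)), inv)
        return add(mul(xn, reshape(self.gamma, (1, -1, 1, 1))),
                   reshape(self.beta, (1, -1, 1, 1)))


class LayerNorm(Module):
    """Layer normalization over the trailing (embedding) axis."""

    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(dim, dtype=np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(dim, dtype=np.float32), requires_grad=True)
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = tmean(x, axis=-1, keepdims=True)
        xc = add(x, mul(mu, -1.0))
        var = tmean(power(xc, 2.0), axis=-1, keepdims=True)
        xn = mul(xc, power(add(var, self.eps), -0.5))
        return add(mul(xn, self.gamma), self.beta)


class Adam:
    """Adam optimizer with classic L2 weight decay added to the gradient."""

    def __init__(self, params: Iterable[Tensor], lr: float = 1e-4,
                 weight_decay: float = 1e-4, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.weight_decay = weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()

    def step(self):
        self.t += 1
        b1, b2 = self.b1, self.b2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad.astype(p.data.dtype)
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
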