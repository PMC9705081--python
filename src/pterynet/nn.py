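"""Minimal numpy tape-autodiff engine with the CNN ops this package needs.

Design notes
------------
Everything is float32.  A :class:`Tensor` wraps an ndarray and remembers the
closure that propagates its gradient to its parents; ``Tensor.backward`` walks
the tape in reverse topological order.  Convolutions run as im2col matrix
multiplies; their input gradient is scattered back with the classic
O(kh*kw)-slice col2im.  Bilinear interpolation is corner-aligned and expressed
as two small interpolation matrices, which makes its adjoint exact and cheap.

Only the ops the pterygium models use are implemented: conv2d (plus a
depthwise variant for the MobileNet trunk), max/adaptive-average pooling,
batch norm, ReLU, dropout, linear, concat, corner-aligned bilinear resize and
softmax cross-entropy (dense and per-pixel).
"""

from __future__ import annotations

import contextlib
from typing import Iterable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable tape construction (evaluation-mode forwards)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._backward = None
        self._parents: tuple = ()

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    def backward(self) -> None:
        """Reverse-mode sweep from this (scalar or any-shape) tensor."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
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
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _node(data: np.ndarray, parents: Sequence[Tensor], backward) -> Tensor:
    req = _GRAD_ENABLED and any(p.requires_grad for p in parents)
    out = Tensor(data, requires_grad=req)
    if req:
        out._parents = tuple(p for p in parents if p.requires_grad)
        out._backward = backward
    return out


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``g`` down to ``shape`` (adjoint of numpy broadcasting)."""
    extra = g.ndim - len(shape)
    if extra:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g


# ---------------------------------------------------------------------------
# elementwise / shape ops
# ---------------------------------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data + b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.data.shape))

    return _node(out_data, (a, b), backward)


def mul_scalar(a: Tensor, s: float) -> Tensor:
    a = as_tensor(a)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * s)

    return _node(a.data * s, (a,), backward)


def relu(x: Tensor) -> Tensor:
    x = as_tensor(x)
    mask = x.data > 0

    def backward(g):
        if x.requires_grad:
            x._accumulate(g * mask)

    return _node(x.data * mask, (x,), backward)


def flatten(x: Tensor) -> Tensor:
    n = x.data.shape[0]
    shape = x.data.shape

    def backward(g):
        if x.requires_grad:
            x._accumulate(g.reshape(shape))

    return _node(x.data.reshape(n, -1), (x,), backward)


def concat(xs: Sequence[Tensor], axis: int = 1) -> Tensor:
    xs = [as_tensor(x) for x in xs]
    sizes = [x.data.shape[axis] for x in xs]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for x, lo, hi in zip(xs, offsets[:-1], offsets[1:]):
            if x.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                x._accumulate(g[tuple(idx)])

    return _node(np.concatenate([x.data for x in xs], axis=axis), xs, backward)


def dropout(x: Tensor, p: float, rng: np.random.Generator, training: bool) -> Tensor:
    if not training or p <= 0.0:
        return x
    keep = (rng.random(x.data.shape) >= p).astype(np.float32) / (1.0 - p)

    def backward(g):
        if x.requires_grad:
            x._accumulate(g * keep)

    return _node(x.data * keep, (x,), backward)


# ---------------------------------------------------------------------------
# dense / conv ops
# ---------------------------------------------------------------------------

def linear(x: Tensor, w: Tensor, b: Tensor | None) -> Tensor:
    out_data = x.data @ w.data.T
    if b is not None:
        out_data = out_data + b.data

    def backward(g):
        if x.requires_grad:
            x._accumulate(g @ w.data)
        if w.requires_grad:
            w._accumulate(g.T @ x.data)
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=0))

    parents = (x, w) if b is None else (x, w, b)
    return _node(out_data, parents, backward)


def _im2col(xp: np.ndarray, kh: int, kw: int, stride: int) -> np.ndarray:
    # xp: (N, C, Hp, Wp) -> (N, Ho, Wo, C, kh, kw), contiguous copy
    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))  # (N,C,Ho',Wo',kh,kw)
    win = win[:, :, ::stride, ::stride]
    return np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5))


def conv2d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1, padding: int = 0) -> Tensor:
    """Cross-correlation, the deep-learning convention: w is (O, C, kh, kw)."""
    n, c, h, wd = x.data.shape
    o, cin, kh, kw = w.data.shape
    if cin != c:
        raise ValueError(f"conv2d channel mismatch: input {c}, weight {cin}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding))) if padding else x.data
    ho = (xp.shape[2] - kh) // stride + 1
    wo = (xp.shape[3] - kw) // stride + 1
    if ho < 1 or wo < 1:
        raise ValueError(f"conv2d: spatial input {h}x{wd} too small for kernel {kh} stride {stride}")
    cols = _im2col(xp, kh, kw, stride)  # (N,Ho,Wo,C,kh,kw)
    cols2 = cols.reshape(n * ho * wo, c * kh * kw)
    wmat = w.data.reshape(o, -1)
    out = cols2 @ wmat.T
    if b is not None:
        out += b.data
    out_data = out.reshape(n, ho, wo, o).transpose(0, 3, 1, 2)

    def backward(g):
        gmat = g.transpose(0, 2, 3, 1).reshape(n * ho * wo, o)
        if w.requires_grad:
            w._accumulate((gmat.T @ cols2).reshape(w.data.shape))
        if b is not None and b.requires_grad:
            b._accumulate(gmat.sum(axis=0))
        if x.requires_grad:
            dcols = (gmat @ wmat).reshape(n, ho, wo, c, kh, kw).transpose(0, 3, 4, 5, 1, 2)
            dxp = np.zeros(xp.shape, dtype=np.float32)
            for i in range(kh):
                for j in range(kw):
                    dxp[:, :, i:i + ho * stride:stride, j:j + wo * stride:stride] += dcols[:, :, i, j]
            if padding:
                dxp = dxp[:, :, padding:padding + h, padding:padding + wd]
            x._accumulate(dxp)

    parents = (x, w) if b is None else (x, w, b)
    return _node(out_data, parents, backward)


def depthwise_conv2d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1, padding: int = 0) -> Tensor:
    """Per-channel convolution, w is (C, kh, kw)."""
    n, c, h, wd = x.data.shape
    cw, kh, kw = w.data.shape
    if cw != c:
        raise ValueError("depthwise_conv2d channel mismatch")
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding))) if padding else x.data
    ho = (xp.shape[2] - kh) // stride + 1
    wo = (xp.shape[3] - kw) // stride + 1
    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))[:, :, ::stride, ::stride]  # (N,C,Ho,Wo,kh,kw)
    out_data = np.einsum("nchwij,cij->nchw", win, w.data, optimize=True)
    if b is not None:
        out_data = out_data + b.data[None, :, None, None]

    def backward(g):
        if w.requires_grad:
            w._accumulate(np.einsum("nchw,nchwij->cij", g, win, optimize=True))
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            dxp = np.zeros(xp.shape, dtype=np.float32)
            for i in range(kh):
                for j in range(kw):
                    dxp[:, :, i:i + ho * stride:stride, j:j + wo * stride:stride] += (
                        g * w.data[None, :, i, j, None, None]
                    )
            if padding:
                dxp = dxp[:, :, padding:padding + h, padding:padding + wd]
            x._accumulate(dxp)

    parents = (x, w) if b is None else (x, w, b)
    return _node(out_data.astype(np.float32), parents, backward)


def max_pool2d(x: Tensor, kernel: int, stride: int, padding: int = 0) -> Tensor:
    n, c, h, w = x.data.shape
    if padding:
        xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)),
                    constant_values=-np.inf)
    else:
        xp = x.data
    hp, wp = xp.shape[2], xp.shape[3]
    ho = (hp - kernel) // stride + 1
    wo = (wp - kernel) // stride + 1
    if ho < 1 or wo < 1:
        raise ValueError(f"max_pool2d: input {h}x{w} too small for kernel {kernel} stride {stride}")
    win = sliding_window_view(xp, (kernel, kernel), axis=(2, 3))[:, :, ::stride, ::stride]
    flat = win.reshape(n, c, ho, wo, kernel * kernel)
    arg = flat.argmax(axis=-1)
    out_data = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]

    def backward(g):
        if not x.requires_grad:
            return
        oy, ox = np.meshgrid(np.arange(ho), np.arange(wo), indexing="ij")
        rows = oy[None, None] * stride + arg // kernel  # coords in padded frame
        cols_ = ox[None, None] * stride + arg % kernel
        dxp = np.zeros((n, c, hp, wp), dtype=np.float32)
        ni = np.arange(n)[:, None, None, None]
        ci = np.arange(c)[None, :, None, None]
        np.add.at(dxp, (ni, ci, rows, cols_), g)
        if padding:
            dxp = dxp[:, :, padding:padding + h, padding:padding + w]
        x._accumulate(dxp)

    return _node(out_data.astype(np.float32), (x,), backward)


def _bin_edges(n_in: int, n_out: int) -> list[tuple[int, int]]:
    return [(int(np.floor(i * n_in / n_out)), int(np.ceil((i + 1) * n_in / n_out)))
            for i in range(n_out)]


def adaptive_avg_pool2d(x: Tensor, out_hw: tuple[int, int]) -> Tensor:
    n, c, h, w = x.data.shape
    oh, ow = out_hw
    hb, wb = _bin_edges(h, oh), _bin_edges(w, ow)
    out_data = np.empty((n, c, oh, ow), dtype=np.float32)
    for i, (h0, h1) in enumerate(hb):
        for j, (w0, w1) in enumerate(wb):
            out_data[:, :, i, j] = x.data[:, :, h0:h1, w0:w1].mean(axis=(2, 3))

    def backward(g):
        if not x.requires_grad:
            return
        dx = np.zeros((n, c, h, w), dtype=np.float32)
        for i, (h0, h1) in enumerate(hb):
            for j, (w0, w1) in enumerate(wb):
                area = (h1 - h0) * (w1 - w0)
                dx[:, :, h0:h1, w0:w1] += (g[:, :, i, j] / area)[:, :, None, None]
        x._accumulate(dx)

    return _node(out_data, (x,), backward)


def interp_matrix(n_out: int, n_in: int) -> np.ndarray:
    """Corner-aligned 1-D linear interpolation matrix (n_out x n_in)."""
    m = np.zeros((n_out, n_in), dtype=np.float32)
    if n_in == 1 or n_out == 1:
        m[:, 0] = 1.0
        return m
    src = np.arange(n_out) * (n_in - 1) / (n_out - 1)
    lo = np.floor(src).astype(int)
    lo = np.minimum(lo, n_in - 2)
    frac = (src - lo).astype(np.float32)
    m[np.arange(n_out), lo] = 1.0 - frac
    m[np.arange(n_out), lo + 1] = frac
    return m


def upsample_bilinear(x: Tensor, out_hw: tuple[int, int]) -> Tensor:
    """Corner-aligned bilinear resize of an (N,C,H,W) tensor (up or down)."""
    n, c, h, w = x.data.shape
    oh, ow = out_hw
    if (oh, ow) == (h, w):
        return x
    rm = interp_matrix(oh, h)
    cm = interp_matrix(ow, w)
    out_data = np.matmul(np.matmul(rm[None, None], x.data), cm.T[None, None])

    def backward(g):
        if x.requires_grad:
            x._accumulate(np.matmul(np.matmul(rm.T[None, None], g), cm[None, None]))

    return _node(out_data, (x,), backward)


def batch_norm2d(x: Tensor, gamma: Tensor, beta: Tensor, running_mean: np.ndarray,
                 running_var: np.ndarray, training: bool, momentum: float = 0.1,
                 eps: float = 1e-5) -> Tensor:
    n, c, h, w = x.data.shape
    if training:
        m = n * h * w
        mean = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        running_mean *= (1 - momentum)
        running_mean += momentum * mean
        running_var *= (1 - momentum)
        running_var += momentum * var * (m / max(m - 1, 1))  # unbiased, torch-style
    else:
        mean, var = running_mean, running_var
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mean[None, :, None, None]) * inv_std[None, :, None, None]
    out_data = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]

    def backward(g):
        dgamma = (g * xhat).sum(axis=(0, 2, 3))
        dbeta = g.sum(axis=(0, 2, 3))
        if gamma.requires_grad:
            gamma._accumulate(dgamma)
        if beta.requires_grad:
            beta._accumulate(dbeta)
        if x.requires_grad:
            if training:
                m = n * h * w
                gs = gamma.data * inv_std
                dx = (g - (dbeta[None, :, None, None] + xhat * dgamma[None, :, None, None]) / m)
                dx = dx * gs[None, :, None, None]
            else:
                dx = g * (gamma.data * inv_std)[None, :, None, None]
            x._accumulate(dx.astype(np.float32))

    return _node(out_data.astype(np.float32), (x, gamma, beta), backward)


# ---------------------------------------------------------------------------
# losses / softmax
# ---------------------------------------------------------------------------

def softmax(x: Tensor, axis: int = 1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    s = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        if x.requires_grad:
            inner = (g * s).sum(axis=axis, keepdims=True)
            x._accumulate(s * (g - inner))

    return _node(s, (x,), backward)


def cross_entropy_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean cross-entropy; logits (M, K), integer targets (M,)."""
    t = np.asarray(targets).reshape(-1)
    m = logits.data.shape[0]
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    lse = np.log(np.exp(z).sum(axis=1))
    loss = (lse - z[np.arange(m), t]).mean()

    def backward(g):
        if logits.requires_grad:
            p = np.exp(z)
            p /= p.sum(axis=1, keepdims=True)
            p[np.arange(m), t] -= 1.0
            logits._accumulate(p * (float(g) / m))

    return _node(np.float32(loss), (logits,), backward)


def pixel_cross_entropy(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Per-pixel mean CE; logits (N,K,H,W), targets (N,H,W) integers."""
    n, k, h, w = logits.data.shape
    flat = logits.data.transpose(0, 2, 3, 1).reshape(-1, k)
    t = np.asarray(targets).reshape(-1)
    m = flat.shape[0]
    z = flat - flat.max(axis=1, keepdims=True)
    lse = np.log(np.exp(z).sum(axis=1))
    loss = (lse - z[np.arange(m), t]).mean()

    def backward(g):
        if logits.requires_grad:
            p = np.exp(z)
            p /= p.sum(axis=1, keepdims=True)
            p[np.arange(m), t] -= 1.0
            p *= float(g) / m
            logits._accumulate(p.reshape(n, h, w, k).transpose(0, 3, 1, 2))

    return _node(np.float32(loss), (logits,), backward)


# ---------------------------------------------------------------------------
# module system
# ---------------------------------------------------------------------------

class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Tiny nn.Module analogue: parameter discovery by attribute recursion."""

    def __init__(self):
        self.training = True

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def _children(self) -> Iterable["Module"]:
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield v
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield item

    def parameters(self) -> list[Parameter]:
        out = []
        for v in self.__dict__.values():
            if isinstance(v, Parameter):
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Parameter):
                        out.append(item)
                    elif isinstance(item, Module):
                        out.extend(item.parameters())
        return out

    def train(self, mode: bool = True):
        self.training = mode
        for c in self._children():
            c.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def named_state(self, prefix: str = "") -> list[tuple[str, np.ndarray]]:
        out = []
        for name, v in self.__dict__.items():
            key = f"{prefix}{name}"
            if isinstance(v, Parameter):
                out.append((key, v.data))
            elif isinstance(v, Module):
                out.extend(v.named_state(key + "."))
            elif isinstance(v, np.ndarray) and name.startswith("running_"):
                out.append((key, v))
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        out.extend(item.named_state(f"{key}.{i}."))
                    elif isinstance(item, Parameter):
                        out.append((f"{key}.{i}", item.data))
        return out

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.named_state()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_state())
        if set(own) != set(state):
            missing = set(own) ^ set(state)
            raise KeyError(f"state mismatch on keys: {sorted(missing)[:5]} ...")
        for k, arr in own.items():
            np.copyto(arr, state[k])

    def num_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


class Identity(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return relu(x)


class Conv2d(Module):
    def __init__(self, cin: int, cout: int, kernel: int, rng: np.random.Generator,
                 stride: int = 1, padding: int = 0, bias: bool = True):
        super().__init__()
        self.stride, self.padding = stride, padding
        fan_in = cin * kernel * kernel
        std = np.sqrt(2.0 / fan_in)
        self.weight = Parameter(rng.normal(0.0, std, (cout, cin, kernel, kernel)))
        self.bias = Parameter(np.zeros(cout)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, self.stride, self.padding)


class DepthwiseConv2d(Module):
    def __init__(self, channels: int, kernel: int, rng: np.random.Generator,
                 stride: int = 1, padding: int = 0, bias: bool = False):
        super().__init__()
        self.stride, self.padding = stride, padding
        std = np.sqrt(2.0 / (kernel * kernel))
        self.weight = Parameter(rng.normal(0.0, std, (channels, kernel, kernel)))
        self.bias = Parameter(np.zeros(channels)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return depthwise_conv2d(x, self.weight, self.bias, self.stride, self.padding)


class Linear(Module):
    def __init__(self, fin: int, fout: int, rng: np.random.Generator, bias: bool = True):
        super().__init__()
        std = np.sqrt(2.0 / fin)
        self.weight = Parameter(rng.normal(0.0, std, (fout, fin)))
        self.bias = Parameter(np.zeros(fout)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return linear(x, self.weight, self.bias)


class BatchNorm2d(Module):
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.weight = Parameter(np.ones(channels))
        self.bias = Parameter(np.zeros(channels))
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)

    def forward(self, x: Tensor) -> Tensor:
        return batch_norm2d(x, self.weight, self.bias, self.running_mean,
                            self.running_var, self.training, self.momentum, self.eps)


class MaxPool2d(Module):
    def __init__(self, kernel: int, stride: int, padding: int = 0):
        super().__init__()
        self.kernel, self.stride, self.padding = kernel, stride, padding

    def forward(self, x: Tensor) -> Tensor:
        return max_pool2d(x, self.kernel, self.stride, self.padding)


class AdaptiveAvgPool2d(Module):
    def __init__(self, out_hw: tuple[int, int]):
        super().__init__()
        self.out_hw = out_hw

    def forward(self, x: Tensor) -> Tensor:
        return adaptive_avg_pool2d(x, self.out_hw)


class Dropout(Module):
    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        self.p = p
        self.rng = rng

    def forward(self, x: Tensor) -> Tensor:
        return dropout(x, self.p, self.rng, self.training)


class SGD:
    """Plain SGD with classical momentum."""

    def __init__(self, params: Sequence[Parameter], lr: float, momentum: float = 0.9,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr, self.momentum, self.weight_decay = lr, momentum, weight_decay
        self._buf = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        for p, buf in zip(self.params, self._buf):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            buf *= self.momentum
            buf += g
            p.data -= self.lr * buf
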