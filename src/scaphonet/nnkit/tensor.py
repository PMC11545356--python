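"""Reverse-mode automatic differentiation over numpy arrays.

A small tape-based autodiff engine sufficient for training the convolutional
detectors in this package on CPU.  Every operation builds a node holding its
parent tensors and closures that map the upstream gradient to each parent's
gradient contribution; :meth:`Tensor.backward` walks the tape in reverse
topological order.

Design constraints:

* arrays keep their dtype (float32 for networks, float64 for hand oracles);
* broadcasting in elementwise ops is supported, with gradients summed back
  to the parent shape;
* a ``no_grad`` context disables tape construction for inference speed.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Sequence

import numpy as np

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable graph construction inside the context (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


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
    """A numpy array plus an optional gradient tape node."""

    __slots__ = ("data", "grad", "requires_grad", "_parents")

    def __init__(self, data, requires_grad: bool = False, _parents=()):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p, _ in _parents
        )
        # parents: sequence of (Tensor, grad_fn) where grad_fn(upstream)->grad
        self._parents = tuple(_parents) if (_GRAD_ENABLED and self.requires_grad) else ()

    # -- bookkeeping ------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    def zero_grad(self) -> None:
        self.grad = None

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, dtype={self.data.dtype}, grad={self.requires_grad})"

    # -- backward ---------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without argument requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; graphs can be deep
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for parent, _ in node._parents:
                if id(parent) not in seen:
                    stack.append((parent, False))
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=self.data.dtype)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad and not node._parents:
                node.grad = g if node.grad is None else node.grad + g
            for parent, grad_fn in node._parents:
                if not parent.requires_grad:
                    continue
                pg = grad_fn(g)
                key = id(parent)
                if key in grads:
                    grads[key] = grads[key] + pg
                else:
                    grads[key] = pg

    # -- operators --------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __sub__(self, other):
        return add(self, mul(other, -1.0))

    def __rsub__(self, other):
        return add(mul(self, -1.0), other)

    def __neg__(self):
        return mul(self, -1.0)

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            return mul(self, power(other, -1.0))
        return mul(self, 1.0 / other)

    def __matmul__(self, other):
        return matmul(self, other)

    def __pow__(self, p):
        return power(self, float(p))

    def reshape(self, *shape):
        return reshape(self, shape)

    def transpose(self, axes):
        return transpose(self, axes)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis=axis, keepdims=keepdims)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


# ---------------------------------------------------------------------------
# elementwise / reduction primitives
# ---------------------------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = Tensor(
        a.data + b.data,
        _parents=(
            (a, lambda g: _unbroadcast(g, a.data.shape)),
            (b, lambda g: _unbroadcast(g, b.data.shape)),
        ),
    )
    return out


def mul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    return Tensor(
        a.data * b.data,
        _parents=(
            (a, lambda g: _unbroadcast(g * b.data, a.data.shape)),
            (b, lambda g: _unbroadcast(g * a.data, b.data.shape)),
        ),
    )


def power(a, p: float) -> Tensor:
    a = as_tensor(a)
    return Tensor(
        a.data**p,
        _parents=((a, lambda g: g * p * a.data ** (p - 1.0)),),
    )


def matmul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    return Tensor(
        a.data @ b.data,
        _parents=(
            (a, lambda g: g @ b.data.T),
            (b, lambda g: a.data.T @ g),
        ),
    )


def relu(a) -> Tensor:
    a = as_tensor(a)
    mask = a.data > 0
    return Tensor(np.where(mask, a.data, 0.0), _parents=((a, lambda g: g * mask),))


def leaky_relu(a, slope: float = 0.01) -> Tensor:
    a = as_tensor(a)
    mask = a.data > 0
    scale = np.where(mask, 1.0, slope)
    return Tensor(a.data * scale, _parents=((a, lambda g: g * scale),))


def sigmoid(a) -> Tensor:
    a = as_tensor(a)
    # tanh-based form is overflow-free for any input magnitude
    y = 0.5 * (1.0 + np.tanh(0.5 * a.data))
    return Tensor(y, _parents=((a, lambda g: g * y * (1.0 - y)),))


def tanh(a) -> Tensor:
    a = as_tensor(a)
    y = np.tanh(a.data)
    return Tensor(y, _parents=((a, lambda g: g * (1.0 - y * y)),))


def exp(a) -> Tensor:
    a = as_tensor(a)
    y = np.exp(a.data)
    return Tensor(y, _parents=((a, lambda g: g * y),))


def log(a) -> Tensor:
    a = as_tensor(a)
    return Tensor(np.log(a.data), _parents=((a, lambda g: g / a.data),))


def clip(a, lo: float, hi: float) -> Tensor:
    """Clamp values; gradient passes only where the value was inside [lo, hi]."""
    a = as_tensor(a)
    mask = (a.data >= lo) & (a.data <= hi)
    return Tensor(np.clip(a.data, lo, hi), _parents=((a, lambda g: g * mask),))


def smooth_l1(a, beta: float = 1.0) -> Tensor:
    """Elementwise smooth-L1: quadratic below ``beta``, linear above."""
    a = as_tensor(a)
    absd = np.abs(a.data)
    quad = absd < beta
    y = np.where(quad, 0.5 * a.data**2 / beta, absd - 0.5 * beta)
    dydx = np.where(quad, a.data / beta, np.sign(a.data))
    return Tensor(y, _parents=((a, lambda g: g * dydx),))


def tsum(a, axis=None, keepdims=False) -> Tensor:
    a = as_tensor(a)
    y = a.data.sum(axis=axis, keepdims=keepdims)

    def grad_fn(g):
        if axis is None:
            return np.broadcast_to(g, a.data.shape).copy()
        if not keepdims:
            ax = axis if isinstance(axis, tuple) else (axis,)
            g = np.expand_dims(g, ax)
        return np.broadcast_to(g, a.data.shape).copy()

    return Tensor(y, _parents=((a, grad_fn),))


def tmean(a, axis=None, keepdims=False) -> Tensor:
    a = as_tensor(a)
    if axis is None:
        n = a.data.size
    else:
        ax = axis if isinstance(axis, tuple) else (axis,)
        n = int(np.prod([a.data.shape[i] for i in ax]))
    return mul(tsum(a, axis=axis, keepdims=keepdims), 1.0 / n)


# ---------------------------------------------------------------------------
# shape primitives
# ---------------------------------------------------------------------------

def reshape(a, shape) -> Tensor:
    a = as_tensor(a)
    return Tensor(
        a.data.reshape(shape), _parents=((a, lambda g: g.reshape(a.data.shape)),)
    )


def transpose(a, axes: Sequence[int]) -> Tensor:
    a = as_tensor(a)
    inv = np.argsort(axes)
    return Tensor(
        a.data.transpose(axes), _parents=((a, lambda g: g.transpose(inv)),)
    )


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def make_grad(i):
        def grad_fn(g):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(int(offsets[i]), int(offsets[i + 1]))
            return g[tuple(sl)]

        return grad_fn

    return Tensor(
        np.concatenate([t.data for t in tensors], axis=axis),
        _parents=tuple((t, make_grad(i)) for i, t in enumerate(tensors)),
    )


def take_rows(a, idx: np.ndarray) -> Tensor:
    """Select rows along axis 0 (gradient scatter-adds back)."""
    a = as_tensor(a)
    idx = np.asarray(idx)

    def grad_fn(g):
        out = np.zeros_like(a.data)
        np.add.at(out, idx, g)
        return out

    return Tensor(a.data[idx], _parents=((a, grad_fn),))


def softmax_cross_entropy(logits, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy of (N, K) logits against integer labels.

    Fused log-softmax formulation: numerically stable and with gradient
    (softmax - onehot)/N, which does not vanish when the softmax saturates.
    """
    logits = as_tensor(logits)
    labels = np.asarray(labels)
    n, k = logits.data.shape
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    lse = np.log(np.exp(z).sum(axis=1))
    loss = (lse - z[np.arange(n), labels]).mean()
    p = np.exp(z) / np.exp(z).sum(axis=1, keepdims=True)

    def grad_fn(g):
        d = p.copy()
        d[np.arange(n), labels] -= 1.0
        return (g * d / n).astype(logits.data.dtype)

    return Tensor(np.asarray(loss, dtype=logits.data.dtype),
                  _parents=((logits, grad_fn),))


def softmax(a, axis: int = -1) -> Tensor:
    a = as_tensor(a)
    z = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    y = e / e.sum(axis=axis, keepdims=True)

    def grad_fn(g):
        dot = (g * y).sum(axis=axis, keepdims=True)
        return y * (g - dot)

    return Tensor(y, _parents=((a, grad_fn),))


# ---------------------------------------------------------------------------
# convolution / pooling primitives
# ---------------------------------------------------------------------------

def conv2d(x, weight, bias=None, stride: int = 1, padding: int = 0,
           dilation: int = 1) -> Tensor:
    """2-D convolution (cross-correlation), NCHW layout.

    Implemented as a sum of k*k strided matmuls, which keeps memory low and
    makes the backward pass a mirror of the forward loop.
    """
    x, weight = as_tensor(x), as_tensor(weight)
    n, cin, h, w = x.data.shape
    cout, cin_w, kh, kw = weight.data.shape
    if cin != cin_w:
        raise ValueError(f"conv2d channel mismatch: input {cin}, weight {cin_w}")
    s, p, d = stride, padding, dilation
    ho = (h + 2 * p - d * (kh - 1) - 1) // s + 1
    wo = (w + 2 * p - d * (kw - 1) - 1) // s + 1
    if ho <= 0 or wo <= 0:
        raise ValueError("conv2d output size would be non-positive")
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p))) if p else x.data
    acc = np.zeros((n, ho, wo, cout), dtype=x.data.dtype)
    patches = []  # cache views for backward
    for ki in range(kh):
        for kj in range(kw):
            xs = xp[:, :, ki * d: ki * d + (ho - 1) * s + 1: s,
                    kj * d: kj * d + (wo - 1) * s + 1: s]
            patches.append(xs)
            # (N,Cin,Ho,Wo) x (Cout,Cin) -> (N,Ho,Wo,Cout)
            acc += np.tensordot(xs, weight.data[:, :, ki, kj], axes=([1], [1]))
    y = acc.transpose(0, 3, 1, 2)

    def grad_x(g):
        gt = np.ascontiguousarray(g.transpose(0, 2, 3, 1))  # (N,Ho,Wo,Cout)
        dxp = np.zeros((n, cin, h + 2 * p, w + 2 * p), dtype=x.data.dtype)
        idx = 0
        for ki in range(kh):
            for kj in range(kw):
                contrib = np.tensordot(gt, weight.data[:, :, ki, kj], axes=([3], [0]))
                dxp[:, :, ki * d: ki * d + (ho - 1) * s + 1: s,
                    kj * d: kj * d + (wo - 1) * s + 1: s] += contrib.transpose(0, 3, 1, 2)
                idx += 1
        return dxp[:, :, p: p + h, p: p + w] if p else dxp

    def grad_w(g):
        gt = g.transpose(0, 2, 3, 1)  # (N,Ho,Wo,Cout)
        dw = np.empty_like(weight.data)
        idx = 0
        for ki in range(kh):
            for kj in range(kw):
                xs = patches[idx]
                idx += 1
                # sum over N,Ho,Wo -> (Cout, Cin)
                dw[:, :, ki, kj] = np.tensordot(gt, xs, axes=([0, 1, 2], [0, 2, 3]))
        return dw

    parents = [(x, grad_x), (weight, grad_w)]
    if bias is not None:
        bias = as_tensor(bias)
        y = y + bias.data.reshape(1, cout, 1, 1)
        parents.append((bias, lambda g: g.sum(axis=(0, 2, 3))))
    return Tensor(y, _parents=tuple(parents))


def upsample_nearest2x(x) -> Tensor:
    x = as_tensor(x)
    y = x.data.repeat(2, axis=2).repeat(2, axis=3)

    def grad_fn(g):
        n, c, h2, w2 = g.shape
        return g.reshape(n, c, h2 // 2, 2, w2 // 2, 2).sum(axis=(3, 5))

    return Tensor(y, _parents=((x, grad_fn),))


def global_avg_pool(x) -> Tensor:
    """Spatial mean of an NCHW map -> (N, C) vector (GAP)."""
    x = as_tensor(x)
    n, c, h, w = x.data.shape
    y = x.data.mean(axis=(2, 3))

    def grad_fn(g):
        return np.broadcast_to(g[:, :, None, None] / (h * w), x.data.shape).copy()

    return Tensor(y, _parents=((x, grad_fn),))


def roi_align(features, boxes: np.ndarray, out_size: int,
              spatial_scale: float = 1.0) -> Tensor:
    """RoI Align with one bilinear sample per bin and no coordinate rounding.

    ``boxes`` is an (R, 4) array of (x_min, y_min, x_max, y_max) in input-image
    coordinates; ``spatial_scale`` maps them onto the feature grid.  Feature
    pixels live at integer coordinates (pixel-center convention).  Gradients
    flow to ``features`` only; boxes are constants.
    """
    features = as_tensor(features)
    boxes = np.asarray(boxes, dtype=np.float64)
    if boxes.ndim == 1:
        boxes = boxes[None]
    n, c, h, w = features.data.shape
    if n != 1:
        raise ValueError("roi_align expects a single feature map (N=1)")
    r = boxes.shape[0]
    if np.any(boxes[:, 2] <= boxes[:, 0]) or np.any(boxes[:, 3] <= boxes[:, 1]):
        raise ValueError("roi_align: degenerate box (zero or negative area)")
    o = out_size
    # bin-center sample coordinates on the feature grid
    xs = np.empty((r, o))
    ys = np.empty((r, o))
    for i, (x0, y0, x1, y1) in enumerate(boxes * spatial_scale):
        bw, bh = (x1 - x0) / o, (y1 - y0) / o
        xs[i] = x0 + (np.arange(o) + 0.5) * bw
        ys[i] = y0 + (np.arange(o) + 0.5) * bh
    xs = np.clip(xs, 0, w - 1)
    ys = np.clip(ys, 0, h - 1)
    x0i = np.clip(np.floor(xs).astype(int), 0, w - 2) if w > 1 else np.zeros_like(xs, int)
    y0i = np.clip(np.floor(ys).astype(int), 0, h - 2) if h > 1 else np.zeros_like(ys, int)
    fx = xs - x0i  # (R, O)
    fy = ys - y0i
    f = features.data[0]  # (C, H, W)
    # gather corners: build (R, O, O) index grids
    yy0 = y0i[:, :, None].repeat(o, axis=2)
    xx0 = x0i[:, None, :].repeat(o, axis=1)
    wy = fy[:, :, None]
    wx = fx[:, None, :]
    x1i = np.minimum(xx0 + 1, w - 1)
    y1i = np.minimum(yy0 + 1, h - 1)
    v00 = f[:, yy0, xx0]
    v01 = f[:, yy0, x1i]
    v10 = f[:, y1i, xx0]
    v11 = f[:, y1i, x1i]
    out = ((1 - wy) * (1 - wx) * v00 + (1 - wy) * wx * v01 +
           wy * (1 - wx) * v10 + wy * wx * v11)  # (C, R, O, O) broadcast
    out = out.transpose(1, 0, 2, 3).astype(features.data.dtype)

    def grad_fn(g):
        df = np.zeros_like(features.data)
        gt = g.transpose(1, 0, 2, 3)  # (C, R, O, O)
        for (iy, ix, wgt) in (
            (yy0, xx0, (1 - wy) * (1 - wx)),
            (yy0, x1i, (1 - wy) * wx),
            (y1i, xx0, wy * (1 - wx)),
            (y1i, x1i, wy * wx),
        ):
            np.add.at(df[0], (slice(None), iy, ix), gt * wgt)
        return df

    return Tensor(out, _parents=((features, grad_fn),))
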