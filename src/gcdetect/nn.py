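"""Minimal reverse-mode automatic differentiation over numpy arrays.

The detection stack in this package (convolutions, batch norm, ROI-align,
attention gates, box losses) runs on this engine.  It is a tape-based
autograd in the micrograd style, generalized to ndarrays with broadcasting:
every operation records a backward closure, and :meth:`Tensor.backward`
runs the tape in reverse topological order.  Everything is float64 and
CPU-deterministic, which is what the reproducibility contract of the
package requires.

Only the operations the detector needs are implemented; this is not a
general deep-learning framework.
"""

from __future__ import annotations

import math
from typing import Callable, Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "Parameter",
    "Module",
    "Sequential",
    "ModuleList",
    "Conv2d",
    "Linear",
    "BatchNorm2d",
    "MaxPool2d",
    "ReLU",
    "SGD",
    "astensor",
    "concat",
    "conv2d",
    "max_pool2d",
    "upsample_nearest",
    "roi_align",
    "softmax_cross_entropy",
    "binary_cross_entropy_with_logits",
    "smooth_l1",
    "initialize",
    "gradcheck",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An ndarray plus gradient bookkeeping."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False, _prev: tuple = ()):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward: Callable[[], None] | None = None
        self._prev = _prev

    # -- construction helpers -------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __len__(self) -> int:
        return len(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -- autograd core --------------------------------------------------------
    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(grad)  # own copy; callers may reuse buffers
        else:
            self.grad += grad

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this tensor (default seed: ones)."""
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
            for child in node._prev:
                if id(child) not in visited:
                    stack.append((child, False))
        if grad is None:
            grad = np.ones_like(self.data)
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward()

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other) -> "Tensor":
        other = astensor(other)
        out = Tensor(self.data + other.data,
                     self.requires_grad or other.requires_grad,
                     (self, other))
        if out.requires_grad:
            def _backward():
                if self.requires_grad:
                    self._accumulate(_unbroadcast(out.grad, self.shape))
                if other.requires_grad:
                    other._accumulate(_unbroadcast(out.grad, other.shape))
            out._backward = _backward
        return out

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        return self * -1.0

    def __sub__(self, other) -> "Tensor":
        return self + (-astensor(other))

    def __rsub__(self, other) -> "Tensor":
        return astensor(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = astensor(other)
        out = Tensor(self.data * other.data,
                     self.requires_grad or other.requires_grad,
                     (self, other))
        if out.requires_grad:
            def _backward():
                if self.requires_grad:
                    self._accumulate(_unbroadcast(out.grad * other.data, self.shape))
                if other.requires_grad:
                    other._accumulate(_unbroadcast(out.grad * self.data, other.shape))
            out._backward = _backward
        return out

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        return self * astensor(other) ** -1.0

    def __rtruediv__(self, other) -> "Tensor":
        return astensor(other) * self ** -1.0

    def __pow__(self, exponent: float) -> "Tensor":
        out = Tensor(self.data ** exponent, self.requires_grad, (self,))
        if out.requires_grad:
            def _backward():
                self._accumulate(out.grad * exponent * self.data ** (exponent - 1.0))
            out._backward = _backward
        return out

    def __matmul__(self, other) -> "Tensor":
        other = astensor(other)
        out = Tensor(self.data @ other.data,
                     self.requires_grad or other.requires_grad,
                     (self, other))
        if out.requires_grad:
            def _backward():
                if self.requires_grad:
                    self._accumulate(_unbroadcast(out.grad @ np.swapaxes(other.data, -1, -2), self.shape))
                if other.requires_grad:
                    other._accumulate(_unbroadcast(np.swapaxes(self.data, -1, -2) @ out.grad, other.shape))
            out._backward = _backward
        return out

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                     self.requires_grad, (self,))
        if out.requires_grad:
            def _backward():
                g = out.grad
                if axis is not None and not keepdims:
                    g = np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(g, self.shape).copy())
            out._backward = _backward
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max(self, axis: int, keepdims: bool = False) -> "Tensor":
        """Max along one axis; gradient flows to the first argmax (deterministic)."""
        idx = np.argmax(self.data, axis=axis)
        val = np.take_along_axis(self.data, np.expand_dims(idx, axis), axis=axis)
        out_data = val if keepdims else np.squeeze(val, axis=axis)
        out = Tensor(out_data, self.requires_grad, (self,))
        if out.requires_grad:
            def _backward():
                g = out.grad if keepdims else np.expand_dims(out.grad, axis)
                buf = np.zeros_like(self.data)
                np.put_along_axis(buf, np.expand_dims(idx, axis), g, axis=axis)
                self._accumulate(buf)
            out._backward = _backward
        return out

    # -- shape ops ------------------------------------------------------------
    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), self.requires_grad, (self,))
        if out.requires_grad:
            def _backward():
                self._accumulate(out.grad.reshape(self.shape))
            out._backward = _backward
        return out

    def transpose(self, *axes) -> "Tensor":
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        out = Tensor(self.data.transpose(axes), self.requires_grad, (self,))
        if out.requires_grad:
            inv = np.argsort(axes)
            def _backward():
                self._accumulate(out.grad.transpose(inv))
            out._backward = _backward
        return out

    def __getitem__(self, key) -> "Tensor":
        out = Tensor(self.data[key], self.requires_grad, (self,))
        if out.requires_grad:
            def _backward():
                buf = np.zeros_like(self.data)
                np.add.at(buf, key, out.grad)
                self._accumulate(buf)
            out._backward = _backward
        return out

    # -- nonlinearities -------------------------------------------------------
    def relu(self) -> "Tensor":
        mask = self.data > 0
        out = Tensor(self.data * mask, self.requires_grad, (self,))
        if out.requires_grad:
            def _backward():
                self._accumulate(out.grad * mask)
            out._backward = _backward
        return out

    def tanh(self) -> "Tensor":
        t = np.tanh(self.data)
        out = Tensor(t, self.requires_grad, (self,))
        if out.requires_grad:
            def _backward():
                self._accumulate(out.grad * (1.0 - t * t))
            out._backward = _backward
        return out

    def sigmoid(self) -> "Tensor":
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(s, self.requires_grad, (self,))
        if out.requires_grad:
            def _backward():
                self._accumulate(out.grad * s * (1.0 - s))
            out._backward = _backward
        return out

    def exp(self) -> "Tensor":
        e = np.exp(self.data)
        out = Tensor(e, self.requires_grad, (self,))
        if out.requires_grad:
            def _backward():
                self._accumulate(out.grad * e)
            out._backward = _backward
        return out

    def log(self) -> "Tensor":
        out = Tensor(np.log(self.data), self.requires_grad, (self,))
        if out.requires_grad:
            def _backward():
                self._accumulate(out.grad / self.data)
            out._backward = _backward
        return out

    def sqrt(self) -> "Tensor":
        r = np.sqrt(self.data)
        out = Tensor(r, self.requires_grad, (self,))
        if out.requires_grad:
            def _backward():
                self._accumulate(out.grad * 0.5 / r)
            out._backward = _backward
        return out

    def abs(self) -> "Tensor":
        s = np.sign(self.data)
        out = Tensor(np.abs(self.data), self.requires_grad, (self,))
        if out.requires_grad:
            def _backward():
                self._accumulate(out.grad * s)
            out._backward = _backward
        return out

    def maximum(self, other) -> "Tensor":
        other = astensor(other)
        out = Tensor(np.maximum(self.data, other.data),
                     self.requires_grad or other.requires_grad,
                     (self, other))
        if out.requires_grad:
            # ties route the full gradient to `self` (deterministic convention)
            mask = self.data >= other.data
            def _backward():
                if self.requires_grad:
                    self._accumulate(_unbroadcast(out.grad * mask, self.shape))
                if other.requires_grad:
                    other._accumulate(_unbroadcast(out.grad * ~mask, other.shape))
            out._backward = _backward
        return out

    def minimum(self, other) -> "Tensor":
        other = astensor(other)
        out = Tensor(np.minimum(self.data, other.data),
                     self.requires_grad or other.requires_grad,
                     (self, other))
        if out.requires_grad:
            mask = self.data <= other.data
            def _backward():
                if self.requires_grad:
                    self._accumulate(_unbroadcast(out.grad * mask, self.shape))
                if other.requires_grad:
                    other._accumulate(_unbroadcast(out.grad * ~mask, other.shape))
            out._backward = _backward
        return out

    def clamp_min(self, value: float) -> "Tensor":
        return self.maximum(Tensor(np.full((), value)))


def astensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [astensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 any(t.requires_grad for t in tensors), tuple(tensors))
    if out.requires_grad:
        sizes = [t.shape[axis] for t in tensors]
        offsets = np.cumsum([0] + sizes)
        def _backward():
            for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
                if t.requires_grad:
                    sl = [slice(None)] * out.ndim
                    sl[axis] = slice(lo, hi)
                    t._accumulate(out.grad[tuple(sl)])
        out._backward = _backward
    return out


# ---------------------------------------------------------------------------
# convolution / pooling primitives (im2col based)
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray, kh: int, kw: int, sh: int, sw: int,
            ph: int, pw: int) -> tuple[np.ndarray, int, int]:
    """Patch matrix (N, C*kh*kw, oh*ow), built in-place in its final layout."""
    if ph or pw:
        x = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    n, c, h, w = x.shape
    oh = (h - kh) // sh + 1
    ow = (w - kw) // sw + 1
    cols = np.empty((n, c * kh * kw, oh * ow), dtype=x.dtype)
    view = cols.reshape(n, c, kh, kw, oh, ow)  # contiguous -> a view
    for i in range(kh):
        for j in range(kw):
            view[:, :, i, j] = x[:, :, i:i + sh * oh:sh, j:j + sw * ow:sw]
    return cols, oh, ow


def _col2im(cols: np.ndarray, xshape: tuple, kh: int, kw: int, sh: int, sw: int,
            ph: int, pw: int, oh: int, ow: int) -> np.ndarray:
    """Adjoint of _im2col; `cols` has shape (N, C*kh*kw, oh*ow)."""
    n, c, h, w = xshape
    hp, wp = h + 2 * ph, w + 2 * pw
    view = cols.reshape(n, c, kh, kw, oh, ow)
    xp = np.zeros((n, c, hp, wp), dtype=cols.dtype)
    for i in range(kh):
        for j in range(kw):
            xp[:, :, i:i + sh * oh:sh, j:j + sw * ow:sw] += view[:, :, i, j]
    return xp[:, :, ph:hp - ph, pw:wp - pw] if (ph or pw) else xp


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None,
           stride: int = 1, padding: int = 0) -> Tensor:
    """2-D cross-correlation, NCHW layout."""
    k, cin, kh, kw = weight.shape
    cols2, oh, ow = _im2col(x.data, kh, kw, stride, stride, padding, padding)
    n = x.shape[0]
    w2 = weight.data.reshape(k, cin * kh * kw)
    out_data = np.matmul(w2, cols2).reshape(n, k, oh, ow)
    if bias is not None:
        out_data += bias.data.reshape(1, k, 1, 1)
    prev = (x, weight) if bias is None else (x, weight, bias)
    out = Tensor(out_data, any(t.requires_grad for t in prev), prev)
    if out.requires_grad:
        def _backward():
            g = out.grad.reshape(n, k, oh * ow)
            if weight.requires_grad:
                dw = np.einsum("nkq,npq->kp", g, cols2, optimize=True)
                weight._accumulate(dw.reshape(weight.shape))
            if bias is not None and bias.requires_grad:
                bias._accumulate(out.grad.sum(axis=(0, 2, 3)))
            if x.requires_grad:
                dcols = np.matmul(w2.T, g)
                x._accumulate(_col2im(dcols, x.shape, kh, kw, stride, stride,
                                      padding, padding, oh, ow))
        out._backward = _backward
    return out


def _max_pool2d_impl(x: Tensor, kernel: int, stride: int, padding: int) -> Tensor:
    data = x.data
    if padding:
        data = np.pad(data, ((0, 0), (0, 0), (padding, padding), (padding, padding)),
                      constant_values=-np.inf)
    cols, oh, ow = _im2col(data, kernel, kernel, stride, stride, 0, 0)
    n, c = data.shape[:2]
    flat = cols.reshape(n, c, kernel * kernel, oh, ow)
    idx = np.argmax(flat, axis=2)
    out_data = np.take_along_axis(flat, idx[:, :, None], axis=2)[:, :, 0]
    out = Tensor(out_data, x.requires_grad, (x,))
    if out.requires_grad:
        def _backward():
            gflat = np.zeros_like(flat)
            np.put_along_axis(gflat, idx[:, :, None], out.grad[:, :, None], axis=2)
            padded_shape = (n, c, x.shape[2] + 2 * padding, x.shape[3] + 2 * padding)
            gx = _col2im(gflat.reshape(n, c * kernel * kernel, oh * ow),
                         padded_shape, kernel, kernel, stride, stride, 0, 0, oh, ow)
            if padding:
                gx = gx[:, :, padding:-padding, padding:-padding]
            x._accumulate(gx)
        out._backward = _backward
    return out


def max_pool2d(x: Tensor, kernel: int = 2, stride: int | None = None,
               padding: int = 0) -> Tensor:
    return _max_pool2d_impl(x, kernel, stride or kernel, padding)


def upsample_nearest(x: Tensor, out_h: int, out_w: int) -> Tensor:
    """Nearest-neighbour resize to (out_h, out_w)."""
    n, c, h, w = x.shape
    ys = (np.arange(out_h) * h) // out_h
    xs = (np.arange(out_w) * w) // out_w
    out = Tensor(x.data[:, :, ys][:, :, :, xs], x.requires_grad, (x,))
    if out.requires_grad:
        exact = out_h % h == 0 and out_w % w == 0
        def _backward():
            if exact:  # integer zoom: block-sum, no scatter needed
                fy, fx = out_h // h, out_w // w
                gx = out.grad.reshape(n, c, h, fy, w, fx).sum(axis=(3, 5))
            else:
                gx = np.zeros_like(x.data)
                np.add.at(gx, (slice(None), slice(None), ys[:, None], xs[None, :]),
                          out.grad)
            x._accumulate(gx)
        out._backward = _backward
    return out


def roi_align(feat: Tensor, rois: np.ndarray, out_size: int,
              spatial_scale: float, sampling_ratio: int = 2) -> Tensor:
    """ROI-align with bilinear sampling for a single image.

    feat: (C, H, W) tensor; rois: (R, 4) numpy array of [x1, y1, x2, y2]
    boxes in input-image coordinates.  Returns (R, C, out_size, out_size).
    Gradients flow to `feat` only; boxes are treated as constants.
    """
    c, h, w = feat.shape
    r = rois.shape[0]
    if r == 0:
        return Tensor(np.zeros((0, c, out_size, out_size)), feat.requires_grad, (feat,))
    boxes = rois * spatial_scale
    x1, y1, x2, y2 = boxes[:, 0], boxes[:, 1], boxes[:, 2], boxes[:, 3]
    rw = np.maximum(x2 - x1, 1e-6)
    rh = np.maximum(y2 - y1, 1e-6)
    ns = sampling_ratio
    bin_h = rh / out_size
    bin_w = rw / out_size
    # sample point grid: (R, out, ns) along each axis
    iy = (np.arange(out_size)[None, :, None]
          + (np.arange(ns)[None, None, :] + 0.5) / ns)
    sy = y1[:, None, None] + iy * bin_h[:, None, None]
    sx = x1[:, None, None] + iy * bin_w[:, None, None]
    sy = sy.reshape(r, out_size, ns)
    sx = sx.reshape(r, out_size, ns)
    # full 2-D grid per roi: (R, out, ns, out, ns)
    yy = sy[:, :, :, None, None]
    xx = sx[:, None, None, :, :]
    yy, xx = np.broadcast_arrays(yy, xx)
    yy = np.clip(yy - 0.5, 0, h - 1)  # align_corners=False convention
    xx = np.clip(xx - 0.5, 0, w - 1)
    y0 = np.floor(yy).astype(np.int64)
    x0 = np.floor(xx).astype(np.int64)
    y1i = np.minimum(y0 + 1, h - 1)
    x1i = np.minimum(x0 + 1, w - 1)
    wy1 = yy - y0
    wx1 = xx - x0
    wy0 = 1.0 - wy1
    wx0 = 1.0 - wx1
    flat = feat.data.reshape(c, h * w)
    i00 = (y0 * w + x0).reshape(r, -1)
    i01 = (y0 * w + x1i).reshape(r, -1)
    i10 = (y1i * w + x0).reshape(r, -1)
    i11 = (y1i * w + x1i).reshape(r, -1)
    w00 = (wy0 * wx0).reshape(r, -1)
    w01 = (wy0 * wx1).reshape(r, -1)
    w10 = (wy1 * wx0).reshape(r, -1)
    w11 = (wy1 * wx1).reshape(r, -1)
    samples = (flat[:, i00] * w00 + flat[:, i01] * w01
               + flat[:, i10] * w10 + flat[:, i11] * w11)  # (C, R, S)
    samples = samples.reshape(c, r, out_size, ns, out_size, ns)
    out_data = samples.mean(axis=(3, 5)).transpose(1, 0, 2, 3)
    out = Tensor(out_data, feat.requires_grad, (feat,))
    if out.requires_grad:
        def _backward():
            g = out.grad.transpose(1, 0, 2, 3) * (1.0 / (ns * ns))  # (C, R, oh, ow)
            g = np.ascontiguousarray(np.broadcast_to(
                g.reshape(c, r, out_size, 1, out_size, 1),
                (c, r, out_size, ns, out_size, ns))).reshape(c, -1)
            idx = np.concatenate([i00.ravel(), i01.ravel(), i10.ravel(), i11.ravel()])
            wts = np.concatenate([w00.ravel(), w01.ravel(), w10.ravel(), w11.ravel()])
            vals = np.tile(g, (1, 4)) * wts
            # scatter via bincount on per-channel flattened indices (fast path)
            flat_idx = (np.arange(c)[:, None] * (h * w) + idx[None, :]).ravel()
            gflat = np.bincount(flat_idx, weights=vals.ravel(), minlength=c * h * w)
            feat._accumulate(gflat.reshape(c, h, w))
        out._backward = _backward
    return out


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def softmax_cross_entropy(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean cross-entropy over rows of (N, K) logits; integer targets."""
    n = logits.shape[0]
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    ez = np.exp(z)
    p = ez / ez.sum(axis=1, keepdims=True)
    loss = -np.mean(np.log(p[np.arange(n), targets] + 1e-300))
    out = Tensor(loss, logits.requires_grad, (logits,))
    if out.requires_grad:
        def _backward():
            g = p.copy()
            g[np.arange(n), targets] -= 1.0
            logits._accumulate(out.grad * g / n)
        out._backward = _backward
    return out


def binary_cross_entropy_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean BCE over a flat logit vector; float targets in {0, 1}."""
    x = logits.data
    t = np.asarray(targets, dtype=np.float64)
    loss = np.mean(np.maximum(x, 0) - x * t + np.log1p(np.exp(-np.abs(x))))
    out = Tensor(loss, logits.requires_grad, (logits,))
    if out.requires_grad:
        def _backward():
            s = 1.0 / (1.0 + np.exp(-x))
            logits._accumulate(out.grad * (s - t) / x.size)
        out._backward = _backward
    return out


def smooth_l1(diff: Tensor, beta: float = 1.0) -> Tensor:
    """Elementwise Huber / smooth-L1 of a difference tensor (no reduction)."""
    d = diff.data
    small = np.abs(d) < beta
    val = np.where(small, 0.5 * d * d / beta, np.abs(d) - 0.5 * beta)
    out = Tensor(val, diff.requires_grad, (diff,))
    if out.requires_grad:
        def _backward():
            dd = np.where(small, d / beta, np.sign(d))
            diff._accumulate(out.grad * dd)
        out._backward = _backward
    return out


# ---------------------------------------------------------------------------
# modules
# ---------------------------------------------------------------------------

class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Base class with hierarchical parameter/submodule registration."""

    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_buffers", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name: str, value: np.ndarray) -> None:
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    def _set_buffer(self, name: str, value: np.ndarray) -> None:
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    def named_modules(self, prefix: str = "") -> Iterator[tuple[str, "Module"]]:
        yield prefix, self
        for name, mod in self._modules.items():
            sub = f"{prefix}.{name}" if prefix else name
            yield from mod.named_modules(sub)

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for mname, mod in self.named_modules(prefix):
            for pname, p in mod._params.items():
                yield (f"{mname}.{pname}" if mname else pname), p

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def num_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def train(self, mode: bool = True) -> "Module":
        for _, m in self.named_modules():
            object.__setattr__(m, "training", mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for mname, mod in self.named_modules():
            for pname, p in mod._params.items():
                out[f"{mname}.{pname}" if mname else pname] = p.data.copy()
            for bname, b in mod._buffers.items():
                out[f"{mname}.{bname}" if mname else bname] = np.asarray(b).copy()
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for mname, mod in self.named_modules():
            for pname, p in mod._params.items():
                key = f"{mname}.{pname}" if mname else pname
                p.data = np.asarray(state[key], dtype=np.float64).copy()
            for bname in list(mod._buffers):
                key = f"{mname}.{bname}" if mname else bname
                mod._set_buffer(bname, np.asarray(state[key]).copy())

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError


class Sequential(Module):
    def __init__(self, *mods: Module):
        super().__init__()
        for i, m in enumerate(mods):
            setattr(self, str(i), m)
        self._order = [str(i) for i in range(len(mods))]

    def forward(self, x: Tensor) -> Tensor:
        for name in self._order:
            x = self._modules[name](x)
        return x

    def __iter__(self):
        return iter(self._modules[n] for n in self._order)


class ModuleList(Module):
    def __init__(self, mods: Iterable[Module] = ()):
        super().__init__()
        self._order: list[str] = []
        for m in mods:
            self.append(m)

    def append(self, m: Module) -> None:
        name = str(len(self._order))
        setattr(self, name, m)
        self._order.append(name)

    def __iter__(self):
        return iter(self._modules[n] for n in self._order)

    def __len__(self):
        return len(self._order)

    def __getitem__(self, i: int) -> Module:
        return self._modules[self._order[i]]


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int,
                 stride: int = 1, padding: int = 0, bias: bool = True):
        super().__init__()
        self.in_ch, self.out_ch = in_ch, out_ch
        self.kernel, self.stride, self.padding = kernel, stride, padding
        self.weight = Parameter(np.zeros((out_ch, in_ch, kernel, kernel)))
        self.bias = Parameter(np.zeros(out_ch)) if bias else None

    def reset_parameters(self, rng: np.random.Generator) -> None:
        fan_in = self.in_ch * self.kernel * self.kernel
        std = math.sqrt(2.0 / fan_in)
        self.weight.data = rng.normal(0.0, std, self.weight.shape)
        if self.bias is not None:
            self.bias.data = np.zeros(self.out_ch)

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, self.stride, self.padding)


class Linear(Module):
    def __init__(self, in_f: int, out_f: int):
        super().__init__()
        self.in_f, self.out_f = in_f, out_f
        self.weight = Parameter(np.zeros((in_f, out_f)))
        self.bias = Parameter(np.zeros(out_f))

    def reset_parameters(self, rng: np.random.Generator) -> None:
        std = math.sqrt(2.0 / self.in_f)
        self.weight.data = rng.normal(0.0, std, self.weight.shape)
        self.bias.data = np.zeros(self.out_f)

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class BatchNorm2d(Module):
    """Batch normalization over (N, H, W) per channel with running stats."""

    def __init__(self, ch: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.ch, self.eps, self.momentum = ch, eps, momentum
        self.weight = Parameter(np.ones(ch))
        self.bias = Parameter(np.zeros(ch))
        self.register_buffer("running_mean", np.zeros(ch))
        self.register_buffer("running_var", np.ones(ch))

    def reset_parameters(self, rng: np.random.Generator) -> None:
        self.weight.data = np.ones(self.ch)
        self.bias.data = np.zeros(self.ch)
        self._set_buffer("running_mean", np.zeros(self.ch))
        self._set_buffer("running_var", np.ones(self.ch))

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            axes = (0, 2, 3)
            m = x.data.mean(axis=axes)
            v = x.data.var(axis=axes)
            n = x.data.size / self.ch
            self._set_buffer("running_mean",
                             (1 - self.momentum) * self.running_mean + self.momentum * m)
            unbiased = v * n / max(n - 1, 1)
            self._set_buffer("running_var",
                             (1 - self.momentum) * self.running_var + self.momentum * unbiased)
            inv = 1.0 / np.sqrt(v + self.eps)
            xhat = (x.data - m[None, :, None, None]) * inv[None, :, None, None]
            out_data = xhat * self.weight.data[None, :, None, None] \
                + self.bias.data[None, :, None, None]
            out = Tensor(out_data, x.requires_grad or self.weight.requires_grad,
                         (x, self.weight, self.bias))
            if out.requires_grad:
                w = self.weight.data.copy()
                def _backward():
                    g = out.grad
                    if self.weight.requires_grad:
                        self.weight._accumulate((g * xhat).sum(axis=axes))
                    if self.bias.requires_grad:
                        self.bias._accumulate(g.sum(axis=axes))
                    if x.requires_grad:
                        gxhat = g * w[None, :, None, None]
                        mg = gxhat.mean(axis=axes)
                        mgx = (gxhat * xhat).mean(axis=axes)
                        gx = (gxhat - mg[None, :, None, None]
                              - xhat * mgx[None, :, None, None]) * inv[None, :, None, None]
                        x._accumulate(gx)
                out._backward = _backward
            return out
        inv = 1.0 / np.sqrt(self.running_var + self.eps)
        scale = self.weight.data * inv
        shift = self.bias.data - self.running_mean * scale
        out = Tensor(x.data * scale[None, :, None, None] + shift[None, :, None, None],
                     x.requires_grad or self.weight.requires_grad,
                     (x, self.weight, self.bias))
        if out.requires_grad:
            xd = x.data
            def _backward():
                g = out.grad
                if self.weight.requires_grad:
                    self.weight._accumulate(
                        (g * (xd - self.running_mean[None, :, None, None])).sum(axis=(0, 2, 3)) * inv)
                if self.bias.requires_grad:
                    self.bias._accumulate(g.sum(axis=(0, 2, 3)))
                if x.requires_grad:
                    x._accumulate(g * scale[None, :, None, None])
            out._backward = _backward
        return out


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class MaxPool2d(Module):
    def __init__(self, kernel: int, stride: int | None = None, padding: int = 0):
        super().__init__()
        self.kernel, self.stride, self.padding = kernel, stride or kernel, padding

    def forward(self, x: Tensor) -> Tensor:
        return max_pool2d(x, self.kernel, self.stride, self.padding)


def initialize(module: Module, seed: int) -> Module:
    """Deterministically initialize every layer of `module` from one seed.

    Each layer draws from its own generator keyed on (seed, layer path),
    so two model variants share identical weights for every layer with
    the same path: adding attention blocks to a network leaves the init
    of all pre-existing layers untouched.
    """
    import zlib
    for name, m in module.named_modules():
        reset = getattr(m, "reset_parameters", None)
        if reset is not None:
            reset(np.random.default_rng([seed, zlib.crc32(name.encode())]))
    return module


class SGD:
    """Stochastic gradient descent with momentum and decoupled-from-lr L2 decay."""

    def __init__(self, params: Sequence[Parameter], lr: float,
                 momentum: float = 0.9, weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.velocity = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        for p, v in zip(self.params, self.velocity):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data -= self.lr * v

    def state_dict(self) -> dict:
        return {"velocity": [v.copy() for v in self.velocity],
                "lr": self.lr, "momentum": self.momentum,
                "weight_decay": self.weight_decay}

    def load_state_dict(self, state: dict) -> None:
        self.velocity = [np.asarray(v).copy() for v in state["velocity"]]
        self.lr = float(state["lr"])
        self.momentum = float(state["momentum"])
        self.weight_decay = float(state["weight_decay"])


def gradcheck(fn: Callable[..., Tensor], inputs: Sequence[Tensor],
              eps: float = 1e-5, rtol: float = 1e-3) -> float:
    """Compare autodiff gradients of sum(fn(*inputs)) to central differences.

    Returns the worst relative error over all input elements.
    """
    out = fn(*inputs)
    out.sum().backward()
    worst = 0.0
    for t in inputs:
        if not t.requires_grad:
            continue
        ana = t.grad if t.grad is not None else np.zeros_like(t.data)
        flat = t.data.reshape(-1)
        num = np.zeros_like(flat)
        for i in range(flat.size):
            orig = flat[i]
            flat[i] = orig + eps
            hi = fn(*inputs).data.sum()
            flat[i] = orig - eps
            lo = fn(*inputs).data.sum()
            flat[i] = orig
            num[i] = (hi - lo) / (2 * eps)
        num = num.reshape(t.data.shape)
        denom = np.maximum(np.abs(num), 1.0)
        worst = max(worst, float(np.max(np.abs(ana - num) / denom)))
    return worst
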