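"""Minimal reverse-mode autodiff on numpy arrays, for 2D CNN training on CPU.

Design: a :class:`Tensor` wraps a float32 ndarray and (when gradients
are enabled) a closure that scatters its upstream gradient to its
parents.  Ops are free functions; convolutions are shift-and-add — one
(Cout, Cin) x (N, Cin, Ho*Wo) BLAS matmul per kernel offset, which
beats im2col on CPU at desk-scale channel counts, and makes the input
gradient a scatter of the transposed matmuls instead of a dilated full
convolution.

Only what the segmentation networks need is implemented: conv2d
(strided), depthwise conv2d, batch norm, ReLU/SiLU/sigmoid, 2x2 max
pool, nearest 2x upsample, channel concat, residual add, global average
pool, and channel-wise scaling for squeeze-excitation.
"""

from __future__ import annotations

from contextlib import contextmanager

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

_grad_enabled = True


@contextmanager
def no_grad():
    """Disable graph construction (inference mode)."""
    global _grad_enabled
    prev = _grad_enabled
    _grad_enabled = False
    try:
        yield
    finally:
        _grad_enabled = prev


class Tensor:
    __slots__ = ("data", "grad", "_backward", "_parents", "requires_grad")

    def __init__(self, data, parents=(), backward=None, requires_grad=False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self._parents = parents if _grad_enabled else ()
        self._backward = backward if _grad_enabled else None
        self.requires_grad = requires_grad

    @property
    def shape(self):
        return self.data.shape

    def backward(self):
        """Backpropagate from this (scalar) tensor through the graph."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo, seen = [], set()
        stack = [(self, False)]
        while stack:  # iterative DFS: graphs are deep (40+ blocks)
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
                node._backward = None  # free closures as we go

    def accumulate(self, g):
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)
        self._parents = ()
        self._backward = None


def _track(*tensors):
    return _grad_enabled and any(
        t.requires_grad or t._parents or t._backward for t in tensors
    )


# ---------------------------------------------------------------------------
# convolution helpers


def _pad_hw(x: np.ndarray, pad: int) -> np.ndarray:
    """Zero-pad the two trailing spatial axes (faster than np.pad)."""
    n, c, h, w = x.shape
    out = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=x.dtype)
    out[:, :, pad : pad + h, pad : pad + w] = x
    return out


def _out_hw(h: int, w: int, kh: int, kw: int, stride: int, pad: int):
    return (h + 2 * pad - kh) // stride + 1, (w + 2 * pad - kw) // stride + 1


def _tap(xp: np.ndarray, i: int, j: int, ho: int, wo: int, stride: int) -> np.ndarray:
    """The (i, j)-shifted strided window of a padded map, made contiguous."""
    sl = xp[:, :, i : i + (ho - 1) * stride + 1 : stride, j : j + (wo - 1) * stride + 1 : stride]
    return np.ascontiguousarray(sl)


def conv2d(x: Tensor, w: Parameter, b: Parameter | None, stride: int = 1, pad: int = 0):
    """2D convolution (cross-correlation), NCHW, weights (Cout, Cin, kh, kw).

    Implemented shift-and-add: one (Cout, Cin) x (N, Cin, Ho*Wo) BLAS
    matmul per kernel offset.  This beats im2col on CPU for the small
    channel counts of desk-scale networks, and makes the input gradient
    a scatter of the transposed matmuls instead of a full convolution.
    """
    cout, cin, kh, kw = w.shape
    n, c, h, wd = x.data.shape
    pointwise = kh == kw == 1 and stride == 1
    if pointwise:
        x2 = x.data.reshape(n, c, h * wd)
        out = np.matmul(w.data.reshape(cout, cin), x2)
        ho, wo = h, wd
        y = out.reshape(n, cout, ho, wo)
    else:
        xp = _pad_hw(x.data, pad) if pad else x.data
        ho, wo = _out_hw(h, wd, kh, kw, stride, pad)
        acc = np.zeros((n, cout, ho * wo), dtype=np.float32)
        for i in range(kh):
            for j in range(kw):
                acc += np.matmul(
                    w.data[:, :, i, j], _tap(xp, i, j, ho, wo, stride).reshape(n, c, ho * wo)
                )
        y = acc.reshape(n, cout, ho, wo)
    if b is not None:
        y += b.data[None, :, None, None]
    if not _track(x, w):
        return Tensor(y)

    def backward(gy):
        g2 = np.ascontiguousarray(gy).reshape(n, cout, ho * wo)
        if b is not None:
            b.accumulate(g2.sum(axis=(0, 2)))
        need_dx = bool(x._parents) or x.requires_grad
        if pointwise:
            w.accumulate(np.tensordot(g2, x2, axes=([0, 2], [0, 2])).reshape(w.shape))
            if need_dx:
                x.accumulate(np.matmul(w.data.reshape(cout, cin).T, g2).reshape(x.data.shape))
            return
        dw = np.empty_like(w.data)
        for i in range(kh):
            for j in range(kw):
                xs = _tap(xp, i, j, ho, wo, stride).reshape(n, c, ho * wo)
                dw[:, :, i, j] = np.tensordot(g2, xs, axes=([0, 2], [0, 2]))
        w.accumulate(dw)
        if need_dx:
            dxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    dxi = np.matmul(w.data[:, :, i, j].T, g2).reshape(n, c, ho, wo)
                    dxp[:, :, i : i + (ho - 1) * stride + 1 : stride,
                        j : j + (wo - 1) * stride + 1 : stride] += dxi
            x.accumulate(dxp[:, :, pad : pad + h, pad : pad + wd] if pad else dxp)

    parents = (x, w) if b is None else (x, w, b)
    return Tensor(y, parents, backward)


def depthwise_conv2d(x: Tensor, w: Parameter, stride: int = 1, pad: int = 0):
    """Depthwise conv: one k x k kernel per channel.  w: (C, kh, kw)."""
    c, kh, kw = w.shape
    n, _, h, wd = x.data.shape
    xp = _pad_hw(x.data, pad) if pad else x.data
    ho, wo = _out_hw(h, wd, kh, kw, stride, pad)
    y = np.zeros((n, c, ho, wo), dtype=np.float32)
    for i in range(kh):
        for j in range(kw):
            y += w.data[None, :, i, j, None, None] * xp[
                :, :, i : i + (ho - 1) * stride + 1 : stride,
                j : j + (wo - 1) * stride + 1 : stride]
    if not _track(x, w):
        return Tensor(y)

    def backward(gy):
        dw = np.empty_like(w.data)
        need_dx = bool(x._parents) or x.requires_grad
        dxp = np.zeros_like(xp) if need_dx else None
        for i in range(kh):
            for j in range(kw):
                xs = xp[:, :, i : i + (ho - 1) * stride + 1 : stride,
                        j : j + (wo - 1) * stride + 1 : stride]
                dw[:, i, j] = np.einsum("nchw,nchw->c", gy, xs)
                if need_dx:
                    dxp[:, :, i : i + (ho - 1) * stride + 1 : stride,
                        j : j + (wo - 1) * stride + 1 : stride] += (
                        w.data[None, :, i, j, None, None] * gy
                    )
        w.accumulate(dw)
        if need_dx:
            x.accumulate(dxp[:, :, pad : pad + h, pad : pad + wd] if pad else dxp)

    return Tensor(y, (x, w), backward)


# ---------------------------------------------------------------------------
# normalization and activations


def batch_norm(
    x: Tensor,
    gamma: Parameter,
    beta: Parameter,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    training: bool,
    momentum: float = 0.9,
    eps: float = 1e-5,
):
    """Batch norm over (N,H,W) per channel; updates running stats in place."""
    xd = x.data
    if training:
        count = xd.shape[0] * xd.shape[2] * xd.shape[3]
        m = xd.sum(axis=(0, 2, 3)) / count
        v = np.einsum("nchw,nchw->c", xd, xd) / count - m * m
        np.maximum(v, 0.0, out=v)
        running_mean *= momentum
        running_mean += (1 - momentum) * m
        running_var *= momentum
        running_var += (1 - momentum) * v
    else:
        m, v = running_mean, running_var
    inv = 1.0 / np.sqrt(v + eps)
    xhat = (xd - m[None, :, None, None]) * inv[None, :, None, None]
    y = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]
    if not _track(x, gamma, beta):
        return Tensor(y)

    def backward(gy):
        axes = (0, 2, 3)
        gamma.accumulate((gy * xhat).sum(axis=axes))
        beta.accumulate(gy.sum(axis=axes))
        gscale = gamma.data * inv
        if training:
            mcount = gy.shape[0] * gy.shape[2] * gy.shape[3]
            mean_gy = gy.mean(axis=axes)
            mean_gy_xhat = (gy * xhat).mean(axis=axes)
            dx = gscale[None, :, None, None] * (
                gy
                - mean_gy[None, :, None, None]
                - xhat * mean_gy_xhat[None, :, None, None]
            )
            del mcount
        else:
            dx = gscale[None, :, None, None] * gy
        x.accumulate(dx.astype(np.float32))

    return Tensor(y.astype(np.float32), (x, gamma, beta), backward)


def relu(x: Tensor):
    y = np.maximum(x.data, 0.0)
    if not _track(x):
        return Tensor(y)

    def backward(gy):
        x.accumulate(gy * (x.data > 0))

    return Tensor(y, (x,), backward)


def _stable_sigmoid(z: np.ndarray) -> np.ndarray:
    # exp only ever sees non-positive arguments, so it cannot overflow
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def silu(x: Tensor):
    s = _stable_sigmoid(x.data)
    y = x.data * s
    if not _track(x):
        return Tensor(y)

    def backward(gy):
        x.accumulate(gy * (s * (1.0 + x.data * (1.0 - s))))

    return Tensor(y, (x,), backward)


def sigmoid(x: Tensor):
    y = _stable_sigmoid(x.data)
    if not _track(x):
        return Tensor(y)

    def backward(gy):
        x.accumulate(gy * y * (1.0 - y))

    return Tensor(y, (x,), backward)


# ---------------------------------------------------------------------------
# shape ops


def add(a: Tensor, b: Tensor):
    y = a.data + b.data
    if not _track(a, b):
        return Tensor(y)

    def backward(gy):
        a.accumulate(gy)
        b.accumulate(gy)

    return Tensor(y, (a, b), backward)


def concat_channels(a: Tensor, b: Tensor):
    y = np.concatenate([a.data, b.data], axis=1)
    if not _track(a, b):
        return Tensor(y)
    ca = a.data.shape[1]

    def backward(gy):
        a.accumulate(gy[:, :ca])
        b.accumulate(gy[:, ca:])

    return Tensor(y, (a, b), backward)


def max_pool2(x: Tensor):
    """2x2 max pool, stride 2; spatial dims must be even."""
    n, c, h, w = x.data.shape
    if h % 2 or w % 2:
        raise ValueError(f"max_pool2 needs even spatial dims, got {(h, w)}")
    x4 = x.data.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    x4 = np.ascontiguousarray(x4).reshape(n, c, h // 2, w // 2, 4)
    idx = x4.argmax(axis=-1)
    y = np.take_along_axis(x4, idx[..., None], axis=-1)[..., 0]
    if not _track(x):
        return Tensor(y)

    def backward(gy):
        g4 = np.zeros_like(x4)
        np.put_along_axis(g4, idx[..., None], gy[..., None], axis=-1)
        g = g4.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        x.accumulate(np.ascontiguousarray(g).reshape(n, c, h, w))

    return Tensor(y, (x,), backward)


def upsample_nearest2(x: Tensor):
    y = np.repeat(np.repeat(x.data, 2, axis=2), 2, axis=3)
    if not _track(x):
        return Tensor(y)
    n, c, h, w = x.data.shape

    def backward(gy):
        x.accumulate(gy.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5)))

    return Tensor(y, (x,), backward)


def global_avg_pool(x: Tensor):
    y = x.data.mean(axis=(2, 3), keepdims=True)
    if not _track(x):
        return Tensor(y)
    n, c, h, w = x.data.shape

    def backward(gy):
        x.accumulate(np.broadcast_to(gy / (h * w), x.data.shape).astype(np.float32))

    return Tensor(y, (x,), backward)


def scale_channels(x: Tensor, s: Tensor):
    """y = x * s with s of shape (N, C, 1, 1) — squeeze-excitation gating."""
    y = x.data * s.data
    if not _track(x, s):
        return Tensor(y)

    def backward(gy):
        x.accumulate(gy * s.data)
        s.accumulate((gy * x.data).sum(axis=(2, 3), keepdims=True))

    return Tensor(y, (x, s), backward)
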