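"""Differentiable convolution, pooling and resampling kernels.

All operations are stride-1 with "same"-style zero padding, which is all the
two network architectures in this package use.  1D convolutions use im2col +
matmul; 3D convolutions use a cache-friendly scatter-GEMM over kernel
offsets.  Input gradients are computed as a convolution of the upstream
gradient with the spatially flipped, channel-swapped kernel, which keeps the
backward pass on the same fast matmul path.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import as_strided

from .autograd import Tensor

__all__ = [
    "conv1d", "conv3d", "maxpool1d", "maxpool3d_spatial",
    "upsample1d", "upsample3d_spatial", "global_maxpool", "instance_norm",
]


# --------------------------------------------------------------------------
# 1D convolution (sequences), keras-style "same" padding for any kernel size
# --------------------------------------------------------------------------

def _conv1d_raw(x: np.ndarray, w: np.ndarray, pad: tuple) -> np.ndarray:
    """x (N,C,L), w (F,C,k) -> (N,F,L_out) with L_out = L + pl + pr - k + 1."""
    n, c, length = x.shape
    f, _, k = w.shape
    pl, pr = pad
    xp = np.pad(x, ((0, 0), (0, 0), (pl, pr)))
    lout = length + pl + pr - k + 1
    sN, sC, sL = xp.strides
    cols = as_strided(xp, (n, c, k, lout), (sN, sC, sL, sL))
    cols = cols.reshape(n, c * k, lout)
    return np.matmul(w.reshape(f, c * k), cols), cols


def conv1d(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Same-padded stride-1 1D convolution: x (N,C,L) * w (F,C,k) -> (N,F,L)."""
    k = w.shape[2]
    pad = ((k - 1) // 2, k // 2)
    out_data, _ = _conv1d_raw(x.data, w.data, pad)
    if b is not None:
        out_data = out_data + b.data[None, :, None]

    def bw(g):
        n, f, lout = g.shape
        if w.requires_grad:
            _, cols = _conv1d_raw(x.data, w.data, pad)
            dw = np.matmul(g, cols.transpose(0, 2, 1)).sum(axis=0)
            w._accum(dw.reshape(w.shape))
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2)))
        if x.requires_grad:
            wf = w.data[:, :, ::-1].transpose(1, 0, 2)  # (C,F,k)
            gpad = (k - 1 - pad[0], k - 1 - pad[1])
            dx, _ = _conv1d_raw(g, wf, gpad)
            x._accum(dx)

    parents = [t for t in (x, w, b) if t is not None and t.requires_grad]
    req = bool(parents)
    return Tensor(out_data, requires_grad=req, parents=parents, backward=bw if req else None)


# --------------------------------------------------------------------------
# 3D convolution (cine volumes T,H,W), odd kernels, "same" padding
# --------------------------------------------------------------------------

# Work-buffer pool keyed by (shape, dtype).  Fresh >100 MB allocations every
# convolution call dominate run time through page faults; reusing warm
# buffers keeps the im2col fill memory-bandwidth bound.  Buffers are
# overwritten on every use and must not escape this module.
_POOL: dict = {}


def _buffer(shape, dtype):
    key = (shape, np.dtype(dtype).str)
    buf = _POOL.get(key)
    if buf is None:
        buf = _POOL[key] = np.empty(shape, dtype)
    return buf


def clear_buffers():
    """Release pooled convolution work buffers."""
    _POOL.clear()


def _padded(x: np.ndarray, pads: tuple) -> np.ndarray:
    """Zero-pad the trailing spatial axes into a pooled buffer."""
    pt, ph, pw = pads
    n, c, t, h, wd = x.shape
    xp = _buffer((n, c, t + 2 * pt, h + 2 * ph, wd + 2 * pw), x.dtype)
    xp.fill(0.0)
    xp[:, :, pt:pt + t, ph:ph + h, pw:pw + wd] = x
    return xp


def _conv3d_raw(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Same-padded correlation by scatter-GEMM over kernel offsets.

    For each of the k^3 kernel offsets one batched GEMM (F,C)@(N,C,L) is
    accumulated into a padded output at the complementary shift.  All work
    buffers are a few MB and cache-resident, avoiding the k^3-fold patch
    matrix expansion of im2col.
    """
    n, c, t, h, wd = x.shape
    f, _, kt, kh, kw = w.shape
    pt, ph, pw = kt // 2, kh // 2, kw // 2
    length = t * h * wd
    xf = np.ascontiguousarray(x).reshape(n, c, length)
    outp = _buffer((n, f, t + 2 * pt, h + 2 * ph, wd + 2 * pw), x.dtype)
    outp.fill(0.0)
    prod = _buffer((n, f, length), x.dtype)
    for dt in range(kt):
        for dy in range(kh):
            for dx in range(kw):
                np.matmul(w[:, :, dt, dy, dx], xf, out=prod)
                st, sy, sx = 2 * pt - dt, 2 * ph - dy, 2 * pw - dx
                outp[:, :, st:st + t, sy:sy + h, sx:sx + wd] += \
                    prod.reshape(n, f, t, h, wd)
    return outp[:, :, pt:pt + t, ph:ph + h, pw:pw + wd].copy()


def conv3d(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Same-padded stride-1 3D convolution: x (N,C,T,H,W) * w (F,C,kt,kh,kw)."""
    kt, kh, kw = w.shape[2:]
    if kt % 2 == 0 or kh % 2 == 0 or kw % 2 == 0:
        raise ValueError("conv3d requires odd kernel sizes")
    out_data = _conv3d_raw(x.data, w.data)
    if b is not None:
        out_data = out_data + b.data[None, :, None, None, None]

    def bw(g):
        n, f, t, h, wd = g.shape
        c = x.shape[1]
        if w.requires_grad:
            pt, ph, pw = kt // 2, kh // 2, kw // 2
            length = t * h * wd
            gm = np.ascontiguousarray(g).reshape(n, f, length)
            xp = _padded(np.ascontiguousarray(x.data), (pt, ph, pw))
            xoff = _buffer((n, c, length), x.data.dtype)
            dw = np.empty(w.shape, dtype=w.dtype)
            for dt in range(kt):
                for dy in range(kh):
                    for dx in range(kw):
                        xoff.reshape(n, c, t, h, wd)[...] = \
                            xp[:, :, dt:dt + t, dy:dy + h, dx:dx + wd]
                        dw[:, :, dt, dy, dx] = np.matmul(
                            gm, xoff.swapaxes(1, 2)).sum(axis=0)
            w._accum(dw)
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3, 4)))
        if x.requires_grad:
            wf = w.data[:, :, ::-1, ::-1, ::-1].transpose(1, 0, 2, 3, 4)
            x._accum(_conv3d_raw(g, np.ascontiguousarray(wf)))

    parents = [t_ for t_ in (x, w, b) if t_ is not None and t_.requires_grad]
    req = bool(parents)
    return Tensor(out_data, requires_grad=req, parents=parents, backward=bw if req else None)


# --------------------------------------------------------------------------
# Pooling / resampling
# --------------------------------------------------------------------------

def maxpool3d_spatial(x: Tensor, factor: int = 2) -> Tensor:
    """Max pool over H and W only (time preserved); H, W divisible by factor."""
    n, c, t, h, w = x.shape
    f = factor
    if h % f or w % f:
        raise ValueError("spatial size not divisible by pool factor")
    xr = x.data.reshape(n, c, t, h // f, f, w // f, f)
    out_data = xr.max(axis=(4, 6))

    def bw(g):
        oe = out_data[:, :, :, :, None, :, None]
        mask = (xr == oe)
        cnt = mask.sum(axis=(4, 6), keepdims=True)
        dx = mask * (g[:, :, :, :, None, :, None] / cnt)
        x._accum(dx.reshape(x.shape))

    req = x.requires_grad
    return Tensor(out_data, requires_grad=req, parents=(x,) if req else (),
                  backward=bw if req else None)


def maxpool1d(x: Tensor, pool: int) -> Tensor:
    """Max pool a (N,C,L) sequence; L divisible by pool."""
    n, c, length = x.shape
    if length % pool:
        raise ValueError("sequence length not divisible by pool size")
    xr = x.data.reshape(n, c, length // pool, pool)
    out_data = xr.max(axis=3)

    def bw(g):
        mask = (xr == out_data[..., None])
        cnt = mask.sum(axis=3, keepdims=True)
        dx = mask * (g[..., None] / cnt)
        x._accum(dx.reshape(x.shape))

    req = x.requires_grad
    return Tensor(out_data, requires_grad=req, parents=(x,) if req else (),
                  backward=bw if req else None)


def upsample3d_spatial(x: Tensor, factor: int = 2) -> Tensor:
    """Nearest-neighbour upsampling of H and W (time preserved)."""
    f = factor
    out_data = np.repeat(np.repeat(x.data, f, axis=3), f, axis=4)

    def bw(g):
        n, c, t, h, w = x.shape
        gr = g.reshape(n, c, t, h, f, w, f)
        x._accum(gr.sum(axis=(4, 6)))

    req = x.requires_grad
    return Tensor(out_data, requires_grad=req, parents=(x,) if req else (),
                  backward=bw if req else None)


def upsample1d(x: Tensor, factor: int) -> Tensor:
    """Nearest-neighbour upsampling of a (N,C,L) sequence along L."""
    out_data = np.repeat(x.data, factor, axis=2)

    def bw(g):
        n, c, length = x.shape
        x._accum(g.reshape(n, c, length, factor).sum(axis=3))

    req = x.requires_grad
    return Tensor(out_data, requires_grad=req, parents=(x,) if req else (),
                  backward=bw if req else None)


def instance_norm(x: Tensor, eps: float = 1e-5) -> Tensor:
    """Normalize each (sample, channel) slice over its spatial axes.

    Stabilizes deep encoder/decoder stacks in lieu of batch statistics
    (batches are small and heterogeneous here).
    """
    axes = tuple(range(2, x.ndim))
    mu = x.data.mean(axis=axes, keepdims=True)
    var = x.data.var(axis=axes, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    out_data = (x.data - mu) * inv

    def bw(g):
        gm = g.mean(axis=axes, keepdims=True)
        gy = (g * out_data).mean(axis=axes, keepdims=True)
        x._accum((g - gm - out_data * gy) * inv)

    req = x.requires_grad
    return Tensor(out_data, requires_grad=req, parents=(x,) if req else (),
                  backward=bw if req else None)


def global_maxpool(x: Tensor) -> Tensor:
    """Max over all trailing spatial axes of (N, C, ...) -> (N, C)."""
    n, c = x.shape[:2]
    flat = x.data.reshape(n, c, -1)
    idx = flat.argmax(axis=2)
    out_data = np.take_along_axis(flat, idx[:, :, None], axis=2)[:, :, 0]

    def bw(g):
        dx = np.zeros_like(flat)
        np.put_along_axis(dx, idx[:, :, None], g[:, :, None], axis=2)
        x._accum(dx.reshape(x.shape))

    req = x.requires_grad
    return Tensor(out_data, requires_grad=req, parents=(x,) if req else (),
                  backward=bw if req else None)
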