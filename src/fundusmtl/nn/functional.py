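"""Differentiable array operations for NCHW feature grids."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor

__all__ = [
    "conv2d", "conv_transpose2d", "max_pool2d", "avg_pool2d",
    "global_avg_pool", "upsample_bilinear2x", "dropout",
]


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    """Return patches of ``x`` as (N, C*kh*kw, Ho*Wo) plus output dims."""
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    hp, wp = x.shape[2], x.shape[3]
    ho = (hp - kh) // stride + 1
    wo = (wp - kw) // stride + 1
    sn, sc, sh, sw = x.strides
    shape = (n, c, kh, kw, ho, wo)
    strides = (sn, sc, sh, sw, sh * stride, sw * stride)
    cols = np.lib.stride_tricks.as_strided(x, shape=shape, strides=strides)
    return np.ascontiguousarray(cols).reshape(n, c * kh * kw, ho * wo), ho, wo


def _col2im(cols: np.ndarray, x_shape, kh: int, kw: int, stride: int, pad: int):
    """Scatter-add patch gradients back onto the input grid."""
    n, c, h, w = x_shape
    hp, wp = h + 2 * pad, w + 2 * pad
    ho = (hp - kh) // stride + 1
    wo = (wp - kw) // stride + 1
    cols = cols.reshape(n, c, kh, kw, ho, wo)
    out = np.zeros((n, c, hp, wp), dtype=cols.dtype)
    for i in range(kh):
        for j in range(kw):
            out[:, :, i:i + stride * ho:stride, j:j + stride * wo:stride] += cols[:, :, i, j]
    if pad:
        out = out[:, :, pad:-pad, pad:-pad]
    return out


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None,
           stride: int = 1, padding: int = 0) -> Tensor:
    """2-D convolution; ``weight`` is (Cout, Cin, kh, kw)."""
    co, ci, kh, kw = weight.shape
    n = x.shape[0]
    cols, ho, wo = _im2col(x.data, kh, kw, stride, padding)
    wmat = weight.data.reshape(co, ci * kh * kw)
    out_data = np.matmul(wmat, cols)
    if bias is not None:
        out_data = out_data + bias.data[None, :, None]
    out_data = out_data.reshape(n, co, ho, wo)
    parents = (x, weight) if bias is None else (x, weight, bias)
    req = any(p.requires_grad for p in parents)
    out = Tensor(out_data, requires_grad=req, _parents=parents)
    if out.requires_grad:
        def _backward(g, x=x, weight=weight, bias=bias, cols=cols,
                      stride=stride, padding=padding, kh=kh, kw=kw, co=co, ci=ci):
            gf = g.reshape(g.shape[0], co, -1)
            if weight.requires_grad:
                dw = np.matmul(gf, cols.transpose(0, 2, 1)).sum(axis=0)
                weight._accumulate(dw.reshape(weight.data.shape))
            if bias is not None and bias.requires_grad:
                bias._accumulate(gf.sum(axis=(0, 2)))
            if x.requires_grad:
                wmat = weight.data.reshape(co, ci * kh * kw)
                dcols = np.matmul(wmat.T, gf)
                x._accumulate(_col2im(dcols, x.data.shape, kh, kw, stride, padding))
        out._backward = _backward
    return out


def conv_transpose2d(x: Tensor, weight: Tensor, bias: Tensor | None = None,
                     stride: int = 2) -> Tensor:
    """Transposed convolution; ``weight`` is (Cin, Cout, kh, kw), no padding."""
    ci, co, kh, kw = weight.shape
    n, _, h, w = x.shape
    ho = (h - 1) * stride + kh
    wo = (w - 1) * stride + kw
    wmat = weight.data.reshape(ci, co * kh * kw)
    xf = x.data.reshape(n, ci, h * w)
    cols = np.matmul(wmat.T, xf)
    out_data = _col2im(cols, (n, co, ho, wo), kh, kw, stride, 0)
    if bias is not None:
        out_data = out_data + bias.data[None, :, None, None]
    parents = (x, weight) if bias is None else (x, weight, bias)
    req = any(p.requires_grad for p in parents)
    out = Tensor(out_data, requires_grad=req, _parents=parents)
    if out.requires_grad:
        def _backward(g, x=x, weight=weight, bias=bias, stride=stride,
                      kh=kh, kw=kw, ci=ci, co=co):
            gcols, _, _ = _im2col(g, kh, kw, stride, 0)
            if weight.requires_grad:
                xf = x.data.reshape(x.shape[0], ci, -1)
                dw = np.matmul(xf, gcols.transpose(0, 2, 1)).sum(axis=0)
                weight._accumulate(dw.reshape(weight.data.shape))
            if bias is not None and bias.requires_grad:
                bias._accumulate(g.sum(axis=(0, 2, 3)))
            if x.requires_grad:
                wmat = weight.data.reshape(ci, co * kh * kw)
                dx = np.matmul(wmat, gcols)
                x._accumulate(dx.reshape(x.data.shape))
        out._backward = _backward
    return out


def max_pool2d(x: Tensor, k: int = 2) -> Tensor:
    """Non-overlapping max pooling; spatial dims must divide by ``k``."""
    n, c, h, w = x.shape
    if h % k or w % k:
        raise ValueError(f"max_pool2d: spatial dims {(h, w)} not divisible by {k}")
    xr = x.data.reshape(n, c, h // k, k, w // k, k).transpose(0, 1, 2, 4, 3, 5)
    xr = np.ascontiguousarray(xr).reshape(n, c, h // k, w // k, k * k)
    idx = xr.argmax(axis=-1)
    out_data = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
    out = Tensor(out_data, requires_grad=x.requires_grad, _parents=(x,))
    if out.requires_grad:
        def _backward(g, x=x, idx=idx, k=k):
            n, c, ho, wo = g.shape
            dxr = np.zeros((n, c, ho, wo, k * k), dtype=g.dtype)
            np.put_along_axis(dxr, idx[..., None], g[..., None], axis=-1)
            dx = dxr.reshape(n, c, ho, wo, k, k).transpose(0, 1, 2, 4, 3, 5)
            x._accumulate(dx.reshape(x.data.shape))
        out._backward = _backward
    return out


def avg_pool2d(x: Tensor, k: int) -> Tensor:
    """Non-overlapping average pooling by an exact integer factor."""
    n, c, h, w = x.shape
    if h % k or w % k:
        raise ValueError(f"avg_pool2d: spatial dims {(h, w)} not divisible by {k}")
    out_data = x.data.reshape(n, c, h // k, k, w // k, k).mean(axis=(3, 5))
    out = Tensor(out_data, requires_grad=x.requires_grad, _parents=(x,))
    if out.requires_grad:
        def _backward(g, x=x, k=k):
            dx = np.repeat(np.repeat(g, k, axis=2), k, axis=3) / (k * k)
            x._accumulate(dx)
        out._backward = _backward
    return out


def global_avg_pool(x: Tensor) -> Tensor:
    """(N, C, H, W) -> (N, C) spatial mean."""
    return x.mean(axis=(2, 3))


def _linear_resize_matrix(n_in: int, n_out: int) -> np.ndarray:
    """Row-stochastic bilinear interpolation matrix (half-pixel centers)."""
    mat = np.zeros((n_out, n_in), dtype=np.float32)
    scale = n_in / n_out
    for o in range(n_out):
        src = (o + 0.5) * scale - 0.5
        i0 = int(np.floor(src))
        frac = src - i0
        i0c = min(max(i0, 0), n_in - 1)
        i1c = min(max(i0 + 1, 0), n_in - 1)
        mat[o, i0c] += 1.0 - frac
        mat[o, i1c] += frac
    return mat


def upsample_bilinear2x(x: Tensor) -> Tensor:
    """Bilinear x2 upsampling, expressed as separable 1-D interpolation."""
    n, c, h, w = x.shape
    a = _linear_resize_matrix(h, 2 * h)
    b = _linear_resize_matrix(w, 2 * w)
    out_data = np.einsum("oh,nchw,pw->ncop", a, x.data, b, optimize=True)
    out = Tensor(out_data, requires_grad=x.requires_grad, _parents=(x,))
    if out.requires_grad:
        def _backward(g, x=x, a=a, b=b):
            x._accumulate(np.einsum("oh,ncop,pw->nchw", a, g, b, optimize=True))
        out._backward = _backward
    return out


def dropout(x: Tensor, p: float, rng: np.random.Generator,
            training: bool) -> Tensor:
    """Inverted dropout; identity when not training or p == 0."""
    if not training or p <= 0.0:
        return x
    mask = (rng.random(x.shape) >= p).astype(np.float32) / (1.0 - p)
    return x * Tensor(mask)
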