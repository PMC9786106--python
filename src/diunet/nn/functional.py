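"""Convolution, pooling and related array-level ops for the autodiff backend.

Convolutions run as im2col + one BLAS matmul; the column tensor is built by a
small loop over kernel offsets (at most 5x5 = 25 slices), which is both simple
and fast at the spatial sizes this package trains on.  Stride is fixed at 1
for dilated/`same` convolutions; downsampling is done by 2x2 max-pooling and
upsampling by a non-overlapping 2x2 transposed convolution.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .tensor import Tensor


def _im2col(xp: np.ndarray, kh: int, kw: int, dilation: int,
            oh: int, ow: int) -> np.ndarray:
    """(N, C, Hp, Wp) padded input -> (N, C, kh, kw, oh, ow) window view copy."""
    n, c = xp.shape[:2]
    cols = np.empty((n, c, kh, kw, oh, ow), dtype=xp.dtype)
    for a in range(kh):
        ia = a * dilation
        for b in range(kw):
            jb = b * dilation
            cols[:, :, a, b] = xp[:, :, ia:ia + oh, jb:jb + ow]
    return cols


def conv2d(x: Tensor, weight: Tensor, bias: Optional[Tensor] = None,
           padding: int = 0, dilation: int = 1) -> Tensor:
    """2-D convolution, stride 1.

    Parameters
    ----------
    x : Tensor, shape (N, C, H, W)
    weight : Tensor, shape (O, C, kh, kw)
    bias : Tensor of shape (O,) or None
    padding : symmetric zero padding
    dilation : dilation rate of the kernel
    """
    n, c, h, w = x.shape
    o, c2, kh, kw = weight.shape
    if c2 != c:
        raise ValueError(f"conv2d channel mismatch: input {c}, weight {c2}")
    eff_h, eff_w = dilation * (kh - 1) + 1, dilation * (kw - 1) + 1
    oh, ow = h + 2 * padding - eff_h + 1, w + 2 * padding - eff_w + 1
    if oh <= 0 or ow <= 0:
        raise ValueError("conv2d output would be empty; increase padding")

    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    cols = _im2col(xp, kh, kw, dilation, oh, ow)          # (N,C,kh,kw,oh,ow)
    cols2 = cols.reshape(n, c * kh * kw, oh * ow)
    wmat = weight.data.reshape(o, c * kh * kw)
    y = (wmat @ cols2).reshape(n, o, oh, ow)
    if bias is not None:
        y = y + bias.data.reshape(1, o, 1, 1)

    parents = (x, weight) if bias is None else (x, weight, bias)
    req = any(p.requires_grad for p in parents)
    out = Tensor(y, req, parents)

    def _backward(g):
        gmat = g.reshape(n, o, oh * ow)
        if weight.requires_grad:
            gw = np.einsum("nol,ncl->oc", gmat, cols2, optimize=True)
            weight._accumulate(gw.reshape(o, c, kh, kw))
        if bias is not None and bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gcols = (wmat.T @ gmat).reshape(n, c, kh, kw, oh, ow)
            gxp = np.zeros_like(xp)
            for a in range(kh):
                ia = a * dilation
                for b in range(kw):
                    jb = b * dilation
                    gxp[:, :, ia:ia + oh, jb:jb + ow] += gcols[:, :, a, b]
            if padding:
                gxp = gxp[:, :, padding:-padding, padding:-padding]
            x._accumulate(gxp)

    out._backward = _backward
    return out


def conv_transpose2x2(x: Tensor, weight: Tensor,
                      bias: Optional[Tensor] = None) -> Tensor:
    """Transposed convolution, kernel 2x2, stride 2 (non-overlapping upsample).

    weight shape: (C_in, C_out, 2, 2); output spatial size doubles.
    """
    n, c, h, w = x.shape
    c2, o = weight.shape[:2]
    if c2 != c:
        raise ValueError(f"conv_transpose channel mismatch: input {c}, weight {c2}")
    t = np.einsum("ncij,coab->noiajb", x.data, weight.data, optimize=True)
    y = t.reshape(n, o, 2 * h, 2 * w).copy()
    if bias is not None:
        y += bias.data.reshape(1, o, 1, 1)

    parents = (x, weight) if bias is None else (x, weight, bias)
    out = Tensor(y, any(p.requires_grad for p in parents), parents)

    def _backward(g):
        g6 = g.reshape(n, o, h, 2, w, 2)
        if x.requires_grad:
            x._accumulate(np.einsum("noiajb,coab->ncij", g6, weight.data,
                                    optimize=True))
        if weight.requires_grad:
            weight._accumulate(np.einsum("ncij,noiajb->coab", x.data, g6,
                                         optimize=True))
        if bias is not None and bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 2, 3)))

    out._backward = _backward
    return out


def maxpool2x2(x: Tensor) -> Tensor:
    """2x2 max pooling with stride 2; ties route gradient to every maximum."""
    n, c, h, w = x.shape
    if h % 2 or w % 2:
        raise ValueError(f"maxpool2x2 needs even spatial dims, got {h}x{w}")
    win = x.data.reshape(n, c, h // 2, 2, w // 2, 2)
    y = win.max(axis=(3, 5))
    out = Tensor(y, x.requires_grad, (x,))

    def _backward(g):
        if not x.requires_grad:
            return
        mask = win == y[:, :, :, None, :, None]
        gx = mask * g[:, :, :, None, :, None]
        x._accumulate(gx.reshape(n, c, h, w))

    out._backward = _backward
    return out


def global_avg_pool(x: Tensor) -> Tensor:
    """(N, C, H, W) -> (N, C) spatial mean."""
    return x.mean(axis=(2, 3))


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Numerically shifted softmax along ``axis``."""
    shift = Tensor(x.data.max(axis=axis, keepdims=True))  # constant shift
    e = (x - shift).exp()
    return e / e.sum(axis=axis, keepdims=True)
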