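"""Convolution and pooling primitives for the autodiff engine.

Implemented with im2col / col2im on `numpy.lib.stride_tricks.sliding_window_view`
so the heavy lifting is a single GEMM per layer.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .autograd import Tensor

__all__ = ["conv2d", "max_pool2d", "dropout"]


def _pad_hw(x: np.ndarray, pad: int) -> np.ndarray:
    if pad == 0:
        return x
    return np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))


def _windows(xp: np.ndarray, kh: int, kw: int, stride: int) -> np.ndarray:
    """(B, C, OH, OW, kh, kw) view of the padded input."""
    v = sliding_window_view(xp, (kh, kw), axis=(2, 3))
    return v[:, :, ::stride, ::stride, :, :]


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None,
           stride: int = 1, padding: int = 0) -> Tensor:
    """2-D cross-correlation. x: (B,C,H,W), weight: (Cout,C,kh,kw)."""
    B, C, H, W = x.data.shape
    Cout, Cin, kh, kw = weight.data.shape
    if Cin != C:
        raise ValueError(f"conv2d channel mismatch: input {C}, weight {Cin}")
    xp = _pad_hw(x.data, padding)
    win = _windows(xp, kh, kw, stride)
    B_, C_, OH, OW = win.shape[:4]
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
        B * OH * OW, C * kh * kw)
    w2d = weight.data.reshape(Cout, C * kh * kw)
    out2d = cols @ w2d.T
    if bias is not None:
        out2d = out2d + bias.data
    out_data = out2d.reshape(B, OH, OW, Cout).transpose(0, 3, 1, 2)

    parents = [x, weight] + ([bias] if bias is not None else [])
    out = Tensor._op(out_data, parents, None)

    def bwd(g):
        gcols = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(
            B * OH * OW, Cout)
        if weight.requires_grad:
            weight._accum((gcols.T @ cols).reshape(weight.data.shape))
        if bias is not None and bias.requires_grad:
            bias._accum(gcols.sum(axis=0))
        if x.requires_grad:
            dcols = (gcols @ w2d).reshape(B, OH, OW, C, kh, kw)
            dxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    dxp[:, :, i:i + stride * OH:stride, j:j + stride * OW:stride] += \
                        dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
            if padding:
                dxp = dxp[:, :, padding:-padding, padding:-padding]
            x._accum(dxp)
    out._backward = bwd
    return out


def max_pool2d(x: Tensor, kernel: int, stride: int, padding: int = 0) -> Tensor:
    B, C, H, W = x.data.shape
    xp = _pad_hw(x.data, padding)
    if padding:  # padded cells must never win the max
        xp = xp.copy()
        xp[:, :, :padding, :] = -np.inf
        xp[:, :, -padding:, :] = -np.inf
        xp[:, :, :, :padding] = -np.inf
        xp[:, :, :, -padding:] = -np.inf
    win = _windows(xp, kernel, kernel, stride)
    B_, C_, OH, OW = win.shape[:4]
    flat = win.reshape(B, C, OH, OW, kernel * kernel)
    arg = flat.argmax(axis=-1)
    out_data = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]

    out = Tensor._op(out_data, (x,), None)

    def bwd(g):
        dxp = np.zeros_like(xp)
        ki, kj = np.divmod(arg, kernel)
        b_idx, c_idx, oi, oj = np.indices(arg.shape)
        rows = oi * stride + ki
        cols_ = oj * stride + kj
        np.add.at(dxp, (b_idx, c_idx, rows, cols_), g)
        if padding:
            dxp = dxp[:, :, padding:-padding, padding:-padding]
        x._accum(dxp)
    out._backward = bwd
    return out


def dropout(x: Tensor, p: float, rng: np.random.Generator,
            training: bool) -> Tensor:
    if not training or p <= 0.0:
        return x
    keep = (rng.random(x.data.shape) >= p).astype(x.data.dtype) / (1.0 - p)
    return x * Tensor(keep)
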