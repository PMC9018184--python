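"""Functional convolution primitives (im2col / matmul formulation).

Array layout is NCHW throughout; weights are (out, in, kh, kw) for
convolution and (in, out, kh, kw) for transposed convolution. Gradients are
exact: the input gradient of a strided/dilated convolution is computed as
the matching transposed convolution, so no scatter-add is needed.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def _eff(k: int, dilation: int) -> int:
    return (k - 1) * dilation + 1


def conv_out_size(size: int, k: int, stride: int, dilation: int, pad: int) -> int:
    return (size + 2 * pad - _eff(k, dilation)) // stride + 1


def im2col(x: np.ndarray, kh: int, kw: int, stride: int, dilation: int, pad: int):
    """(N, C, H, W) -> columns (N, H_out*W_out, C*kh*kw)."""
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = sliding_window_view(x, (_eff(kh, dilation), _eff(kw, dilation)), axis=(2, 3))
    win = win[:, :, ::stride, ::stride, ::dilation, ::dilation]
    n_, c_, ho, wo, kh_, kw_ = win.shape
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n_, ho * wo, c_ * kh_ * kw_)
    return np.ascontiguousarray(cols), ho, wo


def conv2d(x, w, b=None, stride=1, dilation=1, pad=0, return_cols=False):
    """Cross-correlation of x (N,C,H,W) with w (O,C,kh,kw)."""
    o, c, kh, kw = w.shape
    cols, ho, wo = im2col(x, kh, kw, stride, dilation, pad)
    y = cols @ w.reshape(o, -1).T
    if b is not None:
        y = y + b
    y = y.transpose(0, 2, 1).reshape(x.shape[0], o, ho, wo)
    if return_cols:
        return y, cols
    return y


def conv2d_weight_grad(dy, cols, w_shape):
    """dL/dw from output grad dy (N,O,Ho,Wo) and cached im2col columns."""
    o = w_shape[0]
    dyf = dy.reshape(dy.shape[0], o, -1).transpose(0, 2, 1)  # (N, L, O)
    dw = np.einsum("nlo,nlk->ok", dyf, cols, optimize=True)
    return dw.reshape(w_shape)


def conv2d_input_grad(dy, w, x_hw, stride=1, dilation=1, pad=0):
    """dL/dx of conv2d, computed as a transposed convolution of dy."""
    o, c, kh, kw = w.shape
    h, w_in = x_hw
    eh, ew = _eff(kh, dilation), _eff(kw, dilation)
    n, _, ho, wo = dy.shape
    # zero-stuff by the stride
    ys = np.zeros((n, o, (ho - 1) * stride + 1, (wo - 1) * stride + 1), dtype=dy.dtype)
    ys[:, :, ::stride, ::stride] = dy
    adj_h = (h + 2 * pad - eh) % stride
    adj_w = (w_in + 2 * pad - ew) % stride
    pl_h, pl_w = eh - 1 - pad, ew - 1 - pad
    if min(pl_h, pl_w) < 0:
        raise ValueError("padding larger than effective kernel is unsupported")
    yp = np.pad(ys, ((0, 0), (0, 0), (pl_h, pl_h + adj_h), (pl_w, pl_w + adj_w)))
    w_t = np.ascontiguousarray(w[:, :, ::-1, ::-1].transpose(1, 0, 2, 3))
    dx = conv2d(yp, w_t, stride=1, dilation=dilation, pad=0)
    return dx


def conv_transpose2d(x, w, b=None, stride=2, pad=1, return_cache=False):
    """Transposed convolution of x (N,C,H,W) with w (C,O,kh,kw).

    Output size = (H-1)*stride - 2*pad + kh. Implemented as a stride-1
    convolution of the zero-stuffed, edge-padded input with the spatially
    flipped, axis-swapped kernel.
    """
    c, o, kh, kw = w.shape
    n, _, h, win = x.shape
    xs = np.zeros((n, c, (h - 1) * stride + 1, (win - 1) * stride + 1), dtype=x.dtype)
    xs[:, :, ::stride, ::stride] = x
    p = kh - 1 - pad
    if p < 0:
        raise ValueError("pad must be <= kernel-1")
    xp = np.pad(xs, ((0, 0), (0, 0), (p, p), (p, p)))
    w_eq = np.ascontiguousarray(w[:, :, ::-1, ::-1].transpose(1, 0, 2, 3))
    y, cols = conv2d(xp, w_eq, b=b, stride=1, dilation=1, pad=0, return_cols=True)
    if return_cache:
        return y, (cols, xp.shape)
    return y


def conv_transpose2d_input_grad(dy, w, x_hw, stride=2, pad=1):
    """dL/dx of conv_transpose2d = the matching forward convolution of dy."""
    c, o, kh, kw = w.shape
    p = kh - 1 - pad
    # gradient through the equivalent stride-1 conv
    w_eq = np.ascontiguousarray(w[:, :, ::-1, ::-1].transpose(1, 0, 2, 3))
    h_sp = (x_hw[0] - 1) * stride + 1 + 2 * p
    w_sp = (x_hw[1] - 1) * stride + 1 + 2 * p
    dxp = conv2d_input_grad(dy, w_eq, (h_sp, w_sp), stride=1, dilation=1, pad=0)
    # un-pad, then un-stuff
    dxs = dxp[:, :, p : h_sp - p, p : w_sp - p] if p else dxp
    return dxs[:, :, ::stride, ::stride]


def conv_transpose2d_weight_grad(dy, cols, w_shape):
    """dL/dw of conv_transpose2d from the cached equivalent-conv columns."""
    c, o, kh, kw = w_shape
    dw_eq = conv2d_weight_grad(dy, cols, (o, c, kh, kw))
    return np.ascontiguousarray(dw_eq.transpose(1, 0, 2, 3)[:, :, ::-1, ::-1])
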