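"""Minimal numpy tensor layers for the patch classifier.

All activations are NHWC (batch, row, column, channel): with channels
last, the im2col gather of a 5x5xC window touches contiguous channel
runs, which keeps the copy that feeds the convolution matmul cheap.

Convolutions are stride-1 with 'same' zero padding, evaluated as one
matrix product over im2col columns; the input gradient is itself a
'same' convolution of the output gradient with transposed, 180-degree
rotated kernels.  Max pooling is 3x3 stride 2 with ceil-mode output
sizing (32 -> 16 -> 8 -> 4), padded with -inf; its backward pass
scatters into the padded array at the recorded argmax offsets.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def im2col(x, k):
    """x (N,H,W,C) zero-padded for 'same' -> columns (N*H*W, k*k*C)."""
    n, h, w, c = x.shape
    p = k // 2
    padded = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
    win = sliding_window_view(padded, (k, k), axis=(1, 2))  # N,H,W,C,k,k
    win = win.transpose(0, 1, 2, 4, 5, 3)                   # N,H,W,k,k,C
    return win.reshape(n * h * w, k * k * c)


def conv_forward(x, w, b, need_cache=True):
    """x (N,H,W,C), w (k,k,C,F), stride 1, same padding -> (N,H,W,F)."""
    n, h, wd, c = x.shape
    k, _, _, f = w.shape
    cols = im2col(x, k)
    out = cols @ w.reshape(-1, f) + b
    cache = (cols, x.shape, w) if need_cache else None
    return out.reshape(n, h, wd, f), cache


def conv_backward(dout, cache, need_dx=True):
    cols, x_shape, w = cache
    n, h, wd, c = x_shape
    k, _, _, f = w.shape
    dmat = dout.reshape(n * h * wd, f)
    dw = (cols.T @ dmat).reshape(w.shape)
    db = dmat.sum(axis=0)
    dx = None
    if need_dx:
        # input gradient = same-conv of dout with swapped+rotated kernels
        w_rot = np.ascontiguousarray(
            w[::-1, ::-1].transpose(0, 1, 3, 2)             # (k,k,F,C)
        )
        dx, _ = conv_forward(dout, w_rot, np.zeros(c, dtype=w.dtype),
                             need_cache=False)
    return dx, dw, db


def relu_forward(x):
    return np.maximum(x, 0), x > 0


def relu_backward(dout, mask):
    return dout * mask


def pool_out_len(h, k=3, s=2):
    """Ceil-mode pooled length: ceil((h - k) / s) + 1."""
    return int(-(-(h - k) // s) + 1)


def maxpool_forward(x, k=3, s=2):
    n, h, w, c = x.shape
    oh, ow = pool_out_len(h, k, s), pool_out_len(w, k, s)
    hp, wp = (oh - 1) * s + k, (ow - 1) * s + k
    padded = np.full((n, hp, wp, c), -np.inf, dtype=x.dtype)
    padded[:, :h, :w] = x
    win = sliding_window_view(padded, (k, k), axis=(1, 2))[:, ::s, ::s]
    flat = win.reshape(n, oh, ow, c, k * k)
    arg = flat.argmax(axis=4)
    out = np.take_along_axis(flat, arg[..., None], axis=4)[..., 0]
    cache = (arg, x.shape, (hp, wp), k, s)
    return np.ascontiguousarray(out), cache


def maxpool_backward(dout, cache):
    arg, x_shape, (hp, wp), k, s = cache
    n, h, w, c = x_shape
    oh, ow = arg.shape[1], arg.shape[2]
    rows = (np.arange(oh) * s)[None, :, None, None] + arg // k
    colz = (np.arange(ow) * s)[None, None, :, None] + arg % k
    base = (np.arange(n)[:, None, None, None] * hp * wp * c
            + np.arange(c)[None, None, None, :])
    flat_idx = base + (rows * wp + colz) * c
    dxp = np.zeros(n * hp * wp * c, dtype=dout.dtype)
    np.add.at(dxp, flat_idx.ravel(), dout.ravel())
    return dxp.reshape(n, hp, wp, c)[:, :h, :w]


def dense_forward(x, w, b):
    """x (N,D), w (D,M)."""
    return x @ w + b, (x, w)


def dense_backward(dout, cache):
    x, w = cache
    return dout @ w.T, x.T @ dout, dout.sum(axis=0)


def softmax(logits):
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_ce(logits, labels):
    """Mean cross-entropy of one-hot targets; returns (loss, probs, dlogits)."""
    n = logits.shape[0]
    p = softmax(logits)
    eps = np.finfo(p.dtype).tiny
    loss = -np.log(np.clip(p[np.arange(n), labels], eps, None)).mean()
    d = p.copy()
    d[np.arange(n), labels] -= 1.0
    return loss, p, d / n
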