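"""im2col-based 2-D convolution kernels (forward and adjoint).

Patch extraction and scattering loop over the (small) kernel window and use
vectorised slice assignments, which is far faster in numpy than per-patch
fancy indexing.  Grouped convolution is expressed as a stacked matmul with
the group axis batched, so depthwise convolution needs no Python loop over
channels.
"""

from __future__ import annotations

import numpy as np


def conv_output_size(size: int, k: int, stride: int, padding: int, dilation: int) -> int:
    eff = dilation * (k - 1) + 1
    return (size + 2 * padding - eff) // stride + 1


def im2col(x: np.ndarray, kh: int, kw: int, stride: int, padding: int,
           dilation: int) -> np.ndarray:
    """(N,C,H,W) -> (N, C*kh*kw, Hout*Wout) patch matrix."""
    n, c, h, w = x.shape
    hout = conv_output_size(h, kh, stride, padding, dilation)
    wout = conv_output_size(w, kw, stride, padding, dilation)
    if padding:
        x = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    cols = np.empty((n, c, kh, kw, hout, wout), dtype=x.dtype)
    for ki in range(kh):
        i0 = ki * dilation
        for kj in range(kw):
            j0 = kj * dilation
            cols[:, :, ki, kj] = x[:, :, i0:i0 + stride * hout:stride,
                                   j0:j0 + stride * wout:stride]
    return cols.reshape(n, c * kh * kw, hout * wout)


def col2im(cols: np.ndarray, x_shape: tuple, kh: int, kw: int, stride: int,
           padding: int, dilation: int) -> np.ndarray:
    """Adjoint of :func:`im2col`; scatters patch gradients back to the image."""
    n, c, h, w = x_shape
    hout = conv_output_size(h, kh, stride, padding, dilation)
    wout = conv_output_size(w, kw, stride, padding, dilation)
    cols = cols.reshape(n, c, kh, kw, hout, wout)
    xp = np.zeros((n, c, h + 2 * padding, w + 2 * padding), dtype=cols.dtype)
    for ki in range(kh):
        i0 = ki * dilation
        for kj in range(kw):
            j0 = kj * dilation
            xp[:, :, i0:i0 + stride * hout:stride,
               j0:j0 + stride * wout:stride] += cols[:, :, ki, kj]
    if padding:
        return xp[:, :, padding:-padding, padding:-padding]
    return xp


def conv2d_forward(x: np.ndarray, w: np.ndarray, stride: int, padding: int,
                   dilation: int, groups: int):
    """Returns (out, cols); the patch matrix is cached for the backward pass."""
    n, cin, h, wdt = x.shape
    cout, cin_g, kh, kw = w.shape
    if cin % groups or cout % groups or cin_g != cin // groups:
        raise ValueError(
            f"incompatible group convolution: in={cin}, out={cout}, groups={groups}")
    hout = conv_output_size(h, kh, stride, padding, dilation)
    wout = conv_output_size(wdt, kw, stride, padding, dilation)
    cols = im2col(x, kh, kw, stride, padding, dilation)  # (N, Cin*kh*kw, L)
    k = cin_g * kh * kw
    if groups == 1:
        out = w.reshape(cout, k) @ cols                  # (N, Cout, L)
    else:
        cols_g = cols.reshape(n, groups, k, hout * wout)
        w_g = w.reshape(groups, cout // groups, k)
        out = np.matmul(w_g[None], cols_g).reshape(n, cout, hout * wout)
    return out.reshape(n, cout, hout, wout), cols


def conv2d_backward(gout: np.ndarray, x: np.ndarray, w: np.ndarray,
                    cols: np.ndarray, stride: int, padding: int, dilation: int,
                    groups: int, need_dx: bool = True, need_dw: bool = True):
    """Gradients of conv2d w.r.t. input and weights given the output gradient."""
    n, cin, h, wdt = x.shape
    cout, cin_g, kh, kw = w.shape
    k = cin_g * kh * kw
    hout, wout = gout.shape[2], gout.shape[3]
    dx = dw = None
    l = hout * wout
    g_g = gout.reshape(n, groups, cout // groups, l)
    cols_g = cols.reshape(n, groups, k, l)
    w_g = w.reshape(groups, cout // groups, k)
    if need_dw:
        if groups == 1:
            # fold batch and spatial axes into one big matmul
            gt = np.ascontiguousarray(g_g[:, 0].transpose(1, 0, 2)).reshape(cout, n * l)
            ct = np.ascontiguousarray(cols_g[:, 0].transpose(1, 0, 2)).reshape(k, n * l)
            dw = (gt @ ct.T).reshape(w.shape)
        else:
            gt = np.ascontiguousarray(g_g.transpose(1, 2, 0, 3)).reshape(
                groups, cout // groups, n * l)
            ct = np.ascontiguousarray(cols_g.transpose(1, 0, 3, 2)).reshape(
                groups, n * l, k)
            dw = np.matmul(gt, ct).reshape(w.shape)
    if need_dx:
        dcols = np.matmul(np.swapaxes(w_g, 1, 2)[None], g_g)   # (N, G, K, L)
        dx = col2im(dcols.reshape(n, cin * kh * kw, l),
                    x.shape, kh, kw, stride, padding, dilation)
    return dx, dw
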