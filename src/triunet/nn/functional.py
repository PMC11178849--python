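"""Volumetric neural-network primitives with hand-derived adjoints.

Convolution lowers to GEMM through an im2col gather that is chunked along the
output depth axis so the scratch column matrix stays below a fixed byte
budget even for upsampled feature maps. The trilinear upsampling operator is
linear, so its gradient is the transpose operator, applied axis by axis.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, _make

# upper bound on the im2col scratch buffer; keeps peak memory flat when the
# Trible-Res-Block upsampling path convolves 2x-enlarged feature maps
_MAX_COLS_BYTES = 160 * 1024 * 1024


def _slab_depths(d_out: int, row_bytes: int) -> int:
    rows = max(1, _MAX_COLS_BYTES // max(row_bytes, 1))
    return max(1, min(d_out, rows))


def _pad5(arr: np.ndarray, p: int) -> np.ndarray:
    if p == 0:
        return arr
    return np.pad(arr, ((0, 0), (p, p), (p, p), (p, p), (0, 0)))


def _cols_slab(xp_n: np.ndarray, d0: int, d1: int, k: int, s: int, ho: int, wo: int) -> np.ndarray:
    """im2col for one item's output depths [d0, d1): rows x (k^3 * C)."""
    c = xp_n.shape[-1]
    sl = xp_n[s * d0 : s * (d1 - 1) + k]
    win = np.lib.stride_tricks.sliding_window_view(sl, (k, k, k), axis=(0, 1, 2))
    win = win[::s, ::s, ::s]  # (d1-d0, ho, wo, C, k, k, k)
    # channels innermost: (k3, C) becomes a unit-stride run, so the gather
    # copy degenerates to memcpy chunks rather than scalar loads
    win = win.transpose(0, 1, 2, 4, 5, 6, 3)
    return win.reshape((d1 - d0) * ho * wo, k * k * k * c)


def _cols_batch(xp: np.ndarray, k: int, s: int, do: int, ho: int, wo: int) -> np.ndarray:
    """im2col over the whole batch at once (small feature maps)."""
    n, c = xp.shape[0], xp.shape[-1]
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k, k), axis=(1, 2, 3))
    win = win[:, ::s, ::s, ::s]  # (N, do, ho, wo, C, k, k, k)
    win = win.transpose(0, 1, 2, 3, 5, 6, 7, 4)
    return win.reshape(n * do * ho * wo, k * k * k * c)


def _conv_raw(xin: np.ndarray, w2: np.ndarray, k: int, s: int, p: int) -> np.ndarray:
    """Plain convolution on a raw array; w2 is (k^3*C, O)."""
    n, d, h, wd, c = xin.shape
    o = w2.shape[1]
    do = (d + 2 * p - k) // s + 1
    ho = (h + 2 * p - k) // s + 1
    wo = (wd + 2 * p - k) // s + 1
    xp = _pad5(xin, p)
    total_bytes = n * do * ho * wo * (k ** 3 * c) * 4
    if total_bytes <= _MAX_COLS_BYTES:
        return (_cols_batch(xp, k, s, do, ho, wo) @ w2).reshape(n, do, ho, wo, o)
    out = np.empty((n, do, ho, wo, o), dtype=np.float32)
    slab = _slab_depths(do, ho * wo * (k ** 3 * c) * 4)
    for i in range(n):
        for d0 in range(0, do, slab):
            d1 = min(d0 + slab, do)
            y = _cols_slab(xp[i], d0, d1, k, s, ho, wo) @ w2
            out[i, d0:d1] = y.reshape(d1 - d0, ho, wo, o)
    return out


def conv3d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1, pad: int = 1) -> Tensor:
    """3D cross-correlation, channels-last.

    ``x``: (N, D, H, W, C); ``w``: (k, k, k, C, O); ``b``: (O,) or None.
    Forward and both adjoints lower onto im2col + GEMM; for unit stride the
    input gradient is itself a convolution with spatially flipped, channel-
    transposed weights, which reuses the same fast path.
    """
    n, d, h, wd, c = x.data.shape
    k = w.data.shape[0]
    o = w.data.shape[-1]
    s, p = stride, pad
    do = (d + 2 * p - k) // s + 1
    ho = (h + 2 * p - k) // s + 1
    wo = (wd + 2 * p - k) // s + 1
    if min(do, ho, wo) < 1:
        raise ValueError(
            f"conv3d: spatial dims {(d, h, wd)} too small for kernel {k}, stride {s}, pad {p}"
        )
    w2 = w.data.reshape(k * k * k * c, o)
    out = _conv_raw(x.data, w2, k, s, p)
    if b is not None:
        out += b.data

    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        g = np.ascontiguousarray(g, dtype=np.float32)
        if b is not None:
            b.accumulate(g.sum(axis=(0, 1, 2, 3)))
        xp = _pad5(x.data, p)
        # weight gradient: cols^T @ g, slab-chunked
        gw2 = np.zeros_like(w2)
        g2 = g.reshape(n, do * ho * wo, o)
        total_bytes = n * do * ho * wo * (k ** 3 * c) * 4
        if total_bytes <= _MAX_COLS_BYTES:
            gw2 += _cols_batch(xp, k, s, do, ho, wo).T @ g2.reshape(-1, o)
        else:
            slab = _slab_depths(do, ho * wo * (k ** 3 * c) * 4)
            for i in range(n):
                for d0 in range(0, do, slab):
                    d1 = min(d0 + slab, do)
                    cols = _cols_slab(xp[i], d0, d1, k, s, ho, wo)
                    gw2 += cols.T @ g[i, d0:d1].reshape(-1, o)
        w.accumulate(gw2.reshape(w.data.shape))
        if s == 1:
            # transposed convolution: flip kernel, swap C and O
            wt = w.data[::-1, ::-1, ::-1].transpose(0, 1, 2, 4, 3)
            wt2 = np.ascontiguousarray(wt).reshape(k * k * k * o, c)
            x.accumulate(_conv_raw(g, wt2, k, 1, k - 1 - p))
        else:
            gxp = np.zeros_like(xp)
            slab = _slab_depths(do, ho * wo * (k ** 3 * c) * 4)
            for i in range(n):
                for d0 in range(0, do, slab):
                    d1 = min(d0 + slab, do)
                    gslab = g[i, d0:d1].reshape(-1, o)
                    gcols = (gslab @ w2.T).reshape(d1 - d0, ho, wo, k, k, k, c)
                    for ki in range(k):
                        dlo = s * d0 + ki
                        dhi = dlo + s * (d1 - d0)
                        for kj in range(k):
                            for kl in range(k):
                                gxp[
                                    i, dlo:dhi:s, kj : kj + s * ho : s, kl : kl + s * wo : s
                                ] += gcols[:, :, :, ki, kj, kl, :]
            if p == 0:
                x.accumulate(gxp)
            else:
                x.accumulate(gxp[:, p:-p, p:-p, p:-p])

    return _make(out, parents, backward)


def maxpool2(x: Tensor) -> Tensor:
    """2x2x2 max pooling, stride 2, channels-last; requires even spatial dims."""
    n, d, h, w, c = x.data.shape
    if d % 2 or h % 2 or w % 2:
        raise ValueError(f"maxpool2 requires even spatial dims, got {(d, h, w)}")
    d2, h2, w2 = d // 2, h // 2, w // 2
    r = (
        x.data.reshape(n, d2, 2, h2, 2, w2, 2, c)
        .transpose(0, 1, 3, 5, 7, 2, 4, 6)
        .reshape(n, d2, h2, w2, c, 8)
    )
    idx = r.argmax(axis=-1)
    out = np.take_along_axis(r, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        g8 = np.zeros((n, d2, h2, w2, c, 8), dtype=np.float32)
        np.put_along_axis(g8, idx[..., None], g[..., None], axis=-1)
        gx = (
            g8.reshape(n, d2, h2, w2, c, 2, 2, 2)
            .transpose(0, 1, 5, 2, 6, 3, 7, 4)
            .reshape(n, d, h, w, c)
        )
        x.accumulate(gx)

    return _make(out, (x,), backward)


def _lin_up(a: np.ndarray, axis: int) -> np.ndarray:
    """Factor-2 linear interpolation along ``axis`` (half-voxel-shift sampling)."""
    a = np.swapaxes(a, 1, axis)
    left = np.concatenate([a[:, :1], a[:, :-1]], axis=1)
    right = np.concatenate([a[:, 1:], a[:, -1:]], axis=1)
    shape = list(a.shape)
    shape[1] *= 2
    out = np.empty(shape, dtype=np.float32)
    out[:, 0::2] = 0.75 * a + 0.25 * left
    out[:, 1::2] = 0.75 * a + 0.25 * right
    return np.swapaxes(out, 1, axis)


def _lin_up_t(g: np.ndarray, axis: int) -> np.ndarray:
    """Transpose (adjoint) of :func:`_lin_up` along ``axis``."""
    g = np.swapaxes(g, 1, axis)
    ge = g[:, 0::2]
    go = g[:, 1::2]
    gx = (0.75 * (ge + go)).astype(np.float32)
    gx[:, 1:] += 0.25 * go[:, :-1]
    gx[:, :-1] += 0.25 * ge[:, 1:]
    gx[:, :1] += 0.25 * ge[:, :1]
    gx[:, -1:] += 0.25 * go[:, -1:]
    return np.swapaxes(gx, 1, axis)


def upsample2(x: Tensor) -> Tensor:
    """Trilinear 2x upsampling over the three spatial axes of (N, D, H, W, C)."""
    out = x.data
    for ax in (1, 2, 3):
        out = _lin_up(out, ax)

    def backward(g):
        for ax in (3, 2, 1):
            g = _lin_up_t(g, ax)
        x.accumulate(g)

    return _make(out, (x,), backward)


def group_norm(x: Tensor, gamma: Tensor, beta: Tensor, groups: int, eps: float = 1e-5) -> Tensor:
    """Group normalization over (spatial, channels-in-group), channels-last.

    Statistics are per sample, so evaluation is batch-size independent.
    """
    n, d, h, w, c = x.data.shape
    if c % groups:
        raise ValueError(f"channels {c} not divisible by groups {groups}")
    cg = c // groups
    s = d * h * w
    xr = x.data.reshape(n, s, groups, cg)
    mu = xr.mean(axis=(1, 3), keepdims=True)
    var = xr.var(axis=(1, 3), keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (xr - mu) * inv
    xhat_full = xhat.reshape(n, d, h, w, c)
    out = xhat_full * gamma.data + beta.data

    def backward(g):
        gamma.accumulate((g * xhat_full).sum(axis=(0, 1, 2, 3)))
        beta.accumulate(g.sum(axis=(0, 1, 2, 3)))
        gr = (g * gamma.data).reshape(n, s, groups, cg)
        m1 = gr.mean(axis=(1, 3), keepdims=True)
        m2 = (gr * xhat).mean(axis=(1, 3), keepdims=True)
        gx = (inv * (gr - m1 - xhat * m2)).reshape(n, d, h, w, c)
        x.accumulate(gx.astype(np.float32))

    return _make(out, (x, gamma, beta), backward)
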