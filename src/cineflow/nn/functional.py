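"""Structured differentiable ops: convolution, pooling, resampling, warping.

All image tensors follow the (N, C, H, W) layout.  Displacement fields follow
the package-wide convention: ``flow[..., 0]`` is a row offset, ``flow[..., 1]``
a column offset, and warping samples the source at ``p + flow(p)`` with
edge-clamped coordinates.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .tensor import Tensor, _GRAD_ENABLED  # noqa: F401


def _windows(xp: np.ndarray, kh: int, kw: int, stride: int) -> np.ndarray:
    """(N, C, Hp, Wp) -> (N, C, Ho, Wo, kh, kw) view."""
    w = sliding_window_view(xp, (kh, kw), axis=(2, 3))
    return w[:, :, ::stride, ::stride]


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None,
           stride: int = 1, padding: int = 0, groups: int = 1) -> Tensor:
    """2D convolution (cross-correlation). weight: (O, C//groups, kh, kw).

    Implemented as shift-and-accumulate over kernel offsets (one BLAS product
    per offset), which beats im2col at the small spatial sizes used here.
    Supported group settings: dense (groups=1) and depth-wise (groups=C).
    """
    N, C, H, W = x.shape
    O, Cg, kh, kw = weight.shape
    if not (groups == 1 or (groups == C and O == C and Cg == 1)):
        raise NotImplementedError("only dense or depth-wise convolutions")
    assert C == Cg * groups
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    Ho = (H + 2 * padding - kh) // stride + 1
    Wo = (W + 2 * padding - kw) // stride + 1
    depthwise = groups != 1
    wd = weight.data
    if depthwise:
        out_data = np.zeros((N, O, Ho, Wo), dtype=np.float32)
        for i in range(kh):
            for j in range(kw):
                xs = xp[:, :, i:i + Ho * stride:stride, j:j + Wo * stride:stride]
                out_data += xs * wd[None, :, 0, i, j, None, None]
    else:
        acc = np.zeros((N, Ho, Wo, O), dtype=np.float32)
        for i in range(kh):
            for j in range(kw):
                xs = xp[:, :, i:i + Ho * stride:stride, j:j + Wo * stride:stride]
                # (N, Ho, Wo, C) @ (C, O)
                acc += np.tensordot(xs, wd[:, :, i, j], axes=([1], [1]))
        out_data = np.ascontiguousarray(acc.transpose(0, 3, 1, 2))
    if bias is not None:
        out_data = out_data + bias.data.reshape(1, O, 1, 1)

    parents = (x, weight) if bias is None else (x, weight, bias)

    def backward(g):
        if bias is not None and bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 2, 3)))
        need_x = x.requires_grad
        need_w = weight.requires_grad
        if not (need_x or need_w):
            return
        gxp = np.zeros_like(xp) if need_x else None
        gw = np.zeros_like(wd) if need_w else None
        g_nhwo = None if depthwise else np.ascontiguousarray(
            g.transpose(0, 2, 3, 1))
        for i in range(kh):
            for j in range(kw):
                sl = (slice(None), slice(None),
                      slice(i, i + Ho * stride, stride),
                      slice(j, j + Wo * stride, stride))
                if depthwise:
                    if need_w:
                        gw[:, 0, i, j] = (g * xp[sl]).sum(axis=(0, 2, 3))
                    if need_x:
                        gxp[sl] += g * wd[None, :, 0, i, j, None, None]
                else:
                    if need_w:
                        # (O, C) <- sum_nhw g(N,Ho,Wo,O)^T xs(N,?,Ho,Wo)
                        gw[:, :, i, j] = np.tensordot(
                            g_nhwo, xp[sl], axes=([0, 1, 2], [0, 2, 3]))
                    if need_x:
                        gxp[sl] += np.tensordot(
                            g_nhwo, wd[:, :, i, j], axes=([3], [0])
                        ).transpose(0, 3, 1, 2)
        if need_w:
            weight._accumulate(gw)
        if need_x:
            if padding:
                gxp = gxp[:, :, padding:-padding, padding:-padding]
            x._accumulate(gxp)

    return x._make(out_data, parents, backward)


def conv_transpose2d(x: Tensor, weight: Tensor, bias: Tensor | None = None,
                     stride: int = 2) -> Tensor:
    """Transposed convolution, weight: (C_in, C_out, kh, kw), no padding."""
    N, C, H, W = x.shape
    Ci, O, kh, kw = weight.shape
    assert C == Ci
    Ho = (H - 1) * stride + kh
    Wo = (W - 1) * stride + kw
    t = np.einsum("nchw,coij->noijhw", x.data, weight.data, optimize=True)
    out_data = np.zeros((N, O, Ho, Wo), dtype=np.float32)
    for i in range(kh):
        for j in range(kw):
            out_data[:, :, i:i + (H - 1) * stride + 1:stride,
                     j:j + (W - 1) * stride + 1:stride] += t[:, :, i, j]
    if bias is not None:
        out_data = out_data + bias.data.reshape(1, O, 1, 1)

    parents = (x, weight) if bias is None else (x, weight, bias)

    def backward(g):
        if bias is not None and bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 2, 3)))
        gx = np.zeros_like(x.data) if x.requires_grad else None
        gw = np.zeros_like(weight.data) if weight.requires_grad else None
        for i in range(kh):
            for j in range(kw):
                sub = g[:, :, i:i + (H - 1) * stride + 1:stride,
                        j:j + (W - 1) * stride + 1:stride]  # (N, O, H, W)
                if gx is not None:
                    gx += np.einsum("nohw,co->nchw", sub, weight.data[:, :, i, j],
                                    optimize=True)
                if gw is not None:
                    gw[:, :, i, j] += np.einsum("nchw,nohw->co", x.data, sub,
                                                optimize=True)
        if gx is not None:
            x._accumulate(gx)
        if gw is not None:
            weight._accumulate(gw)

    return x._make(out_data, parents, backward)


def max_pool2d(x: Tensor, k: int = 2) -> Tensor:
    N, C, H, W = x.shape
    assert H % k == 0 and W % k == 0
    r = x.data.reshape(N, C, H // k, k, W // k, k)
    out_data = r.max(axis=(3, 5))
    mask = r == out_data[:, :, :, None, :, None]

    def backward(g):
        if x.requires_grad:
            gexp = mask * g[:, :, :, None, :, None]
            x._accumulate(gexp.reshape(N, C, H, W))

    return x._make(out_data, (x,), backward)


def avg_pool2d(x: Tensor, k: int = 2) -> Tensor:
    """Average pooling over the last two axes; odd trailing rows/columns are
    dropped (floor behaviour), so odd-sized grids pool like their even crop."""
    H, W = x.shape[-2:]
    H2, W2 = (H // k) * k, (W // k) * k
    if (H2, W2) != (H, W):
        x = x[..., :H2, :W2]
    r = x.reshape(*x.shape[:-2], H2 // k, k, W2 // k, k)
    return r.mean(axis=(-3, -1))


def upsample_bilinear(x: Tensor, scale: int) -> Tensor:
    """Bilinear upsampling by an integer factor (align_corners=False style)."""
    N, C, H, W = x.shape
    Ho, Wo = H * scale, W * scale
    rows = (np.arange(Ho, dtype=np.float32) + 0.5) / scale - 0.5
    cols = (np.arange(Wo, dtype=np.float32) + 0.5) / scale - 0.5
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    return sample_at(x, rr, cc)


def sample_at(x: Tensor, rr: np.ndarray, cc: np.ndarray) -> Tensor:
    """Bilinearly sample (N, C, H, W) at fixed (non-differentiable) positions."""
    N, C, H, W = x.shape
    r = np.clip(rr, 0, H - 1)
    c = np.clip(cc, 0, W - 1)
    r0 = np.floor(r).astype(np.int64)
    c0 = np.floor(c).astype(np.int64)
    r1 = np.minimum(r0 + 1, H - 1)
    c1 = np.minimum(c0 + 1, W - 1)
    fr = (r - r0).astype(np.float32)
    fc = (c - c0).astype(np.float32)
    w00 = (1 - fr) * (1 - fc)
    w01 = (1 - fr) * fc
    w10 = fr * (1 - fc)
    w11 = fr * fc
    xd = x.data
    out_data = (xd[:, :, r0, c0] * w00 + xd[:, :, r0, c1] * w01
                + xd[:, :, r1, c0] * w10 + xd[:, :, r1, c1] * w11)

    def backward(g):
        if not x.requires_grad:
            return
        gx = np.zeros_like(xd)
        flat = gx.reshape(N, C, H * W)
        np.add.at(flat, (slice(None), slice(None), (r0 * W + c0).ravel()),
                  (g * w00).reshape(N, C, -1))
        np.add.at(flat, (slice(None), slice(None), (r0 * W + c1).ravel()),
                  (g * w01).reshape(N, C, -1))
        np.add.at(flat, (slice(None), slice(None), (r1 * W + c0).ravel()),
                  (g * w10).reshape(N, C, -1))
        np.add.at(flat, (slice(None), slice(None), (r1 * W + c1).ravel()),
                  (g * w11).reshape(N, C, -1))
        x._accumulate(gx)

    return x._make(out_data, (x,), backward)


def warp(x: Tensor, flow: Tensor) -> Tensor:
    """Differentiable backward warp: out(p) = x(p + flow(p)), edge-clamped.

    x: (N, C, H, W); flow: (N, H, W, 2) in (row, col) pixel offsets.
    Differentiable in both the source image and the flow.
    """
    N, C, H, W = x.shape
    assert flow.shape == (N, H, W, 2), (flow.shape, x.shape)
    base_r, base_c = np.meshgrid(np.arange(H, dtype=np.float32),
                                 np.arange(W, dtype=np.float32), indexing="ij")
    r = base_r[None] + flow.data[..., 0]
    c = base_c[None] + flow.data[..., 1]
    in_r = (r >= 0) & (r <= H - 1)
    in_c = (c >= 0) & (c <= W - 1)
    r = np.clip(r, 0, H - 1)
    c = np.clip(c, 0, W - 1)
    r0 = np.floor(r).astype(np.int64)
    c0 = np.floor(c).astype(np.int64)
    r1 = np.minimum(r0 + 1, H - 1)
    c1 = np.minimum(c0 + 1, W - 1)
    fr = (r - r0).astype(np.float32)
    fc = (c - c0).astype(np.float32)
    w00 = ((1 - fr) * (1 - fc))[:, None]
    w01 = ((1 - fr) * fc)[:, None]
    w10 = (fr * (1 - fc))[:, None]
    w11 = (fr * fc)[:, None]
    xd = x.data
    # gather the four corners per batch element
    g00 = np.stack([xd[n][:, r0[n], c0[n]] for n in range(N)])
    g01 = np.stack([xd[n][:, r0[n], c1[n]] for n in range(N)])
    g10 = np.stack([xd[n][:, r1[n], c0[n]] for n in range(N)])
    g11 = np.stack([xd[n][:, r1[n], c1[n]] for n in range(N)])
    out_data = g00 * w00 + g01 * w01 + g10 * w10 + g11 * w11

    def backward(g):
        if x.requires_grad:
            gx = np.zeros_like(xd)
            for n in range(N):
                flat = gx[n].reshape(C, H * W)
                np.add.at(flat, (slice(None), (r0[n] * W + c0[n]).ravel()),
                          (g[n] * w00[n]).reshape(C, -1))
                np.add.at(flat, (slice(None), (r0[n] * W + c1[n]).ravel()),
                          (g[n] * w01[n]).reshape(C, -1))
                np.add.at(flat, (slice(None), (r1[n] * W + c0[n]).ravel()),
                          (g[n] * w10[n]).reshape(C, -1))
                np.add.at(flat, (slice(None), (r1[n] * W + c1[n]).ravel()),
                          (g[n] * w11[n]).reshape(C, -1))
            x._accumulate(gx)
        if flow.requires_grad:
            # d out / d r = (g10 + fc*(g11-g10-g01+g00_terms)) ... standard bilinear
            d_dr = ((g10 - g00) * (1 - fc)[:, None] + (g11 - g01) * fc[:, None])
            d_dc = ((g01 - g00) * (1 - fr)[:, None] + (g11 - g10) * fr[:, None])
            gr = (g * d_dr).sum(axis=1) * in_r
            gc = (g * d_dc).sum(axis=1) * in_c
            gf = np.stack([gr, gc], axis=-1)
            flow._accumulate(gf)

    return x._make(out_data, (x, flow), backward)


def sample_points(x: Tensor, pos: Tensor) -> Tensor:
    """Bilinearly sample P points per batch element.

    x: (N, C, H, W); pos: (N, P, 2) absolute (row, col) positions, edge
    clamped.  Returns (N, C, P).  Differentiable in both arguments; the
    position gradient is zeroed where the sample was clamped.
    """
    N, C, H, W = x.shape
    _, P, _ = pos.shape
    r = pos.data[..., 0]
    c = pos.data[..., 1]
    in_r = (r >= 0) & (r <= H - 1)
    in_c = (c >= 0) & (c <= W - 1)
    r = np.clip(r, 0, H - 1)
    c = np.clip(c, 0, W - 1)
    r0 = np.floor(r).astype(np.int64)
    c0 = np.floor(c).astype(np.int64)
    r1 = np.minimum(r0 + 1, H - 1)
    c1 = np.minimum(c0 + 1, W - 1)
    fr = (r - r0).astype(np.float32)
    fc = (c - c0).astype(np.float32)
    w00 = ((1 - fr) * (1 - fc))[:, None]   # (N, 1, P)
    w01 = ((1 - fr) * fc)[:, None]
    w10 = (fr * (1 - fc))[:, None]
    w11 = (fr * fc)[:, None]
    xf = x.data.reshape(N, C, H * W)
    i00 = (r0 * W + c0)[:, None]
    i01 = (r0 * W + c1)[:, None]
    i10 = (r1 * W + c0)[:, None]
    i11 = (r1 * W + c1)[:, None]
    g00 = np.take_along_axis(xf, np.broadcast_to(i00, (N, C, P)), axis=2)
    g01 = np.take_along_axis(xf, np.broadcast_to(i01, (N, C, P)), axis=2)
    g10 = np.take_along_axis(xf, np.broadcast_to(i10, (N, C, P)), axis=2)
    g11 = np.take_along_axis(xf, np.broadcast_to(i11, (N, C, P)), axis=2)
    out_data = g00 * w00 + g01 * w01 + g10 * w10 + g11 * w11

    def backward(g):
        if x.requires_grad:
            gx = np.zeros((N, C, H * W), dtype=np.float32)
            n_idx = np.arange(N)[:, None, None]
            c_idx = np.arange(C)[None, :, None]
            np.add.at(gx, (n_idx, c_idx, i00), g * w00)
            np.add.at(gx, (n_idx, c_idx, i01), g * w01)
            np.add.at(gx, (n_idx, c_idx, i10), g * w10)
            np.add.at(gx, (n_idx, c_idx, i11), g * w11)
            x._accumulate(gx.reshape(N, C, H, W))
        if pos.requires_grad:
            d_dr = (g10 - g00) * (1 - fc)[:, None] + (g11 - g01) * fc[:, None]
            d_dc = (g01 - g00) * (1 - fr)[:, None] + (g11 - g10) * fr[:, None]
            gr = (g * d_dr).sum(axis=1) * in_r
            gc = (g * d_dc).sum(axis=1) * in_c
            pos._accumulate(np.stack([gr, gc], axis=-1))

    return x._make(out_data, (x, pos), backward)


def batch_norm2d(x: Tensor, gamma: Tensor, beta: Tensor,
                 running_mean: np.ndarray, running_var: np.ndarray,
                 training: bool, momentum: float = 0.1,
                 eps: float = 1e-5) -> Tensor:
    """Batch normalization over (N, H, W) per channel; updates running stats."""
    if training:
        mu = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        running_mean += momentum * (mu - running_mean)
        running_var += momentum * (var - running_var)
        mean_t = x.mean(axis=(0, 2, 3), keepdims=True)
        centered = x - mean_t
        var_t = (centered * centered).mean(axis=(0, 2, 3), keepdims=True)
        inv = (var_t + eps) ** -0.5
        xhat = centered * inv
    else:
        mu = running_mean.reshape(1, -1, 1, 1)
        inv = 1.0 / np.sqrt(running_var.reshape(1, -1, 1, 1) + eps)
        xhat = (x - Tensor(mu)) * Tensor(inv.astype(np.float32))
    return xhat * gamma.reshape(1, -1, 1, 1) + beta.reshape(1, -1, 1, 1)
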