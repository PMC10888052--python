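"""Differentiable volumetric operations: 3D convolution, GroupNorm, trilinear resampling.

Convolution is im2col + matmul (grouped, so depthwise and pointwise fall out of
the same kernel); 1x1x1 convolutions take a cheaper pure-matmul path.
Resampling follows half-pixel-center ("align_corners=False") semantics, which
makes power-of-two down/up scaling exact for constant fields.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .autograd import Tensor


def conv3d(x: Tensor, w: Tensor, b: Tensor | None = None, *, padding: int = 0,
           groups: int = 1, pad_mode: str = "zeros") -> Tensor:
    """Grouped 3D convolution, stride 1.

    x: (B, Cin, H, W, D); w: (Cout, Cin//groups, k, k, k); b: (Cout,) or None.
    pad_mode 'zeros' or 'edge' (replicate; used by gate convolutions so that a
    constant field yields a constant response).
    """
    B, Cin, H, W, D = x.shape
    Cout, Cg, k, _, _ = w.shape
    G = groups
    if Cin != Cg * G:
        raise ValueError(f"channel mismatch: input has {Cin}, kernel expects {Cg * G}")
    if k == 1 and G == 1:
        return _pointwise(x, w, b)

    pad = padding
    np_mode = {"zeros": "constant", "edge": "edge"}[pad_mode]
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad), (pad, pad)),
                mode=np_mode)
    Ho, Wo, Do = H + 2 * pad - k + 1, W + 2 * pad - k + 1, D + 2 * pad - k + 1
    P, K = Ho * Wo * Do, k ** 3
    cols = sliding_window_view(xp, (k, k, k), axis=(2, 3, 4))
    # (B, Cin, Ho, Wo, Do, k,k,k) -> (B, G, P, Cg*K)
    colm = np.ascontiguousarray(cols).reshape(B, G, Cg, P, K)
    colm = colm.transpose(0, 1, 3, 2, 4).reshape(B, G, P, Cg * K)
    wm = w.data.reshape(G, Cout // G, Cg * K)
    out = np.einsum("bgpk,gok->bgop", colm, wm, optimize=True)
    out = out.reshape(B, Cout, Ho, Wo, Do)
    if b is not None:
        out = out + b.data.reshape(1, Cout, 1, 1, 1)

    parents = (x, w) if b is None else (x, w, b)

    def vjp(g):
        gm = g.reshape(B, G, Cout // G, P)
        grad_w = np.einsum("bgop,bgpk->gok", gm, colm, optimize=True).reshape(w.shape)
        need_gx = x.requires_grad or x._vjp is not None
        grad_x = None
        if need_gx:
            gcol = np.einsum("bgop,gok->bgpk", gm, wm, optimize=True)
            gcol = gcol.reshape(B, G, P, Cg, K).transpose(0, 1, 3, 2, 4)
            gcol = gcol.reshape(B, Cin, Ho, Wo, Do, k, k, k)
            gxp = np.zeros_like(xp)
            for i in range(k):
                for j in range(k):
                    for l in range(k):
                        gxp[:, :, i:i + Ho, j:j + Wo, l:l + Do] += gcol[..., i, j, l]
            if pad and pad_mode == "edge":
                # fold replicate-padding gradients back onto the edge voxels
                for ax in (2, 3, 4):
                    sl = [slice(None)] * 5
                    sl_edge = [slice(None)] * 5
                    sl[ax], sl_edge[ax] = slice(0, pad), slice(pad, pad + 1)
                    gxp[tuple(sl_edge)] += gxp[tuple(sl)].sum(axis=ax, keepdims=True)
                    sl[ax], sl_edge[ax] = slice(-pad, None), slice(-pad - 1, -pad)
                    gxp[tuple(sl_edge)] += gxp[tuple(sl)].sum(axis=ax, keepdims=True)
            grad_x = gxp[:, :, pad:pad + H, pad:pad + W, pad:pad + D] if pad else gxp
        if b is None:
            return (grad_x, grad_w)
        return (grad_x, grad_w, g.sum(axis=(0, 2, 3, 4)))

    return Tensor._make(out, parents, vjp)


def _pointwise(x: Tensor, w: Tensor, b: Tensor | None) -> Tensor:
    """1x1x1 convolution as a channel matmul."""
    B, Cin, H, W, D = x.shape
    Cout = w.shape[0]
    wm = w.data.reshape(Cout, Cin)
    out = np.einsum("oc,bchwd->bohwd", wm, x.data, optimize=True)
    if b is not None:
        out = out + b.data.reshape(1, Cout, 1, 1, 1)
    parents = (x, w) if b is None else (x, w, b)

    def vjp(g):
        grad_w = np.einsum("bohwd,bchwd->oc", g, x.data, optimize=True).reshape(w.shape)
        grad_x = np.einsum("oc,bohwd->bchwd", wm, g, optimize=True)
        if b is None:
            return (grad_x, grad_w)
        return (grad_x, grad_w, g.sum(axis=(0, 2, 3, 4)))

    return Tensor._make(out, parents, vjp)


def group_norm(x: Tensor, num_groups: int, gamma: Tensor, beta: Tensor,
               eps: float = 1e-5) -> Tensor:
    B, C = x.shape[:2]
    if C % num_groups:
        raise ValueError(f"groups {num_groups} must divide channels {C}")
    spatial = x.shape[2:]
    xg = x.data.reshape(B, num_groups, -1)
    mu = xg.mean(axis=2, keepdims=True)
    var = xg.var(axis=2, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = ((xg - mu) * inv).reshape(x.shape)
    gshape = (1, C) + (1,) * len(spatial)
    out = xhat * gamma.data.reshape(gshape) + beta.data.reshape(gshape)

    def vjp(g):
        sum_ax = (0,) + tuple(range(2, x.ndim))
        grad_gamma = (g * xhat).sum(axis=sum_ax)
        grad_beta = g.sum(axis=sum_ax)
        gxh = (g * gamma.data.reshape(gshape)).reshape(B, num_groups, -1)
        xh = xhat.reshape(B, num_groups, -1)
        m1 = gxh.mean(axis=2, keepdims=True)
        m2 = (gxh * xh).mean(axis=2, keepdims=True)
        grad_x = ((gxh - m1 - xh * m2) * inv).reshape(x.shape)
        return (grad_x.astype(np.float32), grad_gamma, grad_beta)

    return Tensor._make(out.astype(np.float32), (x, gamma, beta), vjp)


def _axis_weights(n_in: int, n_out: int):
    """Linear-interpolation source indices/weights, half-pixel-center convention."""
    coord = (np.arange(n_out, dtype=np.float64) + 0.5) * (n_in / n_out) - 0.5
    i0 = np.clip(np.floor(coord).astype(np.int64), 0, n_in - 1)
    i1 = np.minimum(i0 + 1, n_in - 1)
    w1 = np.clip(coord - np.floor(coord), 0.0, 1.0).astype(np.float32)
    w1[coord < 0] = 0.0
    return i0, i1, w1


def _resample_axis(x: Tensor, axis: int, n_out: int) -> Tensor:
    n_in = x.shape[axis]
    if n_in == n_out:
        return x
    i0, i1, w1 = _axis_weights(n_in, n_out)
    wshape = [1] * x.ndim
    wshape[axis] = n_out
    w1b = w1.reshape(wshape)
    out = (np.take(x.data, i0, axis=axis) * (1.0 - w1b)
           + np.take(x.data, i1, axis=axis) * w1b)

    def vjp(g):
        gm = np.moveaxis(g, axis, 0)
        wv = w1.reshape((n_out,) + (1,) * (g.ndim - 1))
        shape = list(g.shape)
        shape[axis] = n_in
        full = np.zeros((n_in,) + gm.shape[1:], dtype=np.float32)
        np.add.at(full, i0, gm * (1.0 - wv))
        np.add.at(full, i1, gm * wv)
        return (np.moveaxis(full, 0, axis),)

    return Tensor._make(out.astype(np.float32), (x,), vjp)


def interpolate_trilinear(x: Tensor, size: tuple[int, int, int]) -> Tensor:
    """Resample a (B, C, H, W, D) volume to spatial `size` by separable linear interpolation."""
    out = x
    for ax, n in zip((2, 3, 4), size):
        out = _resample_axis(out, ax, n)
    return out
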