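"""Differentiable volumetric network primitives.

3D convolution is implemented as a strided-view gather followed by a BLAS
``tensordot`` (im2col), with the input-gradient scatter looping over the
k^3 kernel taps; this is the fastest layout pure NumPy offers for the
patch sizes this package trains on.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import as_strided

from .tensor import Tensor, _PENDING, _acc, _make, as_tensor


def _triple(v) -> tuple[int, int, int]:
    if np.isscalar(v):
        return (int(v),) * 3
    t = tuple(int(x) for x in v)
    assert len(t) == 3
    return t


def conv3d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride=1, dilation=1, padding=None) -> Tensor:
    """3D cross-correlation over a (N, C, X, Y, Z) tensor.

    ``padding`` defaults to ``dilation * (k - 1) // 2`` per axis ("same"
    for odd kernels at stride 1; with ``stride=2`` output dims are
    ``ceil(dim / 2)``). Dilation inserts ``d - 1`` zeros between kernel
    taps, enlarging the receptive field at constant parameter count.
    """
    x, w = as_tensor(x), as_tensor(w)
    s, d = _triple(stride), _triple(dilation)
    kc = w.shape[2:]
    if padding is None:
        p = tuple(d[i] * (kc[i] - 1) // 2 for i in range(3))
    else:
        p = _triple(padding)

    dt = np.result_type(x.data.dtype, w.data.dtype, np.float32)
    xd = np.ascontiguousarray(x.data, dtype=dt)
    wd = np.ascontiguousarray(w.data, dtype=dt)
    xp = np.pad(xd, ((0, 0), (0, 0), (p[0], p[0]), (p[1], p[1]), (p[2], p[2])))
    N, C = xp.shape[:2]
    sp = xp.strides
    out_dims = tuple((xp.shape[2 + i] - d[i] * (kc[i] - 1) - 1) // s[i] + 1 for i in range(3))
    view = as_strided(
        xp,
        shape=(N, C) + out_dims + kc,
        strides=(sp[0], sp[1],
                 s[0] * sp[2], s[1] * sp[3], s[2] * sp[4],
                 d[0] * sp[2], d[1] * sp[3], d[2] * sp[4]),
        writeable=False)
    # (N, Ox, Oy, Oz, Cout)
    out = np.tensordot(view, wd, axes=([1, 5, 6, 7], [1, 2, 3, 4]))
    if b is not None:
        out = out + b.data
    out = np.ascontiguousarray(np.moveaxis(out, -1, 1))

    parents = (x, w) if b is None else (x, w, b)
    res = _make(out, parents)
    if res._backward is _PENDING:
        def bw(g):
            gm = np.moveaxis(g, 1, -1)  # (N, Ox, Oy, Oz, Cout)
            if w._needs_graph():
                gw = np.tensordot(gm, view, axes=([0, 1, 2, 3], [0, 2, 3, 4]))
                _acc(w, gw)  # (Cout, C, kx, ky, kz)
            if b is not None and b._needs_graph():
                _acc(b, gm.sum(axis=(0, 1, 2, 3)))
            if x._needs_graph():
                gcols = np.tensordot(gm, wd, axes=([4], [0]))  # (N,Ox,Oy,Oz,C,kx,ky,kz)
                gxp = np.zeros_like(xp)
                Ox, Oy, Oz = out_dims
                for i in range(kc[0]):
                    for j in range(kc[1]):
                        for l in range(kc[2]):
                            gxp[:, :,
                                i * d[0]: i * d[0] + s[0] * Ox: s[0],
                                j * d[1]: j * d[1] + s[1] * Oy: s[1],
                                l * d[2]: l * d[2] + s[2] * Oz: s[2]] += \
                                np.moveaxis(gcols[..., i, j, l], -1, 1)
                gx = gxp[:, :,
                         p[0]: xp.shape[2] - p[0] or None,
                         p[1]: xp.shape[3] - p[1] or None,
                         p[2]: xp.shape[4] - p[2] or None]
                _acc(x, gx)
        res._backward = bw
    return res


def conv_transpose3d(x: Tensor, w: Tensor, b: Tensor | None = None, stride=2) -> Tensor:
    """Strided transposed convolution with kernel == stride (non-overlapping).

    Doubles (for stride 2) each spatial dimension; the standard learned
    upsampler in the decoder. ``w`` has shape (Cin, Cout, k, k, k).
    """
    x, w = as_tensor(x), as_tensor(w)
    s = _triple(stride)
    k = w.shape[2:]
    if k != s:
        raise ValueError(f"kernel {k} must equal stride {s} for this operator")
    dt = np.result_type(x.data.dtype, w.data.dtype, np.float32)
    xd = np.ascontiguousarray(x.data, dtype=dt)
    wd = np.ascontiguousarray(w.data, dtype=dt)
    N, Cin, X, Y, Z = xd.shape
    Cout = wd.shape[1]
    t = np.tensordot(xd, wd, axes=([1], [0]))  # (N, X, Y, Z, Cout, kx, ky, kz)
    out = t.transpose(0, 4, 1, 5, 2, 6, 3, 7).reshape(N, Cout, X * s[0], Y * s[1], Z * s[2])
    if b is not None:
        out = out + b.data.reshape(1, -1, 1, 1, 1)
    out = np.ascontiguousarray(out)

    parents = (x, w) if b is None else (x, w, b)
    res = _make(out, parents)
    if res._backward is _PENDING:
        def bw(g):
            gt = g.reshape(N, Cout, X, s[0], Y, s[1], Z, s[2]) \
                  .transpose(0, 2, 4, 6, 1, 3, 5, 7)  # (N,X,Y,Z,Cout,kx,ky,kz)
            if x._needs_graph():
                gx = np.tensordot(gt, wd, axes=([4, 5, 6, 7], [1, 2, 3, 4]))
                _acc(x, np.moveaxis(gx, -1, 1))
            if w._needs_graph():
                gw = np.tensordot(xd, gt, axes=([0, 2, 3, 4], [0, 1, 2, 3]))
                _acc(w, gw)  # (Cin, Cout, kx, ky, kz)
            if b is not None and b._needs_graph():
                _acc(b, g.sum(axis=(0, 2, 3, 4)))
        res._backward = bw
    return res


def instance_norm3d(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Per-sample, per-channel normalization over the spatial axes."""
    x = as_tensor(x)
    xd = x.data
    mu = xd.mean(axis=(2, 3, 4), keepdims=True)
    var = xd.var(axis=(2, 3, 4), keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (xd - mu) * inv
    gd = gamma.data.reshape(1, -1, 1, 1, 1)
    out = gd * xhat + beta.data.reshape(1, -1, 1, 1, 1)

    res = _make(out, (x, gamma, beta))
    if res._backward is _PENDING:
        def bw(g):
            if gamma._needs_graph():
                _acc(gamma, (g * xhat).sum(axis=(0, 2, 3, 4)))
            if beta._needs_graph():
                _acc(beta, g.sum(axis=(0, 2, 3, 4)))
            if x._needs_graph():
                gxh = g * gd
                m1 = gxh.mean(axis=(2, 3, 4), keepdims=True)
                m2 = (gxh * xhat).mean(axis=(2, 3, 4), keepdims=True)
                _acc(x, inv * (gxh - m1 - xhat * m2))
        res._backward = bw
    return res


def prelu(x: Tensor, a: Tensor) -> Tensor:
    """Parametric rectifier with a learned per-channel negative slope."""
    x = as_tensor(x)
    xd = x.data
    neg = xd < 0
    ad = a.data.reshape(1, -1, 1, 1, 1)
    out = np.where(neg, ad * xd, xd)

    res = _make(out, (x, a))
    if res._backward is _PENDING:
        def bw(g):
            if x._needs_graph():
                _acc(x, np.where(neg, ad * g, g))
            if a._needs_graph():
                _acc(a, (g * xd * neg).sum(axis=(0, 2, 3, 4)))
        res._backward = bw
    return res
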