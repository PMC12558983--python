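"""JIT-compiled im2col/col2im kernels (numba).

Column layout is ``(C*KH*KW, N*OH*OW)`` so both GEMM directions run as a
single flat BLAS call (skinny deep-stage convolutions stay one GEMM
instead of a per-sample batch).  Stride-1 kernels copy whole output rows
at a time.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def bn_fwd(x: np.ndarray, gamma: np.ndarray, beta: np.ndarray, eps: float,
           apply_relu: bool):
    """Fused train-mode batch norm (+ optional ReLU) over axes (0, 2, 3).

    Returns (out, xhat, inv, mu, var); xhat/inv feed the backward pass.
    """
    n, c, h, w = x.shape
    hw = h * w
    cnt = n * hw
    mu = np.empty(c, dtype=x.dtype)
    var = np.empty(c, dtype=x.dtype)
    inv = np.empty(c, dtype=x.dtype)
    out = np.empty_like(x)
    xhat = np.empty_like(x)
    for ci in range(c):
        s = 0.0
        s2 = 0.0
        for ni in range(n):
            plane = x[ni, ci]
            for i in range(h):
                for j in range(w):
                    v = plane[i, j]
                    s += v
                    s2 += v * v
        m = s / cnt
        v_ = s2 / cnt - m * m
        if v_ < 0.0:
            v_ = 0.0
        mu[ci] = m
        var[ci] = v_
        iv = 1.0 / np.sqrt(v_ + eps)
        inv[ci] = iv
        ga = gamma[ci]
        be = beta[ci]
        for ni in range(n):
            plane = x[ni, ci]
            po = out[ni, ci]
            ph = xhat[ni, ci]
            for i in range(h):
                for j in range(w):
                    xh = (plane[i, j] - m) * iv
                    ph[i, j] = xh
                    y = ga * xh + be
                    if apply_relu and y < 0.0:
                        y = 0.0
                    po[i, j] = y
    return out, xhat, inv, mu, var


@njit(cache=True)
def bn_bwd(g: np.ndarray, out: np.ndarray, xhat: np.ndarray, inv: np.ndarray,
           gamma: np.ndarray, applied_relu: bool):
    """Backward of the fused batch norm; returns (dx, dgamma, dbeta)."""
    n, c, h, w = g.shape
    cnt = n * h * w
    dx = np.empty_like(g)
    dgamma = np.empty(c, dtype=g.dtype)
    dbeta = np.empty(c, dtype=g.dtype)
    for ci in range(c):
        sg = 0.0
        sgx = 0.0
        for ni in range(n):
            pg = g[ni, ci]
            po = out[ni, ci]
            ph = xhat[ni, ci]
            for i in range(h):
                for j in range(w):
                    gr = pg[i, j]
                    if applied_relu and po[i, j] <= 0.0:
                        gr = 0.0
                    sg += gr
                    sgx += gr * ph[i, j]
        dgamma[ci] = sgx
        dbeta[ci] = sg
        k = gamma[ci] * inv[ci]
        mg = sg / cnt
        mgx = sgx / cnt
        for ni in range(n):
            pg = g[ni, ci]
            po = out[ni, ci]
            ph = xhat[ni, ci]
            pd = dx[ni, ci]
            for i in range(h):
                for j in range(w):
                    gr = pg[i, j]
                    if applied_relu and po[i, j] <= 0.0:
                        gr = 0.0
                    pd[i, j] = k * (gr - mg - ph[i, j] * mgx)
    return dx, dgamma, dbeta


@njit(cache=True)
def add_relu_fwd(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    out = np.empty_like(a)
    af = a.ravel()
    bf = b.ravel()
    of = out.ravel()
    for i in range(af.size):
        v = af[i] + bf[i]
        of[i] = v if v > 0.0 else 0.0
    return out


@njit(cache=True)
def add_relu_bwd(g: np.ndarray, out: np.ndarray) -> np.ndarray:
    dx = np.empty_like(g)
    gf = g.ravel()
    of = out.ravel()
    df = dx.ravel()
    for i in range(gf.size):
        df[i] = gf[i] if of[i] > 0.0 else 0.0
    return dx


@njit(cache=True)
def im2colT(xp: np.ndarray, kh: int, kw: int, stride: int, oh: int, ow: int) -> np.ndarray:
    n, c, hp, wp = xp.shape
    col = np.empty((c * kh * kw, n * oh * ow), dtype=xp.dtype)
    if stride == 1:
        for ci in range(c):
            for ki in range(kh):
                for kj in range(kw):
                    q = (ci * kh + ki) * kw + kj
                    for ni in range(n):
                        for oi in range(oh):
                            r = (ni * oh + oi) * ow
                            col[q, r:r + ow] = xp[ni, ci, oi + ki, kj:kj + ow]
    else:
        for ci in range(c):
            for ki in range(kh):
                for kj in range(kw):
                    q = (ci * kh + ki) * kw + kj
                    for ni in range(n):
                        for oi in range(oh):
                            bi = oi * stride + ki
                            r = (ni * oh + oi) * ow
                            for oj in range(ow):
                                col[q, r + oj] = xp[ni, ci, bi, oj * stride + kj]
    return col


@njit(cache=True)
def colT2im(dcol: np.ndarray, n: int, c: int, hp: int, wp: int,
            kh: int, kw: int, stride: int, oh: int, ow: int) -> np.ndarray:
    dxp = np.zeros((n, c, hp, wp), dtype=dcol.dtype)
    if stride == 1:
        for ci in range(c):
            for ki in range(kh):
                for kj in range(kw):
                    q = (ci * kh + ki) * kw + kj
                    for ni in range(n):
                        for oi in range(oh):
                            r = (ni * oh + oi) * ow
                            dxp[ni, ci, oi + ki, kj:kj + ow] += dcol[q, r:r + ow]
    else:
        for ci in range(c):
            for ki in range(kh):
                for kj in range(kw):
                    q = (ci * kh + ki) * kw + kj
                    for ni in range(n):
                        for oi in range(oh):
                            bi = oi * stride + ki
                            r = (ni * oh + oi) * ow
                            for oj in range(ow):
                                dxp[ni, ci, bi, oj * stride + kj] += dcol[q, r + oj]
    return dxp
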