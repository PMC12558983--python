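"""Minimal reverse-mode automatic differentiation on NumPy arrays.

A :class:`Tensor` wraps a float ndarray together with an optional gradient
and a backward closure.  Operations build a DAG; :meth:`Tensor.backward`
runs reverse accumulation in topological order.  Convolution is lowered to
a BLAS GEMM through an im2col transform, which is what makes CPU training
of the purification encoder practical.

Only the operations the package needs are implemented; dtypes are
preserved (float32 in training, float64 available for numerical checks).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "concat",
    "split",
    "conv2d",
    "relu",
    "add_relu",
    "sigmoid",
    "batch_norm",
    "l2_normalize",
    "logsumexp",
]


def _as_float(data) -> np.ndarray:
    arr = np.asarray(data)
    if arr.dtype not in (np.float32, np.float64):
        arr = arr.astype(np.float32)
    return arr


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev", "_grad_shared")

    def __init__(self, data, requires_grad: bool = False):
        self.data = _as_float(data)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._backward = None
        self._prev: tuple = ()
        self._grad_shared = False

    # ------------------------------------------------------------- basics
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    @property
    def T(self) -> "Tensor":
        return self.transpose()

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, dtype={self.data.dtype}, grad={self.requires_grad})"

    # ---------------------------------------------------------- autograd
    def backward(self, grad=None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without an explicit gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -------------------------------------------------------- arithmetic
    def __add__(self, other):
        return _add(self, _wrap(other))

    __radd__ = __add__

    def __neg__(self):
        return self * -1.0

    def __sub__(self, other):
        return _add(self, _wrap(other) * -1.0)

    def __rsub__(self, other):
        return _wrap(other) + (-self)

    def __mul__(self, other):
        return _mul(self, _wrap(other))

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _wrap(other)
        return _mul(self, other ** -1.0)

    def __pow__(self, p: float):
        return _pow(self, float(p))

    def __matmul__(self, other):
        return _matmul(self, _wrap(other))

    def __getitem__(self, idx):
        return _getitem(self, idx)

    # -------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims=False):
        return _sum(self, axis, keepdims)

    def mean(self, axis=None, keepdims=False):
        out = _sum(self, axis, keepdims)
        n = self.data.size / out.data.size
        return out * (1.0 / n)

    def max(self, axis=None, keepdims=False):
        return _max(self, axis, keepdims)

    # ------------------------------------------------------------ shapes
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return _reshape(self, shape)

    def transpose(self, *axes):
        if not axes:
            axes = tuple(range(self.ndim))[::-1]
        elif len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        return _transpose(self, axes)

    # ---------------------------------------------------------- elemwise
    def exp(self):
        return _exp(self)

    def log(self):
        return _log(self)


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _node(data: np.ndarray, parents: tuple, backward) -> Tensor:
    out = Tensor(data)
    if any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._prev = tuple(p for p in parents if p.requires_grad)
        out._backward = backward
    return out


def _accum(t: Tensor, g: np.ndarray) -> None:
    """Accumulate a gradient contribution.

    The first contribution is stored by reference (it may be a view shared
    with another node), so the second contribution adds out of place; any
    later ones add in place into the privately owned buffer.
    """
    if not t.requires_grad:
        return
    if g.dtype != t.data.dtype:
        g = g.astype(t.data.dtype)
    if t.grad is None:
        t.grad = g
        t._grad_shared = True
    elif t._grad_shared:
        t.grad = t.grad + g
        t._grad_shared = False
    else:
        t.grad += g


# ------------------------------------------------------------------ ops

def _add(a: Tensor, b: Tensor) -> Tensor:
    data = a.data + b.data

    def backward(g):
        _accum(a, _unbroadcast(g, a.data.shape))
        _accum(b, _unbroadcast(g, b.data.shape))

    return _node(data, (a, b), backward)


def _mul(a: Tensor, b: Tensor) -> Tensor:
    data = a.data * b.data

    def backward(g):
        _accum(a, _unbroadcast(g * b.data, a.data.shape))
        _accum(b, _unbroadcast(g * a.data, b.data.shape))

    return _node(data, (a, b), backward)


def _pow(a: Tensor, p: float) -> Tensor:
    data = a.data ** p

    def backward(g):
        _accum(a, g * p * a.data ** (p - 1.0))

    return _node(data, (a,), backward)


def _matmul(a: Tensor, b: Tensor) -> Tensor:
    data = a.data @ b.data

    def backward(g):
        _accum(a, g @ b.data.swapaxes(-1, -2))
        _accum(b, a.data.swapaxes(-1, -2) @ g)

    return _node(data, (a, b), backward)


def _sum(a: Tensor, axis, keepdims: bool) -> Tensor:
    data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        if axis is None:
            _accum(a, np.broadcast_to(g, a.data.shape).copy())
            return
        if not keepdims:
            g = np.expand_dims(g, axis)
        _accum(a, np.broadcast_to(g, a.data.shape).copy())

    return _node(data, (a,), backward)


def _max(a: Tensor, axis, keepdims: bool) -> Tensor:
    if isinstance(axis, int):
        idx = a.data.argmax(axis=axis)
        data = np.take_along_axis(a.data, np.expand_dims(idx, axis), axis)
        out = data if keepdims else np.squeeze(data, axis=axis)

        def backward(g):
            if not keepdims:
                g = np.expand_dims(g, axis)
            full = np.zeros_like(a.data)
            # subgradient: route to the first argmax
            np.put_along_axis(full, np.expand_dims(idx, axis), g, axis)
            _accum(a, full)

        return _node(out, (a,), backward)

    data = a.data.max(axis=axis, keepdims=True)
    mask = (a.data == data)
    counts = mask.sum(axis=axis, keepdims=True)
    out = data if keepdims or axis is None else np.squeeze(data, axis=axis)

    def backward(g):
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
        # subgradient: split equally among ties
        _accum(a, mask * (g / counts))

    return _node(out, (a,), backward)


def _reshape(a: Tensor, shape) -> Tensor:
    data = a.data.reshape(shape)

    def backward(g):
        _accum(a, g.reshape(a.data.shape))

    return _node(data, (a,), backward)


def _transpose(a: Tensor, axes) -> Tensor:
    data = a.data.transpose(axes)
    inv = np.argsort(axes)

    def backward(g):
        _accum(a, g.transpose(inv))

    return _node(data, (a,), backward)


def _getitem(a: Tensor, idx) -> Tensor:
    data = a.data[idx]

    def backward(g):
        full = np.zeros_like(a.data)
        np.add.at(full, idx, g)
        _accum(a, full)

    return _node(data, (a,), backward)


def _exp(a: Tensor) -> Tensor:
    data = np.exp(a.data)

    def backward(g):
        _accum(a, g * data)

    return _node(data, (a,), backward)


def _log(a: Tensor) -> Tensor:
    data = np.log(a.data)

    def backward(g):
        _accum(a, g / a.data)

    return _node(data, (a,), backward)


def relu(a: Tensor) -> Tensor:
    mask = a.data > 0
    data = a.data * mask

    def backward(g):
        _accum(a, g * mask)

    return _node(data, (a,), backward)


def sigmoid(a: Tensor) -> Tensor:
    data = 1.0 / (1.0 + np.exp(-a.data))

    def backward(g):
        _accum(a, g * data * (1.0 - data))

    return _node(data, (a,), backward)


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    tensors = [_wrap(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            _accum(t, g[tuple(sl)])

    return _node(data, tuple(tensors), backward)


def split(t: Tensor, sections: int, axis: int = 1) -> list[Tensor]:
    """Split into ``sections`` equal chunks along ``axis``."""
    size = t.data.shape[axis]
    if size % sections:
        raise ValueError(f"cannot split axis of size {size} into {sections} equal parts")
    step = size // sections
    outs = []
    for k in range(sections):
        sl = [slice(None)] * t.ndim
        sl[axis] = slice(k * step, (k + 1) * step)
        sl = tuple(sl)

        def backward(g, sl=sl):
            full = np.zeros_like(t.data)
            full[sl] = g
            _accum(t, full)

        outs.append(_node(t.data[sl], (t,), backward))
    return outs


def l2_normalize(t: Tensor, axis: int = -1, eps: float = 1e-12) -> Tensor:
    norm = ((t * t).sum(axis=axis, keepdims=True) + eps) ** 0.5
    return t / norm


def logsumexp(t: Tensor, axis: int = -1) -> Tensor:
    """Numerically stabilized log-sum-exp along ``axis``.

    The per-row maximum is treated as a constant; the resulting gradient
    (the softmax) is exact.
    """
    m = t.data.max(axis=axis, keepdims=True)
    shifted = t - Tensor(m)
    out = shifted.exp().sum(axis=axis, keepdims=False).log()
    return out + Tensor(np.squeeze(m, axis=axis))


def batch_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5,
               relu: bool = False):
    """Fused training-mode batch normalization over axes (0, 2, 3), with an
    optionally fused trailing ReLU (single JIT pass each direction).

    Returns ``(out, mean, var)`` where mean/var are plain (1, C, 1, 1)
    arrays of the biased batch statistics (for running-average
    bookkeeping).
    """
    from ._kernels import bn_bwd, bn_fwd

    g1 = gamma.data.ravel()
    b1 = beta.data.ravel()
    data, xhat, inv, mu, var = bn_fwd(x.data, g1, b1, eps, relu)

    def backward(g):
        dx, dgamma, dbeta = bn_bwd(np.ascontiguousarray(g), data, xhat, inv, g1, relu)
        if gamma.requires_grad:
            _accum(gamma, dgamma.reshape(gamma.data.shape))
        if beta.requires_grad:
            _accum(beta, dbeta.reshape(beta.data.shape))
        if x.requires_grad:
            _accum(x, dx)

    out = _node(data, (x, gamma, beta), backward)
    c = mu.shape[0]
    return out, mu.reshape(1, c, 1, 1), var.reshape(1, c, 1, 1)


def add_relu(a: Tensor, b: Tensor) -> Tensor:
    """Fused elementwise ``relu(a + b)`` (residual join); shapes must match."""
    from ._kernels import add_relu_bwd, add_relu_fwd

    if a.data.shape != b.data.shape:
        raise ValueError(f"add_relu shape mismatch: {a.data.shape} vs {b.data.shape}")
    data = add_relu_fwd(np.ascontiguousarray(a.data), np.ascontiguousarray(b.data))

    def backward(g):
        dx = add_relu_bwd(np.ascontiguousarray(g), data)
        _accum(a, dx)
        _accum(b, dx)

    return _node(data, (a, b), backward)


# ----------------------------------------------------------- convolution

def _fft_conv2d(x: Tensor, weight: Tensor, bias: Tensor | None) -> Tensor:
    """Same-padding stride-1 cross-correlation in the frequency domain.

    Used for the large attention kernels (5x5, 7x7), where the im2col
    expansion is memory-bound; per-frequency-bin batched GEMMs contract
    the channel dimension.  Gradients are computed by the adjoint
    correlations, also via FFT.
    """
    from scipy import fft as sfft

    n, c, h, w = x.data.shape
    f, _, kh, kw = weight.data.shape
    p = kh // 2
    s1 = sfft.next_fast_len(h + kh - 1)
    s2 = sfft.next_fast_len(w + kw - 1)
    xf = sfft.rfft2(x.data, s=(s1, s2))        # (n, c, s1, b)
    wf = sfft.rfft2(weight.data, s=(s1, s2))   # (f, c, s1, b)
    b_ = xf.shape[-1]
    xt = np.ascontiguousarray(xf.transpose(2, 3, 0, 1)).reshape(s1 * b_, n, c)
    wt_c = np.ascontiguousarray(np.conj(wf).transpose(2, 3, 1, 0)).reshape(s1 * b_, c, f)
    yf = (xt @ wt_c).reshape(s1, b_, n, f).transpose(2, 3, 0, 1)
    cc = sfft.irfft2(yf, s=(s1, s2))
    data = np.ascontiguousarray(
        np.roll(cc, (p, p), axis=(-2, -1))[..., :h, :w], dtype=x.data.dtype)
    if bias is not None:
        data = data + bias.data.reshape(1, f, 1, 1)

    def backward(g):
        gf = sfft.rfft2(g, s=(s1, s2))         # (n, f, s1, b)
        gt = np.ascontiguousarray(gf.transpose(2, 3, 0, 1)).reshape(s1 * b_, n, f)
        if weight.requires_grad:
            # dW = sum_n corr(g_nf, x_nc), taken at offsets u - p
            xt_t = np.ascontiguousarray(xf.transpose(2, 3, 1, 0)).reshape(s1 * b_, c, n)
            cf = (xt_t @ np.conj(gt)).reshape(s1, b_, c, f).transpose(2, 3, 0, 1)
            dcc = sfft.irfft2(cf, s=(s1, s2))
            dw = np.roll(dcc, (p, p), axis=(-2, -1))[..., :kh, :kw]
            _accum(weight, np.ascontiguousarray(
                dw.transpose(1, 0, 2, 3), dtype=weight.data.dtype))
        if bias is not None and bias.requires_grad:
            _accum(bias, g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            # dx = sum_f conv(g_nf, w_fc), read at offsets t + p
            wt = np.ascontiguousarray(wf.transpose(2, 3, 0, 1)).reshape(s1 * b_, f, c)
            df = (gt @ wt).reshape(s1, b_, n, c).transpose(2, 3, 0, 1)
            dcc = sfft.irfft2(df, s=(s1, s2))
            _accum(x, np.ascontiguousarray(
                np.roll(dcc, (-p, -p), axis=(-2, -1))[..., :h, :w],
                dtype=x.data.dtype))

    parents = (x, weight) if bias is None else (x, weight, bias)
    return _node(data, parents, backward)


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None,
           stride: int = 1, padding: int = 0) -> Tensor:
    """2-D cross-correlation, NCHW layout, weight (F, C, KH, KW).

    Lowered to one flat GEMM over a column matrix (C*KH*KW, N*OH*OW)
    built by a JIT kernel; 1x1 convolutions skip the column transform.
    """
    from ._kernels import colT2im, im2colT

    n, c, h, w = x.data.shape
    f, cw, kh, kw = weight.data.shape
    if c != cw:
        raise ValueError(f"conv2d channel mismatch: input has {c}, weight expects {cw}")

    # Frequency-domain path pays off when the im2col expansion is large
    # relative to the number of weight maps (stage-1-scale feature maps).
    if (stride == 1 and kh == kw and kh >= 5 and padding == kh // 2
            and h >= 16 and w >= 16):
        return _fft_conv2d(x, weight, bias)

    wm = weight.data.reshape(f, -1)

    if kh == 1 and kw == 1 and padding == 0:
        xs = x.data if stride == 1 else x.data[:, :, ::stride, ::stride]
        oh, ow = xs.shape[2], xs.shape[3]
        xT = np.ascontiguousarray(xs.transpose(1, 0, 2, 3)).reshape(c, -1)
        out = wm @ xT  # (f, n*oh*ow)
        data = out.reshape(f, n, oh, ow).transpose(1, 0, 2, 3)
        if bias is not None:
            data = data + bias.data.reshape(1, f, 1, 1)

        def backward(g):
            gm = np.ascontiguousarray(g.transpose(1, 0, 2, 3)).reshape(f, -1)
            if weight.requires_grad:
                _accum(weight, (gm @ xT.T).reshape(f, c, 1, 1))
            if bias is not None and bias.requires_grad:
                _accum(bias, gm.sum(axis=1))
            if x.requires_grad:
                dxs = (wm.T @ gm).reshape(c, n, oh, ow).transpose(1, 0, 2, 3)
                if stride == 1:
                    _accum(x, np.ascontiguousarray(dxs))
                else:
                    dx = np.zeros_like(x.data)
                    dx[:, :, ::stride, ::stride] = dxs
                    _accum(x, dx)

        parents = (x, weight) if bias is None else (x, weight, bias)
        return _node(data, parents, backward)

    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding))) \
        if padding else x.data
    oh = (xp.shape[2] - kh) // stride + 1
    ow = (xp.shape[3] - kw) // stride + 1
    if oh <= 0 or ow <= 0:
        raise ValueError(
            f"kernel {kh}x{kw} (stride {stride}, pad {padding}) does not fit input {h}x{w}"
        )
    col = im2colT(np.ascontiguousarray(xp), kh, kw, stride, oh, ow)
    out = wm @ col  # (f, n*oh*ow)
    data = out.reshape(f, n, oh, ow).transpose(1, 0, 2, 3)
    if bias is not None:
        data = data + bias.data.reshape(1, f, 1, 1)

    def backward(g):
        gm = np.ascontiguousarray(g.transpose(1, 0, 2, 3)).reshape(f, -1)
        if weight.requires_grad:
            _accum(weight, (gm @ col.T).reshape(weight.data.shape))
        if bias is not None and bias.requires_grad:
            _accum(bias, gm.sum(axis=1))
        if x.requires_grad:
            dcol = wm.T @ gm
            dxp = colT2im(dcol, n, c, xp.shape[2], xp.shape[3], kh, kw, stride, oh, ow)
            if padding:
                dxp = np.ascontiguousarray(dxp[:, :, padding:padding + h, padding:padding + w])
            _accum(x, dxp)

    parents = (x, weight) if bias is None else (x, weight, bias)
    return _node(data, parents, backward)
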