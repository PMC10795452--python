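"""Minimal reverse-mode automatic differentiation on numpy arrays.

The engine covers exactly the operations a 2D encoder-decoder segmentation
network needs: convolution, pooling, bilinear upsampling, batch
normalization, dense layers, elementwise nonlinearities, channel
concatenation and the reductions used by attention gating. Tensors hold a
numpy array, an accumulated gradient and a backward closure; ``backward()``
runs the tape in reverse topological order.

Float32 is the working dtype for training; the ops preserve whatever dtype
they are given, so gradient checks can run the whole graph in float64.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "add",
    "mul",
    "matmul",
    "relu",
    "sigmoid",
    "reshape",
    "concat",
    "conv2d",
    "maxpool2x",
    "upsample_bilinear2x",
    "mean_spatial",
    "amax_spatial",
    "mean_channel",
    "amax_channel",
    "batchnorm2d",
    "bce_with_logits_op",
]


class Tensor:
    """A node in the computation tape.

    Parameters with ``requires_grad=True`` accumulate into ``.grad``;
    intermediate nodes propagate through ``_backward`` closures.
    """

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad=False, _prev=()):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = requires_grad
        self._backward = None
        self._prev = _prev

    @property
    def shape(self):
        return self.data.shape

    @property
    def dtype(self):
        return self.data.dtype

    def _accumulate(self, g):
        if self.grad is None:
            self.grad = g.copy() if isinstance(g, np.ndarray) else np.asarray(g)
        else:
            self.grad += g

    def backward(self):
        """Backpropagate from this (scalar or any-shaped seed-1) tensor."""
        topo: list[Tensor] = []
        seen = set()
        stack = [self]
        # iterative DFS; graphs from deep nets overflow recursion limits
        while stack:
            node = stack[-1]
            if id(node) in seen:
                stack.pop()
                continue
            unvisited = [p for p in node._prev if id(p) not in seen]
            if unvisited:
                stack.extend(unvisited)
            else:
                seen.add(id(node))
                topo.append(node)
                stack.pop()
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def detach(self):
        return Tensor(self.data)

    def __repr__(self):  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"


def _as_tensor(x):
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(grad, shape):
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


def add(a, b):
    a, b = _as_tensor(a), _as_tensor(b)
    out = Tensor(a.data + b.data, _prev=(a, b))

    def _bw(g):
        a._accumulate(_unbroadcast(g, a.data.shape))
        b._accumulate(_unbroadcast(g, b.data.shape))

    out._backward = _bw
    return out


def mul(a, b):
    """Elementwise product with numpy broadcasting (used for attention gates)."""
    a, b = _as_tensor(a), _as_tensor(b)
    out = Tensor(a.data * b.data, _prev=(a, b))

    def _bw(g):
        a._accumulate(_unbroadcast(g * b.data, a.data.shape))
        b._accumulate(_unbroadcast(g * a.data, b.data.shape))

    out._backward = _bw
    return out


def matmul(a, b):
    a, b = _as_tensor(a), _as_tensor(b)
    out = Tensor(a.data @ b.data, _prev=(a, b))

    def _bw(g):
        a._accumulate(g @ b.data.T)
        b._accumulate(a.data.T @ g)

    out._backward = _bw
    return out


def relu(x):
    x = _as_tensor(x)
    mask = x.data > 0
    out = Tensor(np.where(mask, x.data, 0), _prev=(x,))

    def _bw(g):
        x._accumulate(g * mask)

    out._backward = _bw
    return out


def sigmoid(x):
    x = _as_tensor(x)
    s = _sigmoid(x.data)
    out = Tensor(s, _prev=(x,))

    def _bw(g):
        x._accumulate(g * s * (1.0 - s))

    out._backward = _bw
    return out


def _sigmoid(x):
    # stable two-branch logistic
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def reshape(x, shape):
    x = _as_tensor(x)
    out = Tensor(x.data.reshape(shape), _prev=(x,))

    def _bw(g):
        x._accumulate(g.reshape(x.data.shape))

    out._backward = _bw
    return out


def concat(tensors, axis=1):
    tensors = [_as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), _prev=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def _bw(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t._accumulate(piece)

    out._backward = _bw
    return out


# ---------------------------------------------------------------------------
# convolution (NCHW, stride 1, 'same' zero padding)
# ---------------------------------------------------------------------------

def _im2col_view(xp, kh, kw):
    n, c, hp, wp = xp.shape
    h, w = hp - kh + 1, wp - kw + 1
    s = xp.strides
    return np.lib.stride_tricks.as_strided(
        xp, (n, c, kh, kw, h, w), (s[0], s[1], s[2], s[3], s[2], s[3])
    )


def conv2d(x, weight, bias=None):
    """2D convolution, stride 1, zero 'same' padding; x (N,C,H,W), weight (O,C,kh,kw)."""
    x = _as_tensor(x)
    weight = _as_tensor(weight)
    o, c, kh, kw = weight.data.shape
    if x.data.shape[1] != c:
        raise ValueError(f"conv2d: input has {x.data.shape[1]} channels, weight expects {c}")
    ph, pw = kh // 2, kw // 2
    n, _, h, w = x.data.shape
    xp = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    cols = _im2col_view(xp, kh, kw).reshape(n, c * kh * kw, h * w)
    wm = weight.data.reshape(o, c * kh * kw)
    y = (wm @ cols).reshape(n, o, h, w)
    prev = (x, weight) if bias is None else (x, weight, bias)
    if bias is not None:
        bias = _as_tensor(bias)
        y = y + bias.data.reshape(1, o, 1, 1)
        prev = (x, weight, bias)
    out = Tensor(y, _prev=prev)

    def _bw(g):
        gm = g.reshape(n, o, h * w)
        if bias is not None:
            bias._accumulate(g.sum(axis=(0, 2, 3)))
        weight._accumulate(
            np.einsum("nop,nkp->ok", gm, cols, optimize=True).reshape(o, c, kh, kw)
        )
        dcols = (wm.T @ gm).reshape(n, c, kh, kw, h, w)
        dxp = np.zeros_like(xp)
        for i in range(kh):
            for j in range(kw):
                dxp[:, :, i : i + h, j : j + w] += dcols[:, :, i, j]
        x._accumulate(dxp[:, :, ph : ph + h, pw : pw + w])

    out._backward = _bw
    return out


def maxpool2x(x):
    """2x2 max pooling, stride 2; H and W must be even."""
    x = _as_tensor(x)
    n, c, h, w = x.data.shape
    if h % 2 or w % 2:
        raise ValueError(f"maxpool2x needs even extents, got {h}x{w}")
    xr = x.data.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    flat = xr.reshape(n, c, h // 2, w // 2, 4)
    idx = flat.argmax(axis=-1)
    out = Tensor(np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0], _prev=(x,))

    def _bw(g):
        gflat = np.zeros_like(flat)
        np.put_along_axis(gflat, idx[..., None], g[..., None], axis=-1)
        gx = (
            gflat.reshape(n, c, h // 2, w // 2, 2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(n, c, h, w)
        )
        x._accumulate(gx)

    out._backward = _bw
    return out


_BILINEAR_CACHE: dict[tuple[int, type], np.ndarray] = {}


def _bilinear_matrix(n_in, dtype):
    """(2n x n) interpolation matrix for x2 bilinear upsampling (half-pixel centers)."""
    key = (n_in, np.dtype(dtype).name)
    mat = _BILINEAR_CACHE.get(key)
    if mat is None:
        mat = np.zeros((2 * n_in, n_in), dtype=dtype)
        for o in range(2 * n_in):
            src = (o + 0.5) / 2.0 - 0.5
            i0 = int(np.floor(src))
            frac = src - i0
            i0c = min(max(i0, 0), n_in - 1)
            i1c = min(max(i0 + 1, 0), n_in - 1)
            mat[o, i0c] += 1.0 - frac
            mat[o, i1c] += frac
        _BILINEAR_CACHE[key] = mat
    return mat


def upsample_bilinear2x(x):
    x = _as_tensor(x)
    n, c, h, w = x.data.shape
    ah = _bilinear_matrix(h, x.data.dtype)
    aw = _bilinear_matrix(w, x.data.dtype)
    out = Tensor(ah @ x.data @ aw.T, _prev=(x,))

    def _bw(g):
        x._accumulate(ah.T @ g @ aw)

    out._backward = _bw
    return out


def upsample_nearest2x(x):
    x = _as_tensor(x)
    out = Tensor(x.data.repeat(2, axis=2).repeat(2, axis=3), _prev=(x,))
    n, c, h, w = x.data.shape

    def _bw(g):
        x._accumulate(g.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5)))

    out._backward = _bw
    return out


# ---------------------------------------------------------------------------
# reductions used by attention modules
# ---------------------------------------------------------------------------

def mean_spatial(x):
    """Global average pool over (H, W): (N,C,H,W) -> (N,C)."""
    x = _as_tensor(x)
    n, c, h, w = x.data.shape
    out = Tensor(x.data.mean(axis=(2, 3)), _prev=(x,))

    def _bw(g):
        x._accumulate(np.broadcast_to(g[:, :, None, None] / (h * w), x.data.shape))

    out._backward = _bw
    return out


def amax_spatial(x):
    """Global max pool over (H, W): (N,C,H,W) -> (N,C)."""
    x = _as_tensor(x)
    n, c, h, w = x.data.shape
    flat = x.data.reshape(n, c, h * w)
    idx = flat.argmax(axis=-1)
    out = Tensor(np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0], _prev=(x,))

    def _bw(g):
        gx = np.zeros_like(flat)
        np.put_along_axis(gx, idx[..., None], g[..., None], axis=-1)
        x._accumulate(gx.reshape(n, c, h, w))

    out._backward = _bw
    return out


def mean_channel(x):
    """Channel-wise average: (N,C,H,W) -> (N,1,H,W)."""
    x = _as_tensor(x)
    c = x.data.shape[1]
    out = Tensor(x.data.mean(axis=1, keepdims=True), _prev=(x,))

    def _bw(g):
        x._accumulate(np.broadcast_to(g / c, x.data.shape))

    out._backward = _bw
    return out


def amax_channel(x):
    """Channel-wise max: (N,C,H,W) -> (N,1,H,W)."""
    x = _as_tensor(x)
    idx = x.data.argmax(axis=1, keepdims=True)
    out = Tensor(np.take_along_axis(x.data, idx, axis=1), _prev=(x,))

    def _bw(g):
        gx = np.zeros_like(x.data)
        np.put_along_axis(gx, idx, g, axis=1)
        x._accumulate(gx)

    out._backward = _bw
    return out


def batchnorm2d(x, gamma, beta, running_mean, running_var, training, momentum=0.1, eps=1e-5):
    """Batch normalization over (N,H,W) per channel.

    In training mode normalizes with batch statistics and updates the running
    buffers in place; in eval mode applies the frozen affine transform.
    """
    x = _as_tensor(x)
    gamma, beta = _as_tensor(gamma), _as_tensor(beta)
    n, c, h, w = x.data.shape
    if training:
        mean = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        m = n * h * w
        running_mean *= 1.0 - momentum
        running_mean += momentum * mean
        running_var *= 1.0 - momentum
        # unbiased variance for the running buffer, biased for normalization
        running_var += momentum * (var * m / max(m - 1, 1))
    else:
        mean = running_mean
        var = running_var
    istd = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mean[None, :, None, None]) * istd[None, :, None, None]
    out = Tensor(
        gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None],
        _prev=(x, gamma, beta),
    )

    def _bw(g):
        beta._accumulate(g.sum(axis=(0, 2, 3)))
        gamma._accumulate((g * xhat).sum(axis=(0, 2, 3)))
        if training:
            m = n * h * w
            gh = g * gamma.data[None, :, None, None]
            mean_gh = gh.mean(axis=(0, 2, 3))
            mean_ghx = (gh * xhat).mean(axis=(0, 2, 3))
            dx = (
                gh
                - mean_gh[None, :, None, None]
                - xhat * mean_ghx[None, :, None, None]
            ) * istd[None, :, None, None]
        else:
            dx = g * (gamma.data * istd)[None, :, None, None]
        x._accumulate(dx)

    out._backward = _bw
    return out


def bce_with_logits_op(logits, targets, weight=None):
    """Weighted binary cross-entropy on raw logits, mean-reduced.

    Computed as ``(1-y)x + (1 + (w-1)y) * softplus(-x)`` with
    ``softplus(-x) = logaddexp(0, -x)`` so the sigmoid is never materialized
    and large logits cannot overflow. ``weight`` multiplies the
    positive-class term only.
    """
    logits = _as_tensor(logits)
    y = np.asarray(targets, dtype=logits.data.dtype)
    x = logits.data
    w = 1.0 if weight is None else float(weight)
    coef = 1.0 + (w - 1.0) * y
    per = (1.0 - y) * x + coef * np.logaddexp(0.0, -x)
    out = Tensor(np.asarray(per.mean()), _prev=(logits,))
    m = per.size

    def _bw(g):
        # d/dx [(1-y)x + coef*softplus(-x)] = (1-y) - coef*sigmoid(-x)
        logits._accumulate(g * ((1.0 - y) - coef * _sigmoid(-x)) / m)

    out._backward = _bw
    return out
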