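"""Minimal reverse-mode automatic differentiation on numpy arrays.

Supports exactly the graph operations the lesion-analysis networks need:
stride-1 2-D convolution (im2col), 2x2 stride-2 transposed convolution,
2x2 max pooling, batch normalization, dropout, dense layers, ReLU /
sigmoid / log-softmax, channel concatenation and reductions.

Every intermediate tensor retains its gradient after ``backward`` so
that input-gradient and activation-gradient saliency methods (guided
backpropagation, Grad-CAM, integrated gradients) can read them directly.
A module-level guided-ReLU switch implements the modified backward rule
in which the signal is zeroed wherever either the forward input or the
incoming gradient is negative.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Iterable

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

_GUIDED_RELU = False


@contextlib.contextmanager
def guided_relu():
    """Within this context ReLU backward suppresses negative gradients."""
    global _GUIDED_RELU
    prev = _GUIDED_RELU
    _GUIDED_RELU = True
    try:
        yield
    finally:
        _GUIDED_RELU = prev


class Tensor:
    """A node in the computation graph wrapping a float64 ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False,
                 parents: tuple = (), backward: Callable | None = None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Reverse-mode sweep seeding this node with ``grad`` (default 1)."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a seed needs a scalar output")
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
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        for node in topo:
            node.grad = None
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=np.float64)
        else:
            self.grad += g

    # -- convenience operators ------------------------------------------
    def __add__(self, other):
        return add(self, as_tensor(other))

    def __mul__(self, other):
        return mul(self, as_tensor(other))

    def __sub__(self, other):
        return add(self, mul(as_tensor(other), as_tensor(-1.0)))

    def __neg__(self):
        return mul(self, as_tensor(-1.0))


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``g`` back down to ``shape`` after numpy broadcasting."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g.reshape(shape)


def add(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data + b.data, parents=(a, b))
    out._backward = lambda g: (a.accumulate(_unbroadcast(g, a.shape)),
                               b.accumulate(_unbroadcast(g, b.shape)))
    return out


def mul(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data * b.data, parents=(a, b))
    out._backward = lambda g: (a.accumulate(_unbroadcast(g * b.data, a.shape)),
                               b.accumulate(_unbroadcast(g * a.data, b.shape)))
    return out


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data @ b.data, parents=(a, b))

    def _bw(g):
        a.accumulate(g @ b.data.T)
        b.accumulate(a.data.T @ g)

    out._backward = _bw
    return out


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    out = Tensor(np.where(mask, x.data, 0.0), parents=(x,))

    def _bw(g):
        gg = g * mask
        if _GUIDED_RELU:
            gg = gg * (g > 0)
        x.accumulate(gg)

    out._backward = _bw
    return out


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-x.data))
    out = Tensor(s, parents=(x,))
    out._backward = lambda g: x.accumulate(g * s * (1.0 - s))
    return out


def log(x: Tensor, eps: float = 1e-12) -> Tensor:
    clipped = np.clip(x.data, eps, None)
    out = Tensor(np.log(clipped), parents=(x,))
    out._backward = lambda g: x.accumulate(g / clipped)
    return out


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    m = x.data.max(axis=axis, keepdims=True)
    z = x.data - m
    lse = np.log(np.exp(z).sum(axis=axis, keepdims=True))
    out = Tensor(z - lse, parents=(x,))
    soft = np.exp(z - lse)
    out._backward = lambda g: x.accumulate(
        g - soft * g.sum(axis=axis, keepdims=True))
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    ls = log_softmax(x, axis=axis)
    out = Tensor(np.exp(ls.data), parents=(ls,))
    out._backward = lambda g: ls.accumulate(g * out.data)
    return out


def mean(x: Tensor) -> Tensor:
    out = Tensor(np.array(x.data.mean()), parents=(x,))
    out._backward = lambda g: x.accumulate(
        np.full(x.shape, float(g) / x.data.size))
    return out


def sum_(x: Tensor) -> Tensor:
    out = Tensor(np.array(x.data.sum()), parents=(x,))
    out._backward = lambda g: x.accumulate(np.full(x.shape, float(g)))
    return out


def reshape(x: Tensor, shape) -> Tensor:
    out = Tensor(x.data.reshape(shape), parents=(x,))
    out._backward = lambda g: x.accumulate(g.reshape(x.shape))
    return out


def concat_channels(tensors: Iterable[Tensor]) -> Tensor:
    ts = list(tensors)
    out = Tensor(np.concatenate([t.data for t in ts], axis=1), parents=tuple(ts))
    splits = np.cumsum([t.shape[1] for t in ts])[:-1]

    def _bw(g):
        for t, piece in zip(ts, np.split(g, splits, axis=1)):
            t.accumulate(piece)

    out._backward = _bw
    return out


def select(x: Tensor, index) -> Tensor:
    """Advanced-indexing selection, e.g. per-sample class logits."""
    out = Tensor(x.data[index], parents=(x,))

    def _bw(g):
        full = np.zeros(x.shape)
        np.add.at(full, index, g)
        x.accumulate(full)

    out._backward = _bw
    return out


def dropout(x: Tensor, rate: float, rng: np.random.Generator) -> Tensor:
    """Inverted dropout with a caller-supplied generator (seedable)."""
    if rate <= 0:
        return x
    keep = (rng.random(x.shape) >= rate) / (1.0 - rate)
    out = Tensor(x.data * keep, parents=(x,))
    out._backward = lambda g: x.accumulate(g * keep)
    return out


# -- spatial ops (NCHW layout) ------------------------------------------

def conv2d(x: Tensor, w: Tensor, b: Tensor, padding: int) -> Tensor:
    """Stride-1 2-D convolution (cross-correlation), same/valid padding."""
    n, c, h, wd = x.shape
    f, _, kh, kw = w.shape
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))  # N,C,OH,OW,kh,kw
    oh, ow = win.shape[2], win.shape[3]
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n, oh * ow, c * kh * kw)
    wmat = w.data.reshape(f, -1)
    out_data = (cols @ wmat.T).transpose(0, 2, 1).reshape(n, f, oh, ow)
    out_data += b.data.reshape(1, f, 1, 1)
    out = Tensor(out_data, parents=(x, w, b))

    def _bw(g):
        gm = g.reshape(n, f, oh * ow)
        w.accumulate(np.einsum("nfp,npk->fk", gm, cols).reshape(w.shape))
        b.accumulate(g.sum(axis=(0, 2, 3)))
        dcols = np.einsum("nfp,fk->npk", gm, wmat)
        dcols = dcols.reshape(n, oh, ow, c, kh, kw)
        dxp = np.zeros_like(xp)
        for i in range(kh):
            for j in range(kw):
                dxp[:, :, i:i + oh, j:j + ow] += dcols[:, :, :, :, i, j].transpose(
                    0, 3, 1, 2)
        if padding:
            dxp = dxp[:, :, padding:-padding, padding:-padding]
        x.accumulate(dxp)

    out._backward = _bw
    return out


def conv_transpose2x2(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """2x2 transposed convolution with stride 2 (non-overlapping upsample).

    ``w`` has shape (C_in, C_out, 2, 2); output is (N, C_out, 2H, 2W).
    """
    n, c, h, wd = x.shape
    f = w.shape[1]
    blocks = np.einsum("nchw,cfij->nfhiwj", x.data, w.data)
    out_data = blocks.reshape(n, f, 2 * h, 2 * wd) + b.data.reshape(1, f, 1, 1)
    out = Tensor(out_data, parents=(x, w, b))

    def _bw(g):
        gb = g.reshape(n, f, h, 2, wd, 2)
        x.accumulate(np.einsum("nfhiwj,cfij->nchw", gb, w.data))
        w.accumulate(np.einsum("nchw,nfhiwj->cfij", x.data, gb))
        b.accumulate(g.sum(axis=(0, 2, 3)))

    out._backward = _bw
    return out


def maxpool2x2(x: Tensor) -> Tensor:
    n, c, h, w = x.shape
    win = x.data.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    flat = win.reshape(n, c, h // 2, w // 2, 4)
    idx = flat.argmax(axis=-1)
    out = Tensor(np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0],
                 parents=(x,))

    def _bw(g):
        dflat = np.zeros_like(flat)
        np.put_along_axis(dflat, idx[..., None], g[..., None], axis=-1)
        dx = dflat.reshape(n, c, h // 2, w // 2, 2, 2).transpose(
            0, 1, 2, 4, 3, 5).reshape(n, c, h, w)
        x.accumulate(dx)

    out._backward = _bw
    return out


def global_avg_pool(x: Tensor) -> Tensor:
    n, c, h, w = x.shape
    out = Tensor(x.data.mean(axis=(2, 3)), parents=(x,))
    out._backward = lambda g: x.accumulate(
        np.broadcast_to(g[:, :, None, None] / (h * w), x.shape).copy())
    return out


def batchnorm(x: Tensor, gamma: Tensor, beta: Tensor,
              mean_: np.ndarray, var_: np.ndarray, training: bool,
              eps: float = 1e-5) -> Tensor:
    """Per-channel batch normalization over an NCHW (or NC) tensor.

    ``mean_``/``var_`` are the statistics actually used (batch stats during
    training, running stats in evaluation); the caller owns the running
    averages.
    """
    axes = (0, 2, 3) if x.data.ndim == 4 else (0,)
    shape = (1, -1, 1, 1) if x.data.ndim == 4 else (1, -1)
    inv = 1.0 / np.sqrt(var_ + eps)
    xhat = (x.data - mean_.reshape(shape)) * inv.reshape(shape)
    out = Tensor(xhat * gamma.data.reshape(shape) + beta.data.reshape(shape),
                 parents=(x, gamma, beta))
    m = x.data.size / x.data.shape[1]

    def _bw(g):
        gamma.accumulate((g * xhat).sum(axis=axes))
        beta.accumulate(g.sum(axis=axes))
        gx = g * gamma.data.reshape(shape)
        if training:
            dxhat_sum = gx.sum(axis=axes, keepdims=True)
            dxhat_x = (gx * xhat).sum(axis=axes, keepdims=True)
            dx = (inv.reshape(shape) / m) * (m * gx - dxhat_sum - xhat * dxhat_x)
        else:
            dx = gx * inv.reshape(shape)
        x.accumulate(dx)

    out._backward = _bw
    return out
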