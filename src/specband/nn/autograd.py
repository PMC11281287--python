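"""A small reverse-mode automatic-differentiation engine on numpy arrays.

Just enough machinery for a residual CNN with channel attention: tensors carry
a value and an accumulated gradient; every op records its parents and a
closure that maps the output gradient to parent-gradient contributions.
``Tensor.backward()`` runs the closures in reverse topological order.

Convolution is implemented via im2col/col2im so that the heavy lifting is a
single BLAS matmul per layer. All computation is float32.
"""

from __future__ import annotations

import numpy as np


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self.requires_grad = requires_grad
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    def backward(self) -> None:
        """Accumulate gradients of all ancestors w.r.t. this (scalar) tensor."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; graphs can be deep (18-layer backbone)
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad or p._parents:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accumulate(self, g: np.ndarray) -> None:
        g = g.astype(np.float32, copy=False)
        if self.grad is None:
            self.grad = g.copy()
        else:
            self.grad += g


def _needs_graph(*tensors: Tensor) -> bool:
    return any(t.requires_grad or t._parents for t in tensors)


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum gradient over broadcast dimensions back to ``shape``."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def _make(data, parents, backward):
    if any(_needs_graph(p) for p in parents):
        return Tensor(data, parents=tuple(parents), backward=backward)
    return Tensor(data)


def add(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data + b.data

    def bw(g):
        a._accumulate(_unbroadcast(g, a.shape))
        b._accumulate(_unbroadcast(g, b.shape))

    return _make(out_data, (a, b), bw)


def mul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data * b.data

    def bw(g):
        a._accumulate(_unbroadcast(g * b.data, a.shape))
        b._accumulate(_unbroadcast(g * a.data, b.shape))

    return _make(out_data, (a, b), bw)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data @ b.data

    def bw(g):
        a._accumulate(g @ b.data.T)
        b._accumulate(a.data.T @ g)

    return _make(out_data, (a, b), bw)


def linear(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """``x @ w.T + b`` with ``w`` of shape (out_features, in_features)."""
    out_data = x.data @ w.data.T + b.data

    def bw(g):
        x._accumulate(g @ w.data)
        w._accumulate(g.T @ x.data)
        b._accumulate(g.sum(axis=tuple(range(g.ndim - 1))))

    return _make(out_data, (x, w, b), bw)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    out_data = x.data * mask

    def bw(g):
        x._accumulate(g * mask)

    return _make(out_data, (x,), bw)


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-x.data))

    def bw(g):
        x._accumulate(g * s * (1.0 - s))

    return _make(s, (x,), bw)


def reshape(x: Tensor, shape) -> Tensor:
    orig = x.shape
    out_data = x.data.reshape(shape)

    def bw(g):
        x._accumulate(g.reshape(orig))

    return _make(out_data, (x,), bw)


def mean_spatial(x: Tensor) -> Tensor:
    """Mean over the two trailing spatial axes: (N, C, H, W) -> (N, C)."""
    n, c, h, w = x.shape
    out_data = x.data.mean(axis=(2, 3))

    def bw(g):
        x._accumulate(np.broadcast_to(g[:, :, None, None] / (h * w), x.shape))

    return _make(out_data, (x,), bw)


def amax_spatial(x: Tensor) -> Tensor:
    """Max over the two trailing spatial axes: (N, C, H, W) -> (N, C).

    The gradient is routed to the first (row-major) maximising pixel of each
    channel, a deterministic tie-break.
    """
    n, c, h, w = x.shape
    flat = x.data.reshape(n, c, h * w)
    idx = flat.argmax(axis=2)
    out_data = np.take_along_axis(flat, idx[:, :, None], axis=2)[:, :, 0]

    def bw(g):
        gx = np.zeros_like(flat)
        np.put_along_axis(gx, idx[:, :, None], g[:, :, None], axis=2)
        x._accumulate(gx.reshape(x.shape))

    return _make(out_data, (x,), bw)


global_avg_pool = mean_spatial


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    oh = (h + 2 * pad - kh) // stride + 1
    ow = (w + 2 * pad - kw) // stride + 1
    s = x.strides
    windows = np.lib.stride_tricks.as_strided(
        x, shape=(n, c, oh, ow, kh, kw),
        strides=(s[0], s[1], s[2] * stride, s[3] * stride, s[2], s[3]))
    # (N, OH, OW, C, KH, KW) -> (N*OH*OW, C*KH*KW)
    cols = windows.transpose(0, 2, 3, 1, 4, 5).reshape(n * oh * ow, c * kh * kw)
    return np.ascontiguousarray(cols), oh, ow


def _col2im(cols: np.ndarray, x_shape, kh: int, kw: int, stride: int, pad: int):
    n, c, h, w = x_shape
    hp, wp = h + 2 * pad, w + 2 * pad
    oh = (hp - kh) // stride + 1
    ow = (wp - kw) // stride + 1
    out = np.zeros((n, c, hp, wp), dtype=np.float32)
    cols = cols.reshape(n, oh, ow, c, kh, kw)
    for i in range(kh):
        for j in range(kw):
            out[:, :, i:i + stride * oh:stride, j:j + stride * ow:stride] += \
                cols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
    return out[:, :, pad:pad + h, pad:pad + w] if pad else out


def conv2d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1,
           pad: int = 0) -> Tensor:
    """2-D convolution (cross-correlation); ``w`` is (C_out, C_in, KH, KW)."""
    n = x.shape[0]
    co, ci, kh, kw = w.shape
    cols, oh, ow = _im2col(x.data, kh, kw, stride, pad)
    wmat = w.data.reshape(co, ci * kh * kw)
    out = cols @ wmat.T  # (N*OH*OW, C_out)
    if b is not None:
        out += b.data
    out_data = out.reshape(n, oh, ow, co).transpose(0, 3, 1, 2)

    def bw(g):
        gmat = g.transpose(0, 2, 3, 1).reshape(n * oh * ow, co)
        w._accumulate((gmat.T @ cols).reshape(w.shape))
        if b is not None:
            b._accumulate(gmat.sum(axis=0))
        gcols = gmat @ wmat
        x._accumulate(_col2im(gcols, x.shape, kh, kw, stride, pad))

    parents = (x, w) if b is None else (x, w, b)
    return _make(out_data, parents, bw)


def maxpool2d(x: Tensor, k: int = 3, stride: int = 2, pad: int = 1) -> Tensor:
    """Max pooling; -inf padding so padded positions never win."""
    n, c, h, w = x.shape
    xp = x.data
    if pad:
        xp = np.pad(xp, ((0, 0), (0, 0), (pad, pad), (pad, pad)),
                    constant_values=-np.inf)
    oh = (h + 2 * pad - k) // stride + 1
    ow = (w + 2 * pad - k) // stride + 1
    s = xp.strides
    windows = np.lib.stride_tricks.as_strided(
        xp, shape=(n, c, oh, ow, k, k),
        strides=(s[0], s[1], s[2] * stride, s[3] * stride, s[2], s[3]))
    flat = windows.reshape(n, c, oh, ow, k * k)
    idx = flat.argmax(axis=4)
    out_data = np.take_along_axis(flat, idx[..., None], axis=4)[..., 0]

    def bw(g):
        gx = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=np.float32)
        ii, jj = np.divmod(idx, k)
        rows = (np.arange(oh) * stride)[None, None, :, None] + ii
        colz = (np.arange(ow) * stride)[None, None, None, :] + jj
        nn = np.arange(n)[:, None, None, None]
        cc = np.arange(c)[None, :, None, None]
        np.add.at(gx, (nn, cc, rows, colz), g)
        x._accumulate(gx[:, :, pad:pad + h, pad:pad + w] if pad else gx)

    return _make(out_data, (x,), bw)


def bce_mean(p: Tensor, y: np.ndarray, eps: float = 1e-7) -> Tensor:
    """Mean binary cross-entropy of probabilities ``p`` against labels ``y``.

    Probabilities are clamped to [eps, 1-eps] before the logarithm.
    """
    y = np.asarray(y, dtype=np.float32).reshape(p.shape)
    pc = np.clip(p.data, eps, 1.0 - eps)
    out_data = np.float32(-(y * np.log(pc) + (1 - y) * np.log(1 - pc)).mean())

    def bw(g):
        inside = (p.data > eps) & (p.data < 1.0 - eps)
        gp = np.where(inside, (pc - y) / (pc * (1 - pc)), 0.0) / p.data.size
        p._accumulate(g * gp.astype(np.float32))

    return _make(out_data, (p,), bw)
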