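"""Reverse-mode automatic differentiation over numpy arrays.

The training stack runs in CPU-only scientific Python environments without a
deep-learning framework, so the handful of differentiable operations the
magnifying-network needs are implemented here directly: broadcast
elementwise arithmetic, matmul, reductions, shape manipulation, strided 2-D
convolution, max pooling, and sparsemax.  Affine grid sampling lives in
:mod:`magnet._sampling`.

Gradients propagate through a dynamically built graph: every operation
records its parents together with one vector-Jacobian-product closure per
parent, and :meth:`Tensor.backward` walks the graph in reverse topological
order.  Arrays keep whatever float dtype they come in with (float32 for
model parameters, float64 in gradient-checking tests).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

__all__ = [
    "Tensor",
    "astensor",
    "concatenate",
    "conv2d",
    "maximum",
    "maxpool2d",
    "minimum",
    "sparsemax",
    "sparsemax_array",
    "stack",
]


def astensor(x) -> "Tensor":
    """Wrap ``x`` in a constant :class:`Tensor` unless it already is one."""
    return x if isinstance(x, Tensor) else Tensor(x)


_GRAD_ENABLED = True


class no_grad:
    """Context manager disabling graph construction (inference mode)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``g`` down to ``shape`` (inverse of numpy broadcasting)."""
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g.reshape(shape)


def _node(data, parents, vjps) -> "Tensor":
    out = Tensor(data)
    if _GRAD_ENABLED and any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = tuple(parents)
        out._vjps = tuple(vjps)
    return out


class Tensor:
    """A numpy array plus the bookkeeping needed for reverse-mode autodiff."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_vjps")

    def __init__(self, data, requires_grad: bool = False):
        arr = np.asarray(data)
        if not np.issubdtype(arr.dtype, np.floating):
            arr = arr.astype(np.float32)
        self.data = arr
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple = ()
        self._vjps: tuple = ()

    # -- basic introspection -------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    @property
    def dtype(self):
        return self.data.dtype

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def __len__(self):
        return len(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self):
        self.grad = None

    # -- autodiff ------------------------------------------------------------

    def backward(self, grad=None, free_graph: bool = True):
        """Accumulate gradients of ``self`` into every reachable leaf.

        With ``free_graph`` (the default) each node's edges are released as
        soon as its gradient has been propagated, so activation buffers held
        by vjp closures are freed progressively instead of lingering until
        the whole graph goes out of scope.
        """
        if grad is None:
            grad = np.ones_like(self.data)
        grads = {id(self): np.asarray(grad, dtype=self.data.dtype)}
        topo, seen = [], set()
        stack_ = [(self, False)]
        while stack_:  # iterative DFS; graphs can be deep (GRU over patches)
            node, processed = stack_.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack_.append((node, True))
            for p in node._parents:
                stack_.append((p, False))
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if not node._parents:
                node.grad = g if node.grad is None else node.grad + g
                continue
            for p, vjp in zip(node._parents, node._vjps):
                if not p.requires_grad or vjp is None:
                    continue
                contrib = _unbroadcast(np.asarray(vjp(g)), p.data.shape)
                acc = grads.get(id(p))
                grads[id(p)] = contrib if acc is None else acc + contrib
            if free_graph:
                node._parents = ()
                node._vjps = ()

    # -- elementwise arithmetic ----------------------------------------------

    def __add__(self, other):
        o = astensor(other)
        return _node(self.data + o.data, (self, o), (lambda g: g, lambda g: g))

    __radd__ = __add__

    def __neg__(self):
        return _node(-self.data, (self,), (lambda g: -g,))

    def __sub__(self, other):
        o = astensor(other)
        return _node(self.data - o.data, (self, o), (lambda g: g, lambda g: -g))

    def __rsub__(self, other):
        return astensor(other) - self

    def __mul__(self, other):
        o = astensor(other)
        return _node(
            self.data * o.data,
            (self, o),
            (lambda g: g * o.data, lambda g: g * self.data),
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        o = astensor(other)
        return _node(
            self.data / o.data,
            (self, o),
            (lambda g: g / o.data, lambda g: -g * self.data / o.data**2),
        )

    def __rtruediv__(self, other):
        return astensor(other) / self

    def __pow__(self, n):
        if not np.isscalar(n):
            raise TypeError("only scalar exponents are supported")
        return _node(
            self.data**n, (self,), (lambda g: g * n * self.data ** (n - 1),)
        )

    def __matmul__(self, other):
        o = astensor(other)
        a, b = self.data, o.data

        def vjp_a(g):
            if b.ndim == 1:
                return np.expand_dims(g, -1) * b
            return g @ np.swapaxes(b, -1, -2)

        def vjp_b(g):
            if b.ndim == 1:
                return np.tensordot(
                    g, a, axes=(tuple(range(g.ndim)), tuple(range(a.ndim - 1)))
                )
            if a.ndim == 1:
                return a[:, None] * g[None, :]
            return np.swapaxes(a, -1, -2) @ g

        return _node(a @ b, (self, o), (vjp_a, vjp_b))

    # -- nonlinearities ------------------------------------------------------

    def exp(self):
        out_data = np.exp(self.data)
        return _node(out_data, (self,), (lambda g: g * out_data,))

    def log(self):
        return _node(np.log(self.data), (self,), (lambda g: g / self.data,))

    def sqrt(self):
        out_data = np.sqrt(self.data)
        return _node(out_data, (self,), (lambda g: g / (2.0 * out_data),))

    def tanh(self):
        out_data = np.tanh(self.data)
        return _node(out_data, (self,), (lambda g: g * (1.0 - out_data**2),))

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))
        return _node(
            out_data, (self,), (lambda g: g * out_data * (1.0 - out_data),)
        )

    def relu(self):
        mask = self.data > 0
        return _node(self.data * mask, (self,), (lambda g: g * mask,))

    def abs(self):
        sign = np.sign(self.data)
        return _node(np.abs(self.data), (self,), (lambda g: g * sign,))

    # -- reductions ----------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def vjp(g):
            if axis is None:
                return np.broadcast_to(g, self.data.shape)
            if not keepdims:
                ax = axis if isinstance(axis, tuple) else (axis,)
                ax = tuple(a % self.data.ndim for a in ax)
                shape = tuple(
                    1 if i in ax else s for i, s in enumerate(self.data.shape)
                )
                g = g.reshape(shape)
            return np.broadcast_to(g, self.data.shape)

        return _node(out_data, (self,), (vjp,))

    def amax(self, axis=None, keepdims: bool = False):
        out_data = self.data.max(axis=axis, keepdims=keepdims)

        def vjp(g):
            expanded = self.data.max(axis=axis, keepdims=True)
            mask = self.data == expanded
            counts = mask.sum(axis=axis, keepdims=True)
            if not keepdims and axis is not None:
                ax = axis if isinstance(axis, tuple) else (axis,)
                ax = tuple(a % self.data.ndim for a in ax)
                shape = tuple(
                    1 if i in ax else s for i, s in enumerate(self.data.shape)
                )
                g = g.reshape(shape)
            return mask * (g / counts)

        return _node(out_data, (self,), (vjp,))

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            ax = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[a] for a in ax]))
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    # -- shape ops -----------------------------------------------------------

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape
        return _node(
            self.data.reshape(shape), (self,), (lambda g: g.reshape(old),)
        )

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = tuple(np.argsort(axes))
        return _node(
            self.data.transpose(axes), (self,), (lambda g: g.transpose(inv),)
        )

    def __getitem__(self, idx):
        def vjp(g):
            out = np.zeros_like(self.data)
            np.add.at(out, idx, g)
            return out

        return _node(self.data[idx], (self,), (vjp,))


# ---------------------------------------------------------------------------
# free functions
# ---------------------------------------------------------------------------


def maximum(a, b) -> Tensor:
    """Elementwise maximum; at ties the gradient flows to ``b``."""
    a, b = astensor(a), astensor(b)
    mask = a.data > b.data
    return _node(
        np.maximum(a.data, b.data),
        (a, b),
        (lambda g: g * mask, lambda g: g * ~mask),
    )


def minimum(a, b) -> Tensor:
    a, b = astensor(a), astensor(b)
    mask = a.data < b.data
    return _node(
        np.minimum(a.data, b.data),
        (a, b),
        (lambda g: g * mask, lambda g: g * ~mask),
    )


def concatenate(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [astensor(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def make_vjp(i):
        sl = [slice(None)] * data.ndim
        sl[axis] = slice(int(offsets[i]), int(offsets[i + 1]))
        sl = tuple(sl)
        return lambda g: g[sl]

    return _node(data, tuple(tensors), tuple(make_vjp(i) for i in range(len(tensors))))


def stack(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [astensor(t) for t in tensors]
    data = np.stack([t.data for t in tensors], axis=axis)

    def make_vjp(i):
        return lambda g: np.take(g, i, axis=axis)

    return _node(data, tuple(tensors), tuple(make_vjp(i) for i in range(len(tensors))))


# ---------------------------------------------------------------------------
# convolution / pooling
# ---------------------------------------------------------------------------


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, stride: int = 1,
           padding: int = 0) -> Tensor:
    """2-D cross-correlation of NCHW input ``x`` with OIkk weights ``w``.

    im2col + batched GEMM; the column buffer is rebuilt on the backward
    pass instead of being cached, trading one extra copy for k^2 lower
    retained memory.
    """
    x, w = astensor(x), astensor(w)
    xd, wd = x.data, w.data
    B, C, H, W = xd.shape
    O, C2, k, k2 = wd.shape
    if C2 != C or k != k2:
        raise ValueError(f"weight shape {wd.shape} incompatible with input {xd.shape}")
    s, p = int(stride), int(padding)
    if p:
        xp = np.zeros((B, C, H + 2 * p, W + 2 * p), dtype=xd.dtype)
        xp[:, :, p : p + H, p : p + W] = xd
    else:
        xp = xd
    Ho = (H + 2 * p - k) // s + 1
    Wo = (W + 2 * p - k) // s + 1

    def im2col():
        cols = np.empty((B, C, k, k, Ho, Wo), dtype=xd.dtype)
        for i in range(k):
            for j in range(k):
                cols[:, :, i, j] = xp[:, :, i : i + s * Ho : s, j : j + s * Wo : s]
        return cols.reshape(B, C * k * k, Ho * Wo)

    w_flat = wd.reshape(O, C * k * k)
    out_data = (w_flat @ im2col()).reshape(B, O, Ho, Wo)

    def vjp_x(g):
        gcols = (w_flat.T @ g.reshape(B, O, Ho * Wo)).reshape(
            B, C, k, k, Ho, Wo
        )
        gxp = np.zeros_like(xp)
        for i in range(k):
            for j in range(k):
                gxp[:, :, i : i + s * Ho : s, j : j + s * Wo : s] += gcols[:, :, i, j]
        return gxp[:, :, p : p + H, p : p + W] if p else gxp

    def vjp_w(g):
        cols_t = im2col().transpose(0, 2, 1)  # (B, HoWo, Ckk)
        gw = np.matmul(g.reshape(B, O, Ho * Wo), cols_t).sum(axis=0)
        return gw.reshape(wd.shape)

    out = _node(out_data, (x, w), (vjp_x, vjp_w))
    if b is not None:
        out = out + astensor(b).reshape(1, O, 1, 1)
    return out


def batchnorm2d(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5):
    """Fused training-mode batch normalisation over a NCHW batch.

    Returns ``(out, batch_mean, batch_var)`` with the batch statistics as
    plain arrays for running-average bookkeeping.
    """
    x, gamma, beta = astensor(x), astensor(gamma), astensor(beta)
    xd = x.data
    B, C, H, W = xd.shape
    n = B * H * W
    mu = xd.mean(axis=(0, 2, 3))
    var = ((xd - mu.reshape(1, C, 1, 1)) ** 2).mean(axis=(0, 2, 3))
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (xd - mu.reshape(1, C, 1, 1)) * inv.reshape(1, C, 1, 1)
    out_data = xhat * gamma.data.reshape(1, C, 1, 1) + beta.data.reshape(1, C, 1, 1)

    def vjp_x(g):
        dxhat = g * gamma.data.reshape(1, C, 1, 1)
        sum_d = dxhat.sum(axis=(0, 2, 3)).reshape(1, C, 1, 1)
        sum_dx = (dxhat * xhat).sum(axis=(0, 2, 3)).reshape(1, C, 1, 1)
        return (inv.reshape(1, C, 1, 1) / n) * (
            n * dxhat - sum_d - xhat * sum_dx
        )

    def vjp_gamma(g):
        return (g * xhat).sum(axis=(0, 2, 3))

    def vjp_beta(g):
        return g.sum(axis=(0, 2, 3))

    out = _node(out_data, (x, gamma, beta), (vjp_x, vjp_gamma, vjp_beta))
    return out, mu, var


def maxpool2d(x: Tensor, kernel: int = 3, stride: int = 1, padding: int = 1) -> Tensor:
    """Max pooling over NCHW input.  Tied maxima share the gradient equally."""
    x = astensor(x)
    xd = x.data
    B, C, H, W = xd.shape
    k, s, p = int(kernel), int(stride), int(padding)
    if p:
        xp = np.full((B, C, H + 2 * p, W + 2 * p), np.finfo(xd.dtype).min,
                     dtype=xd.dtype)
        xp[:, :, p : p + H, p : p + W] = xd
    else:
        xp = xd
    Ho = (xp.shape[2] - k) // s + 1
    Wo = (xp.shape[3] - k) // s + 1
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    win = win[:, :, ::s, ::s]  # (B,C,Ho,Wo,k,k)
    out_data = win.max(axis=(-2, -1))

    def vjp(g):
        mask = win == out_data[..., None, None]
        counts = mask.sum(axis=(-2, -1))
        scaled = (g / counts)[..., None, None] * mask
        gxp = np.zeros_like(xp)
        for i in range(k):
            for j in range(k):
                gxp[:, :, i : i + s * Ho : s, j : j + s * Wo : s] += scaled[..., i, j]
        return gxp[:, :, p : p + H, p : p + W] if p else gxp

    return _node(out_data, (x,), (vjp,))


# ---------------------------------------------------------------------------
# sparsemax
# ---------------------------------------------------------------------------


def sparsemax_array(z: np.ndarray, axis: int = -1) -> np.ndarray:
    """Euclidean projection of ``z`` onto the probability simplex along ``axis``.

    Vectorised sort-based algorithm; returns a dense array that sums to one
    along ``axis`` and may contain exact zeros.
    """
    z = np.asarray(z, dtype=np.float64)
    if z.size == 0:
        raise ValueError("sparsemax of an empty input")
    if not np.all(np.isfinite(z)):
        raise ValueError("sparsemax requires finite inputs")
    z = np.moveaxis(z, axis, -1)
    K = z.shape[-1]
    zs = -np.sort(-z, axis=-1)
    cum = np.cumsum(zs, axis=-1) - 1.0
    ks = np.arange(1, K + 1, dtype=np.float64)
    support = zs * ks > cum
    k_z = support.sum(axis=-1, keepdims=True)
    tau = np.take_along_axis(cum, k_z - 1, axis=-1) / k_z
    out = np.maximum(z - tau, 0.0)
    return np.moveaxis(out, -1, axis)


def sparsemax(x: Tensor, axis: int = -1) -> Tensor:
    """Differentiable sparsemax.

    The Jacobian restricted to the support S is ``I - 1/|S| * 11^T``; entries
    off the support get zero gradient.
    """
    x = astensor(x)
    out_data = sparsemax_array(x.data, axis=axis).astype(x.data.dtype)
    support = out_data > 0

    def vjp(g):
        nnz = support.sum(axis=axis, keepdims=True)
        inner = (g * support).sum(axis=axis, keepdims=True) / nnz
        return np.where(support, g - inner, 0.0).astype(g.dtype)

    return _node(out_data, (x,), (vjp,))
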