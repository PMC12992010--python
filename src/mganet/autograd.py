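"""Reverse-mode automatic differentiation over NumPy arrays.

A deliberately small tape-based engine: :class:`Tensor` wraps an
``ndarray``, records parents and a backward closure, and
:meth:`Tensor.backward` runs the reverse sweep in topological order.
Only the operations needed by the dual-branch network are provided
(elementwise algebra, reductions, matmul, 2-D convolution, max pooling
and bilinear resampling).  Everything is float64 and CPU-only, which is
plenty for the phantom-scale models this package trains.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "relu",
    "sigmoid",
    "exp",
    "log",
    "clip",
    "amin",
    "amax",
    "concat",
    "conv2d",
    "max_pool2d",
    "bilinear_resize",
    "interp_matrix",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, (g, s) in enumerate(zip(grad.shape, shape)):
        if s == 1 and g != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """An ndarray plus gradient bookkeeping."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in parents)
        self._parents = tuple(parents)
        self._backward = backward

    # -- introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def item(self) -> float:
        return float(self.data)

    # -- autodiff core -------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        """Accumulate gradients of ``self`` w.r.t. every ancestor."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without an explicit gradient needs a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
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
                if id(p) not in seen and p.requires_grad:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad = self.grad + grad

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic ----------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))

        out._backward = bwd
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))

        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __truediv__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data / other.data, parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(-g * self.data / (other.data ** 2), other.shape)
                )

        out._backward = bwd
        return out

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, exponent: float):
        out = Tensor(self.data ** exponent, parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * exponent * self.data ** (exponent - 1))

        out._backward = bwd
        return out

    def __matmul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data @ other.data, parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g @ other.data.T)
            if other.requires_grad:
                other._accumulate(self.data.T @ g)

        out._backward = bwd
        return out

    # -- reductions & shape --------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))

        def bwd(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.shape).copy())

        out._backward = bwd
        return out

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            n = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g.reshape(self.shape))

        out._backward = bwd
        return out


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# ---------------------------------------------------------------------
# elementwise nonlinearities
# ---------------------------------------------------------------------

def relu(x: Tensor) -> Tensor:
    x = as_tensor(x)
    mask = x.data > 0
    out = Tensor(np.where(mask, x.data, 0.0), parents=(x,))

    def bwd(g):
        if x.requires_grad:
            x._accumulate(g * mask)

    out._backward = bwd
    return out


def sigmoid(x: Tensor) -> Tensor:
    x = as_tensor(x)
    d = x.data
    s = np.where(d >= 0, 1.0 / (1.0 + np.exp(-np.abs(d))),
                 np.exp(-np.abs(d)) / (1.0 + np.exp(-np.abs(d))))
    out = Tensor(s, parents=(x,))

    def bwd(g):
        if x.requires_grad:
            x._accumulate(g * s * (1.0 - s))

    out._backward = bwd
    return out


def exp(x: Tensor) -> Tensor:
    x = as_tensor(x)
    e = np.exp(x.data)
    out = Tensor(e, parents=(x,))

    def bwd(g):
        if x.requires_grad:
            x._accumulate(g * e)

    out._backward = bwd
    return out


def log(x: Tensor) -> Tensor:
    x = as_tensor(x)
    out = Tensor(np.log(x.data), parents=(x,))

    def bwd(g):
        if x.requires_grad:
            x._accumulate(g / x.data)

    out._backward = bwd
    return out


def clip(x: Tensor, lo: float, hi: float) -> Tensor:
    """Clamp values; the gradient passes only through the interior."""
    x = as_tensor(x)
    inside = (x.data >= lo) & (x.data <= hi)
    out = Tensor(np.clip(x.data, lo, hi), parents=(x,))

    def bwd(g):
        if x.requires_grad:
            x._accumulate(g * inside)

    out._backward = bwd
    return out


def _extreme(x: Tensor, axis, keepdims: bool, op) -> Tensor:
    x = as_tensor(x)
    val = op(x.data, axis=axis, keepdims=True)
    hit = x.data == val
    nhit = hit.sum(axis=axis, keepdims=True)
    out_data = val if keepdims else np.squeeze(val, axis=axis)
    out = Tensor(out_data, parents=(x,))

    def bwd(g):
        if not x.requires_grad:
            return
        if not keepdims and axis is not None:
            g = np.reshape(g, val.shape)
        # ties share the gradient equally
        x._accumulate(np.broadcast_to(g / nhit, x.shape) * hit)

    out._backward = bwd
    return out


def amin(x: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    return _extreme(x, axis, keepdims, np.min)


def amax(x: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    return _extreme(x, axis, keepdims, np.max)


def concat(tensors, axis: int = 1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), parents=tuple(tensors))
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    out._backward = bwd
    return out


# ---------------------------------------------------------------------
# spatial operations (NCHW layout)
# ---------------------------------------------------------------------

def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None,
           stride: int = 1, padding: int = 0) -> Tensor:
    """2-D cross-correlation via im2col; x is (B,C,H,W), weight (O,C,kh,kw)."""
    x, weight = as_tensor(x), as_tensor(weight)
    B, C, H, W = x.shape
    O, Cw, kh, kw = weight.shape
    if C != Cw:
        raise ValueError(f"channel mismatch: input {C}, weight {Cw}")
    s, p = int(stride), int(padding)
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p))) if p else x.data
    Ho = (H + 2 * p - kh) // s + 1
    Wo = (W + 2 * p - kw) // s + 1
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    win = win[:, :, ::s, ::s]  # B,C,Ho,Wo,kh,kw
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(B * Ho * Wo, C * kh * kw)
    wmat = weight.data.reshape(O, C * kh * kw)
    out_data = cols @ wmat.T
    if bias is not None:
        out_data = out_data + bias.data
    out_data = out_data.reshape(B, Ho, Wo, O).transpose(0, 3, 1, 2)
    parents = (x, weight) if bias is None else (x, weight, bias)
    out = Tensor(out_data, parents=parents)

    def bwd(g):
        gmat = g.transpose(0, 2, 3, 1).reshape(B * Ho * Wo, O)
        if bias is not None and bias.requires_grad:
            bias._accumulate(gmat.sum(axis=0))
        if weight.requires_grad:
            weight._accumulate((gmat.T @ cols).reshape(weight.shape))
        if x.requires_grad:
            gcols = (gmat @ wmat).reshape(B, Ho, Wo, C, kh, kw).transpose(0, 3, 4, 5, 1, 2)
            gxp = np.zeros((B, C, H + 2 * p, W + 2 * p))
            for i in range(kh):
                for j in range(kw):
                    gxp[:, :, i:i + s * Ho:s, j:j + s * Wo:s] += gcols[:, :, i, j]
            x._accumulate(gxp[:, :, p:p + H, p:p + W] if p else gxp)

    out._backward = bwd
    return out


def max_pool2d(x: Tensor, kernel: int = 3, stride: int = 2, padding: int = 1) -> Tensor:
    x = as_tensor(x)
    B, C, H, W = x.shape
    k, s, p = int(kernel), int(stride), int(padding)
    fill = -np.inf
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p)), constant_values=fill) if p else x.data
    Ho = (H + 2 * p - k) // s + 1
    Wo = (W + 2 * p - k) // s + 1
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
    flat = win.reshape(B, C, Ho, Wo, k * k)
    arg = flat.argmax(axis=-1)
    out = Tensor(np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0], parents=(x,))

    def bwd(g):
        if not x.requires_grad:
            return
        onehot = np.zeros((B, C, Ho, Wo, k * k))
        np.put_along_axis(onehot, arg[..., None], 1.0, axis=-1)
        gwin = (onehot * g[..., None]).reshape(B, C, Ho, Wo, k, k).transpose(0, 1, 4, 5, 2, 3)
        gxp = np.zeros((B, C, H + 2 * p, W + 2 * p))
        for i in range(k):
            for j in range(k):
                gxp[:, :, i:i + s * Ho:s, j:j + s * Wo:s] += gwin[:, :, i, j]
        x._accumulate(gxp[:, :, p:p + H, p:p + W] if p else gxp)

    out._backward = bwd
    return out


@lru_cache(maxsize=256)
def interp_matrix(n_in: int, n_out: int) -> np.ndarray:
    """1-D bilinear interpolation matrix, half-pixel-center convention
    (sample centres at ``(i + 0.5) * n_in / n_out - 0.5``, edges clamped)."""
    M = np.zeros((n_out, n_in))
    if n_in == 1:
        M[:, 0] = 1.0
        return M
    src = (np.arange(n_out) + 0.5) * (n_in / n_out) - 0.5
    src = np.clip(src, 0.0, n_in - 1.0)
    i0 = np.floor(src).astype(int)
    i1 = np.minimum(i0 + 1, n_in - 1)
    frac = src - i0
    rows = np.arange(n_out)
    np.add.at(M, (rows, i0), 1.0 - frac)
    np.add.at(M, (rows, i1), frac)
    return M


def bilinear_resize(x: Tensor, out_h: int, out_w: int) -> Tensor:
    """Bilinear resample of the trailing two axes of an (...,H,W) tensor."""
    if out_h <= 0 or out_w <= 0:
        raise ValueError("target dimensions must be positive")
    x = as_tensor(x)
    H, W = x.shape[-2], x.shape[-1]
    if (H, W) == (out_h, out_w):
        return x * 1.0  # graph-preserving identity
    Mh = interp_matrix(H, out_h)
    Mw = interp_matrix(W, out_w)

    def apply(arr, Mr, Mc):  # rows/cols interpolation as two batched matmuls
        tmp = arr @ Mc.T
        return (tmp.swapaxes(-1, -2) @ Mr.T).swapaxes(-1, -2)

    out = Tensor(apply(x.data, Mh, Mw), parents=(x,))

    def bwd(g):
        if x.requires_grad:
            x._accumulate(apply(g, Mh.T, Mw.T))

    out._backward = bwd
    return out
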