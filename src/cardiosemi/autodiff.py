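"""Minimal reverse-mode automatic differentiation over NumPy arrays.

This is the numerical core the segmentation network and the differentiable
loss terms are built on.  It implements exactly the operator set the package
needs — elementwise arithmetic with broadcasting, matmul, reductions,
softmax, 3×3 convolution via im2col, 2×2 max-pooling, nearest-neighbour
upsampling and batch normalisation — each with a hand-written backward pass.
Gradients are accumulated by reverse topological traversal of the recorded
operation graph.

Arrays keep whatever float dtype they come in with; the network uses
float32, while the finite-difference gradient checks in the test-suite use
float64.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "Parameter",
    "no_grad",
    "is_grad_enabled",
    "concatenate",
    "conv2d",
    "max_pool2d",
    "upsample_nearest2x",
    "batch_norm2d",
    "softmax",
    "SGD",
]

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Context manager disabling graph construction (e.g. teacher forward)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum away prepended axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """An array node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        if isinstance(data, Tensor):
            data = data.data
        arr = np.asarray(data)
        if not np.issubdtype(arr.dtype, np.floating):
            arr = arr.astype(np.float32)
        self.data: np.ndarray = arr
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward: Callable[[], None] | None = None
        self._prev: tuple = ()

    # ---- plumbing -------------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    def __float__(self) -> float:
        return float(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            if g.dtype == self.data.dtype and g.shape == self.data.shape:
                # copy: g may alias another node's grad buffer
                self.grad = g.copy()
                return
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self) -> None:
        """Backpropagate from this (scalar or any-shape, seeded with ones)."""
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
            for child in node._prev:
                if id(child) not in seen:
                    stack.append((child, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward()
        # the graph is one-shot: drop the closures so the interpreter can
        # free intermediate buffers without waiting for cycle collection
        for node in topo:
            if node._prev:  # interior node: its grad is no longer needed
                node.grad = None
            node._backward = None
            node._prev = ()

    # ---- elementwise arithmetic ----------------------------------------

    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(np.asarray(other, dtype=self.dtype))
        out = _make(self.data + other.data, (self, other))
        if out._prev:
            def _bw():
                if self.requires_grad:
                    self._accumulate(_unbroadcast(out.grad, self.shape))
                if other.requires_grad:
                    other._accumulate(_unbroadcast(out.grad, other.shape))
            out._backward = _bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = _make(-self.data, (self,))
        if out._prev:
            def _bw():
                self._accumulate(-out.grad)
            out._backward = _bw
        return out

    def __sub__(self, other):
        return self + (-(other if isinstance(other, Tensor) else Tensor(np.asarray(other, dtype=self.dtype))))

    def __rsub__(self, other):
        return (-self) + other

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(np.asarray(other, dtype=self.dtype))
        out = _make(self.data * other.data, (self, other))
        if out._prev:
            def _bw():
                if self.requires_grad:
                    self._accumulate(_unbroadcast(out.grad * other.data, self.shape))
                if other.requires_grad:
                    other._accumulate(_unbroadcast(out.grad * self.data, other.shape))
            out._backward = _bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(np.asarray(other, dtype=self.dtype))
        out = _make(self.data / other.data, (self, other))
        if out._prev:
            def _bw():
                if self.requires_grad:
                    self._accumulate(_unbroadcast(out.grad / other.data, self.shape))
                if other.requires_grad:
                    other._accumulate(_unbroadcast(-out.grad * self.data / other.data ** 2, other.shape))
            out._backward = _bw
        return out

    def __rtruediv__(self, other):
        return Tensor(np.asarray(other, dtype=self.dtype)) / self

    def __pow__(self, p: float):
        out = _make(self.data ** p, (self,))
        if out._prev:
            def _bw():
                self._accumulate(out.grad * p * self.data ** (p - 1))
            out._backward = _bw
        return out

    # ---- matmul ---------------------------------------------------------

    def __matmul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = _make(self.data @ other.data, (self, other))
        if out._prev:
            def _bw():
                if self.requires_grad:
                    g = out.grad @ other.data.swapaxes(-1, -2)
                    self._accumulate(_unbroadcast(g, self.shape))
                if other.requires_grad:
                    g = self.data.swapaxes(-1, -2) @ out.grad
                    other._accumulate(_unbroadcast(g, other.shape))
            out._backward = _bw
        return out

    # ---- unary ----------------------------------------------------------

    def exp(self):
        out = _make(np.exp(self.data), (self,))
        if out._prev:
            def _bw():
                self._accumulate(out.grad * out.data)
            out._backward = _bw
        return out

    def log(self):
        out = _make(np.log(self.data), (self,))
        if out._prev:
            def _bw():
                self._accumulate(out.grad / self.data)
            out._backward = _bw
        return out

    def sqrt(self):
        out = _make(np.sqrt(self.data), (self,))
        if out._prev:
            def _bw():
                self._accumulate(out.grad * 0.5 / out.data)
            out._backward = _bw
        return out

    def relu(self):
        out = _make(np.maximum(self.data, 0), (self,))
        if out._prev:
            mask = self.data > 0
            def _bw():
                self._accumulate(out.grad * mask)
            out._backward = _bw
        return out

    # ---- reductions & shape --------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out = _make(self.data.sum(axis=axis, keepdims=keepdims), (self,))
        if out._prev:
            def _bw():
                g = out.grad
                if axis is not None and not keepdims:
                    g = np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(g, self.shape).copy())
            out._backward = _bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = _make(self.data.reshape(shape), (self,))
        if out._prev:
            def _bw():
                self._accumulate(out.grad.reshape(self.shape))
            out._backward = _bw
        return out

    def __getitem__(self, idx):
        """Slice along the leading axis (basic slices only)."""
        out = _make(self.data[idx], (self,))
        if out._prev:
            def _bw():
                g = np.zeros_like(self.data)
                g[idx] = out.grad
                self._accumulate(g)
            out._backward = _bw
        return out

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        out = _make(self.data.transpose(axes), (self,))
        if out._prev:
            inv = np.argsort(axes)
            def _bw():
                self._accumulate(out.grad.transpose(inv))
            out._backward = _bw
        return out


def Parameter(data) -> Tensor:
    """A trainable tensor."""
    return Tensor(np.asarray(data), requires_grad=True)


def _make(data: np.ndarray, children: Sequence[Tensor]) -> Tensor:
    out = Tensor(data)
    if _GRAD_ENABLED and any(c.requires_grad for c in children):
        out.requires_grad = True
        out._prev = tuple(children)
    return out


# ---- composite / structured operations ---------------------------------


def concatenate(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [t if isinstance(t, Tensor) else Tensor(t) for t in tensors]
    out = _make(np.concatenate([t.data for t in tensors], axis=axis), tensors)
    if out._prev:
        sizes = [t.shape[axis] for t in tensors]
        splits = np.cumsum(sizes)[:-1]
        def _bw():
            parts = np.split(out.grad, splits, axis=axis)
            for t, g in zip(tensors, parts):
                if t.requires_grad:
                    t._accumulate(g)
        out._backward = _bw
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable softmax along `axis`."""
    x = x if isinstance(x, Tensor) else Tensor(x)
    shifted = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    y = e / e.sum(axis=axis, keepdims=True)
    out = _make(y, (x,))
    if out._prev:
        def _bw():
            g = out.grad
            dot = (g * y).sum(axis=axis, keepdims=True)
            x._accumulate(y * (g - dot))
        out._backward = _bw
    return out


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, padding: int = 1) -> Tensor:
    """2-D convolution (stride 1, NCHW) via im2col + matmul.

    The column buffer is laid out (N, C·kh·kw, Ho·Wo) and filled with one
    contiguous slice-copy per kernel offset, so neither the forward nor the
    backward pass needs a large transposition.
    """
    x = x if isinstance(x, Tensor) else Tensor(x)
    n, cin, h, wd = x.shape
    cout, cin_w, kh, kw = w.shape
    if cin != cin_w:
        raise ValueError(f"channel mismatch: input {cin}, weight {cin_w}")
    p = padding
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p))) if p else x.data
    ho, wo = h + 2 * p - kh + 1, wd + 2 * p - kw + 1
    cols6 = np.empty((n, cin, kh, kw, ho, wo), dtype=x.dtype)
    for i in range(kh):
        for j in range(kw):
            cols6[:, :, i, j] = xp[:, :, i:i + ho, j:j + wo]
    cols = cols6.reshape(n, cin * kh * kw, ho * wo)
    wmat = w.data.reshape(cout, -1)
    out_flat = wmat @ cols  # (N, Cout, Ho*Wo)
    if b is not None:
        out_flat += b.data[:, None]
    y = out_flat.reshape(n, cout, ho, wo)
    children = (x, w) if b is None else (x, w, b)
    out = _make(y, children)
    if out._prev:
        def _bw():
            gy = out.grad.reshape(n, cout, ho * wo)
            if w.requires_grad:
                # batched GEMM with B transposed in-place (no copy of cols)
                gw = np.matmul(gy, cols.swapaxes(1, 2)).sum(axis=0)
                w._accumulate(gw.reshape(w.shape))
            if b is not None and b.requires_grad:
                b._accumulate(gy.sum(axis=(0, 2)))
            if x.requires_grad:
                gcols = (wmat.T @ gy).reshape(n, cin, kh, kw, ho, wo)
                gxp = np.zeros_like(xp) if p else np.zeros_like(x.data)
                for i in range(kh):
                    for j in range(kw):
                        gxp[:, :, i:i + ho, j:j + wo] += gcols[:, :, i, j]
                x._accumulate(gxp[:, :, p:p + h, p:p + wd] if p else gxp)
        out._backward = _bw
    return out


def max_pool2d(x: Tensor) -> Tensor:
    """2×2 max pooling with stride 2; ties route the gradient to the first
    maximal element (deterministic)."""
    x = x if isinstance(x, Tensor) else Tensor(x)
    n, c, h, w = x.shape
    if h % 2 or w % 2:
        raise ValueError(f"spatial dims must be even for 2x2 pooling, got {h}x{w}")
    r = np.ascontiguousarray(
        x.data.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    ).reshape(n, c, h // 2, w // 2, 4)
    idx = r.argmax(axis=-1)
    y = np.take_along_axis(r, idx[..., None], axis=-1)[..., 0]
    out = _make(y, (x,))
    if out._prev:
        def _bw():
            g4 = np.zeros_like(r)
            np.put_along_axis(g4, idx[..., None], out.grad[..., None], axis=-1)
            g = g4.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
            x._accumulate(np.ascontiguousarray(g).reshape(n, c, h, w))
        out._backward = _bw
    return out


def upsample_nearest2x(x: Tensor) -> Tensor:
    x = x if isinstance(x, Tensor) else Tensor(x)
    n, c, h, w = x.shape
    y = x.data.repeat(2, axis=2).repeat(2, axis=3)
    out = _make(y, (x,))
    if out._prev:
        def _bw():
            g = out.grad.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5))
            x._accumulate(g)
        out._backward = _bw
    return out


def batch_norm2d(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    training: bool,
    momentum: float = 0.1,
    eps: float = 1e-5,
) -> Tensor:
    """Per-channel batch normalisation over (N, H, W).

    In training mode the batch statistics normalise the activations and the
    running buffers are updated in place (biased variance, as used for
    normalisation).  In evaluation mode the running buffers are used.
    """
    x = x if isinstance(x, Tensor) else Tensor(x)
    n, c, h, w = x.shape
    xd = x.data
    if training:
        m = n * h * w
        mean = xd.mean(axis=(0, 2, 3))
        var = xd.var(axis=(0, 2, 3))
        running_mean *= 1 - momentum
        running_mean += momentum * mean
        running_var *= 1 - momentum
        running_var += momentum * var
    else:
        mean, var = running_mean, running_var
        m = None
    invstd = 1.0 / np.sqrt(var + eps)
    xhat = (xd - mean[None, :, None, None]) * invstd[None, :, None, None]
    y = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]
    out = _make(y, (x, gamma, beta))
    if out._prev:
        def _bw():
            gy = out.grad
            if gamma.requires_grad:
                gamma._accumulate((gy * xhat).sum(axis=(0, 2, 3)))
            if beta.requires_grad:
                beta._accumulate(gy.sum(axis=(0, 2, 3)))
            if x.requires_grad:
                gxhat = gy * gamma.data[None, :, None, None]
                if training:
                    # standard batch-norm backward through the batch statistics
                    sum_g = gxhat.sum(axis=(0, 2, 3), keepdims=True)
                    sum_gx = (gxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
                    gx = (gxhat - sum_g / m - xhat * sum_gx / m) * invstd[None, :, None, None]
                else:
                    gx = gxhat * invstd[None, :, None, None]
                x._accumulate(gx)
        out._backward = _bw
    return out


# ---- optimiser ----------------------------------------------------------


class SGD:
    """Stochastic gradient descent with momentum and weight decay."""

    def __init__(self, params: Iterable[Tensor], lr: float, momentum: float = 0.9,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self._velocity = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self, lr: float | None = None) -> None:
        lr = self.lr if lr is None else lr
        for p, v in zip(self.params, self._velocity):
            if p.grad is None:
                continue
            g = p.grad + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data -= (lr * v).astype(p.data.dtype, copy=False)

    def state_dict(self) -> dict:
        return {"velocity": [v.copy() for v in self._velocity]}

    def load_state_dict(self, state: dict) -> None:
        self._velocity = [np.asarray(v).copy() for v in state["velocity"]]
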