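"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Provides exactly the primitives the coupled segmentation/annotator model
needs: broadcasting arithmetic, batched matmul, reductions, 3x3 "same"
convolution via im2col, 2x2 max-pooling, nearest-neighbour upsampling,
log-softmax and an Adam optimiser.  Gradients are accumulated into
``Tensor.grad`` by :meth:`Tensor.backward` over a topologically sorted graph.

All data is float64; gradient-checking against central finite differences is
part of the test suite.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "Adam",
    "concat",
    "conv2d",
    "log_softmax",
    "softmax",
    "maxpool2",
    "upsample2",
    "relu",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """A NumPy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._parents: tuple[Tensor, ...] = ()
        self._backward: Callable[[], None] | None = None

    # -- graph plumbing ----------------------------------------------------
    @staticmethod
    def _result(data, parents: tuple["Tensor", ...], backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = parents
            out._backward = backward(out)
        return out

    def _accum(self, g: np.ndarray) -> None:
        if not self.requires_grad:
            return
        g = _unbroadcast(g, self.data.shape)
        self.grad = g if self.grad is None else self.grad + g

    def backward(self) -> None:
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward()

    # -- basic arithmetic --------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def __add__(self, other):
        other = as_tensor(other)

        def bwd(out):
            def fn():
                self._accum(out.grad)
                other._accum(out.grad)
            return fn

        return Tensor._result(self.data + other.data, (self, other), bwd)

    __radd__ = __add__

    def __neg__(self):
        def bwd(out):
            def fn():
                self._accum(-out.grad)
            return fn

        return Tensor._result(-self.data, (self,), bwd)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)

        def bwd(out):
            def fn():
                self._accum(out.grad * other.data)
                other._accum(out.grad * self.data)
            return fn

        return Tensor._result(self.data * other.data, (self, other), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)

        def bwd(out):
            def fn():
                self._accum(out.grad / other.data)
                other._accum(-out.grad * self.data / other.data**2)
            return fn

        return Tensor._result(self.data / other.data, (self, other), bwd)

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, exponent: float):
        e = float(exponent)

        def bwd(out):
            def fn():
                self._accum(out.grad * e * self.data ** (e - 1.0))
            return fn

        return Tensor._result(self.data**e, (self,), bwd)

    def __matmul__(self, other):
        other = as_tensor(other)

        def bwd(out):
            def fn():
                self._accum(np.matmul(out.grad, np.swapaxes(other.data, -1, -2)))
                other._accum(np.matmul(np.swapaxes(self.data, -1, -2), out.grad))
            return fn

        return Tensor._result(np.matmul(self.data, other.data), (self, other), bwd)

    # -- shape ops ---------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        src = self.data.shape

        def bwd(out):
            def fn():
                self._accum(out.grad.reshape(src))
            return fn

        return Tensor._result(self.data.reshape(shape), (self,), bwd)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def bwd(out):
            def fn():
                self._accum(out.grad.transpose(inv))
            return fn

        return Tensor._result(self.data.transpose(axes), (self,), bwd)

    # -- reductions --------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        src = self.data.shape

        def bwd(out):
            def fn():
                g = out.grad
                if axis is not None and not keepdims:
                    axes = axis if isinstance(axis, tuple) else (axis,)
                    g = np.expand_dims(g, axes)
                self._accum(np.broadcast_to(g, src))
            return fn

        return Tensor._result(self.data.sum(axis=axis, keepdims=keepdims), (self,), bwd)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- elementwise nonlinearities ---------------------------------------
    def log(self):
        def bwd(out):
            def fn():
                self._accum(out.grad / self.data)
            return fn

        return Tensor._result(np.log(self.data), (self,), bwd)

    def exp(self):
        def bwd(out):
            def fn():
                self._accum(out.grad * out.data)
            return fn

        return Tensor._result(np.exp(self.data), (self,), bwd)

    def clip_min(self, low: float):
        """Clamp below at ``low``; gradient is zero in the clamped region."""
        mask = self.data > low

        def bwd(out):
            def fn():
                self._accum(out.grad * mask)
            return fn

        return Tensor._result(np.maximum(self.data, low), (self,), bwd)

    def softplus(self):
        # log(1+e^x), computed stably; derivative is the logistic sigmoid
        def bwd(out):
            def fn():
                self._accum(out.grad / (1.0 + np.exp(-self.data)))
            return fn

        data = np.logaddexp(0.0, self.data)
        return Tensor._result(data, (self,), bwd)

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0

    def bwd(out):
        def fn():
            x._accum(out.grad * mask)
        return fn

    return Tensor._result(x.data * mask, (x,), bwd)


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    m = x.data.max(axis=axis, keepdims=True)
    z = x.data - m
    lse = np.log(np.exp(z).sum(axis=axis, keepdims=True))
    out_data = z - lse
    sm = np.exp(out_data)

    def bwd(out):
        def fn():
            g = out.grad
            x._accum(g - sm * g.sum(axis=axis, keepdims=True))
        return fn

    return Tensor._result(out_data, (x,), bwd)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    return log_softmax(x, axis=axis).exp()


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(out):
        def fn():
            for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
                sl = [slice(None)] * out.grad.ndim
                sl[axis] = slice(a, b)
                t._accum(out.grad[tuple(sl)])
        return fn

    return Tensor._result(
        np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), bwd
    )


def _im2col(xp: np.ndarray, kh: int, kw: int, oh: int, ow: int) -> np.ndarray:
    n, c = xp.shape[:2]
    s = xp.strides
    view = np.lib.stride_tricks.as_strided(
        xp, (n, oh, ow, c, kh, kw), (s[0], s[2], s[3], s[1], s[2], s[3])
    )
    return view.reshape(n * oh * ow, c * kh * kw)


def conv2d(x: Tensor, w: Tensor, b: Tensor, pad: int | None = None) -> Tensor:
    """2D convolution, NCHW layout, stride 1, zero 'same' padding by default."""
    n, c, h, wd = x.data.shape
    o, _, kh, kw = w.data.shape
    if pad is None:
        pad = kh // 2
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    oh, ow = h + 2 * pad - kh + 1, wd + 2 * pad - kw + 1
    cols = _im2col(xp, kh, kw, oh, ow)
    wm = w.data.reshape(o, -1)
    out_data = (cols @ wm.T + b.data).reshape(n, oh, ow, o).transpose(0, 3, 1, 2)

    def bwd(out):
        def fn():
            gm = out.grad.transpose(0, 2, 3, 1).reshape(n * oh * ow, o)
            if w.requires_grad:
                w._accum((gm.T @ cols).reshape(w.data.shape))
            if b.requires_grad:
                b._accum(gm.sum(axis=0))
            if x.requires_grad:
                dcols = (gm @ wm).reshape(n, oh, ow, c, kh, kw)
                dxp = np.zeros_like(xp)
                for i in range(kh):
                    for j in range(kw):
                        dxp[:, :, i : i + oh, j : j + ow] += dcols[
                            :, :, :, :, i, j
                        ].transpose(0, 3, 1, 2)
                x._accum(dxp[:, :, pad : pad + h, pad : pad + wd])
        return fn

    return Tensor._result(out_data, (x, w, b), bwd)


def maxpool2(x: Tensor) -> Tensor:
    """2x2 max pooling, stride 2; spatial dims must be even."""
    n, c, h, w = x.data.shape
    x4 = x.data.reshape(n, c, h // 2, 2, w // 2, 2)
    out_data = x4.max(axis=(3, 5))
    mask = x4 == out_data[:, :, :, None, :, None]
    # split gradient evenly across tied maxima so backward stays well-defined
    mask = mask / mask.sum(axis=(3, 5), keepdims=True)

    def bwd(out):
        def fn():
            g = out.grad[:, :, :, None, :, None] * mask
            x._accum(g.reshape(n, c, h, w))
        return fn

    return Tensor._result(out_data, (x,), bwd)


def upsample2(x: Tensor) -> Tensor:
    """Nearest-neighbour upsampling by a factor of 2."""
    n, c, h, w = x.data.shape

    def bwd(out):
        def fn():
            x._accum(out.grad.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5)))
        return fn

    return Tensor._result(
        np.repeat(np.repeat(x.data, 2, axis=2), 2, axis=3), (x,), bwd
    )


class Adam:
    """Adam optimiser over a list of parameter Tensors."""

    def __init__(self, params: Sequence[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
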