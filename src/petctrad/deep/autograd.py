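"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations the 2.5D CNNs need: broadcasting
arithmetic, matmul, 2D convolution (im2col), max pooling, reductions,
tanh/softplus/sigmoid/exp/log and reshaping.  Gradients flow through a
dynamically built tape; ``Var.backward()`` runs a topological sweep.

Desk-scale by design: numpy + BLAS, float32 throughout, no fusion.
"""

from __future__ import annotations

from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np

__all__ = ["Var", "conv2d", "maxpool2d", "no_grad", "relu_like_ops"]

_GRAD_ENABLED = [True]


class no_grad:
    """Context manager disabling tape construction (inference mode)."""

    def __enter__(self):
        self._prior = _GRAD_ENABLED[0]
        _GRAD_ENABLED[0] = False

    def __exit__(self, *exc):
        _GRAD_ENABLED[0] = self._prior
        return False


def _attach(out: "Var", bw: Callable[[], None]) -> None:
    """Register a backward closure only when the output needs gradients.

    Skipping the closure in inference mode avoids reference cycles that
    would otherwise keep every intermediate activation alive.
    """
    if out.requires_grad:
        out._backward = bw
    else:
        out._prev = ()


def _unbroadcast(grad: np.ndarray, shape: Tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Var:
    """A node in the autodiff tape: value, gradient, and backward closure."""

    __slots__ = ("data", "grad", "_backward", "_prev", "requires_grad")

    def __init__(self, data, requires_grad: bool = False, _prev: Sequence["Var"] = ()):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: Optional[np.ndarray] = None
        self._backward: Optional[Callable[[], None]] = None
        self._prev = tuple(_prev)
        self.requires_grad = _GRAD_ENABLED[0] and (
            requires_grad or any(p.requires_grad for p in _prev)
        )

    # -- graph bookkeeping ------------------------------------------------
    def _accumulate(self, g: np.ndarray) -> None:
        # closures hand over freshly allocated arrays, so the first
        # accumulation can take ownership instead of zero-filling
        if self.grad is None:
            self.grad = g if g.flags.writeable and g.shape == self.data.shape else np.array(
                np.broadcast_to(g, self.data.shape)
            )
        else:
            self.grad = self.grad + g

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo: List[Var] = []
        seen = set()

        def visit(v: "Var"):
            if id(v) in seen or not v.requires_grad:
                return
            seen.add(id(v))
            for p in v._prev:
                visit(p)
            topo.append(v)

        visit(self)
        self.grad = np.ones_like(self.data)
        for v in reversed(topo):
            if v._backward is not None:
                v._backward()
            if v._prev:
                # free the tape eagerly: closures hold large buffers and
                # form reference cycles the garbage collector is slow to find
                v._backward = None
                v._prev = ()
                v.grad = None

    @property
    def shape(self):
        return self.data.shape

    # -- arithmetic -------------------------------------------------------
    def _lift(self, other) -> "Var":
        return other if isinstance(other, Var) else Var(other)

    def __add__(self, other):
        other = self._lift(other)
        out = Var(self.data + other.data, _prev=(self, other))

        def bw():
            if self.requires_grad:
                self._accumulate(_unbroadcast(out.grad, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(out.grad, other.data.shape))

        _attach(out, bw)
        return out

    __radd__ = __add__

    def __neg__(self):
        return self * -1.0

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = Var(self.data * other.data, _prev=(self, other))

        def bw():
            if self.requires_grad:
                self._accumulate(_unbroadcast(out.grad * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(out.grad * self.data, other.data.shape))

        _attach(out, bw)
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return self._lift(other) * self ** -1.0

    def __pow__(self, p: float):
        out = Var(self.data**p, _prev=(self,))

        def bw():
            if self.requires_grad:
                self._accumulate(out.grad * p * self.data ** (p - 1))

        _attach(out, bw)
        return out

    def matmul(self, other: "Var") -> "Var":
        other = self._lift(other)
        out = Var(self.data @ other.data, _prev=(self, other))

        def bw():
            if self.requires_grad:
                self._accumulate(out.grad @ other.data.T)
            if other.requires_grad:
                other._accumulate(self.data.T @ out.grad)

        _attach(out, bw)
        return out

    __matmul__ = matmul

    # -- reductions & reshaping ------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Var":
        out = Var(self.data.sum(axis=axis, keepdims=keepdims), _prev=(self,))
        shape = self.data.shape

        def bw():
            if not self.requires_grad:
                return
            g = out.grad
            if axis is not None and not keepdims:
                axes = (axis,) if isinstance(axis, int) else axis
                for ax in sorted(a % self.data.ndim for a in axes):
                    g = np.expand_dims(g, ax)
            self._accumulate(np.broadcast_to(g, shape).copy())

        _attach(out, bw)
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Var":
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a % self.data.ndim] for a in ((axis,) if isinstance(axis, int) else axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape) -> "Var":
        out = Var(self.data.reshape(*shape), _prev=(self,))

        def bw():
            if self.requires_grad:
                self._accumulate(out.grad.reshape(self.data.shape))

        _attach(out, bw)
        return out

    # -- nonlinearities ---------------------------------------------------
    def tanh(self) -> "Var":
        t = np.tanh(self.data)
        out = Var(t, _prev=(self,))

        def bw():
            if self.requires_grad:
                self._accumulate(out.grad * (1 - t**2))

        _attach(out, bw)
        return out

    def softplus(self) -> "Var":
        # stable: log(1 + e^x) = max(x, 0) + log1p(e^{-|x|})
        e = np.exp(-np.abs(self.data))
        sp = np.maximum(self.data, 0) + np.log1p(e)
        out = Var(sp, _prev=(self,))

        def bw():
            if self.requires_grad:
                sig = np.where(self.data >= 0, 1.0 / (1.0 + e), e / (1.0 + e))
                self._accumulate((out.grad * sig).astype(np.float32))

        _attach(out, bw)
        return out

    def sigmoid(self) -> "Var":
        s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))
        out = Var(s, _prev=(self,))

        def bw():
            if self.requires_grad:
                self._accumulate(out.grad * s * (1 - s))

        _attach(out, bw)
        return out

    def log(self) -> "Var":
        out = Var(np.log(self.data), _prev=(self,))

        def bw():
            if self.requires_grad:
                self._accumulate(out.grad / self.data)

        _attach(out, bw)
        return out

    def exp(self) -> "Var":
        e = np.exp(self.data)
        out = Var(e, _prev=(self,))

        def bw():
            if self.requires_grad:
                self._accumulate(out.grad * e)

        _attach(out, bw)
        return out


# ---------------------------------------------------------------------------
# structured ops
# ---------------------------------------------------------------------------


def _im2col(x: np.ndarray, kh: int, kw: int, pad: int):
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    oh, ow = h + 2 * pad - kh + 1, w + 2 * pad - kw + 1
    s0, s1, s2, s3 = x.strides
    cols = np.lib.stride_tricks.as_strided(
        x, (n, c, kh, kw, oh, ow), (s0, s1, s2, s3, s2, s3), writeable=False
    )
    return cols.reshape(n, c * kh * kw, oh * ow), oh, ow


def conv2d(x: Var, weight: Var, bias: Var, pad: int = 1) -> Var:
    """NCHW convolution, stride 1, symmetric zero padding."""
    n, c, h, w = x.data.shape
    co, ci, kh, kw = weight.data.shape
    cols, oh, ow = _im2col(x.data, kh, kw, pad)
    wmat = weight.data.reshape(co, ci * kh * kw)
    out_data = np.matmul(wmat[None], np.ascontiguousarray(cols)) + bias.data.reshape(1, co, 1)
    out = Var(out_data.reshape(n, co, oh, ow), _prev=(x, weight, bias))

    def bw():
        g = out.grad.reshape(n, co, oh * ow)
        if bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 2)))
        if weight.requires_grad:
            # recompute the im2col view (not captured: it is large)
            cols_b, _, _ = _im2col(x.data, kh, kw, pad)
            gw = np.matmul(g, np.ascontiguousarray(cols_b).transpose(0, 2, 1)).sum(axis=0)
            weight._accumulate(gw.reshape(weight.data.shape))
        if x.requires_grad:
            gcols = np.matmul(wmat.T[None], g)  # (n, c*kh*kw, oh*ow)
            gx = np.zeros((n, c, h + 2 * pad, w + 2 * pad))
            gcols = gcols.reshape(n, c, kh, kw, oh, ow)
            for i in range(kh):
                for j in range(kw):
                    gx[:, :, i : i + oh, j : j + ow] += gcols[:, :, i, j]
            if pad:
                gx = gx[:, :, pad:-pad, pad:-pad]
            x._accumulate(gx)

    _attach(out, bw)
    return out


def maxpool2d(x: Var, k: int = 2) -> Var:
    n, c, h, w = x.data.shape
    oh, ow = h // k, w // k
    view = x.data[:, :, : oh * k, : ow * k].reshape(n, c, oh, k, ow, k)
    flat = view.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, oh, ow, k * k)
    arg = flat.argmax(axis=-1)
    out = Var(np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0], _prev=(x,))

    def bw():
        if not x.requires_grad:
            return
        gflat = np.zeros_like(flat)
        np.put_along_axis(gflat, arg[..., None], out.grad[..., None], axis=-1)
        g = gflat.reshape(n, c, oh, ow, k, k).transpose(0, 1, 2, 4, 3, 5).reshape(
            n, c, oh * k, ow * k
        )
        gx = np.zeros_like(x.data)
        gx[:, :, : oh * k, : ow * k] = g
        x._accumulate(gx)

    _attach(out, bw)
    return out


def relu_like_ops():  # pragma: no cover - introspection helper
    return ["tanh", "softplus", "sigmoid", "exp", "log"]
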