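"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Only the operations needed by the pose encoders, projector head and the
contrastive/probe losses are implemented: broadcasting arithmetic, matmul,
exp/log/pow, relu, reductions, reshape/transpose, concatenation and a 2-D
convolution (im2col).  Gradients are accumulated by a topological sweep over
the tape; every primitive's backward is verified against central finite
differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "conv2d"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after NumPy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    """An array node on the autodiff tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- construction helpers -------------------------------------------------

    @classmethod
    def _from_op(cls, data, parents, backward):
        out = cls(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    # -- arithmetic -----------------------------------------------------------

    @staticmethod
    def _coerce(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._coerce(other)

        def backward(grad, a=self, b=other):
            if a.requires_grad:
                a._accumulate(_unbroadcast(grad, a.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(grad, b.shape))

        return Tensor._from_op(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(grad, a=self):
            if a.requires_grad:
                a._accumulate(-grad)

        return Tensor._from_op(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        other = self._coerce(other)

        def backward(grad, a=self, b=other):
            if a.requires_grad:
                a._accumulate(_unbroadcast(grad * b.data, a.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(grad * a.data, b.shape))

        return Tensor._from_op(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._coerce(other)

        def backward(grad, a=self, b=other):
            if a.requires_grad:
                a._accumulate(_unbroadcast(grad / b.data, a.shape))
            if b.requires_grad:
                b._accumulate(
                    _unbroadcast(-grad * a.data / (b.data**2), b.shape)
                )

        return Tensor._from_op(self.data / other.data, (self, other), backward)

    def __rtruediv__(self, other):
        return self._coerce(other) / self

    def __matmul__(self, other):
        other = self._coerce(other)

        def backward(grad, a=self, b=other):
            if a.requires_grad:
                a._accumulate(grad @ b.data.T)
            if b.requires_grad:
                b._accumulate(a.data.T @ grad)

        return Tensor._from_op(self.data @ other.data, (self, other), backward)

    def pow(self, exponent: float):
        def backward(grad, a=self, p=exponent):
            if a.requires_grad:
                a._accumulate(grad * p * a.data ** (p - 1))

        return Tensor._from_op(self.data**exponent, (self,), backward)

    def sqrt(self):
        return self.pow(0.5)

    def exp(self):
        out_data = np.exp(self.data)

        def backward(grad, a=self, o=out_data):
            if a.requires_grad:
                a._accumulate(grad * o)

        return Tensor._from_op(out_data, (self,), backward)

    def log(self):
        def backward(grad, a=self):
            if a.requires_grad:
                a._accumulate(grad / a.data)

        return Tensor._from_op(np.log(self.data), (self,), backward)

    def relu(self):
        mask = self.data > 0

        def backward(grad, a=self, m=mask):
            if a.requires_grad:
                a._accumulate(grad * m)

        return Tensor._from_op(self.data * mask, (self,), backward)

    # -- reductions & shape ---------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        def backward(grad, a=self, ax=axis, kd=keepdims):
            if not a.requires_grad:
                return
            g = grad
            if ax is not None and not kd:
                g = np.expand_dims(g, ax)
            a._accumulate(np.broadcast_to(g, a.shape).copy())

        return Tensor._from_op(
            self.data.sum(axis=axis, keepdims=keepdims), (self,), backward
        )

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        def backward(grad, a=self):
            if a.requires_grad:
                a._accumulate(grad.reshape(a.shape))

        return Tensor._from_op(self.data.reshape(*shape), (self,), backward)

    def transpose(self, *axes):
        axes = axes or None

        def backward(grad, a=self, ax=axes):
            if a.requires_grad:
                inv = np.argsort(ax) if ax is not None else None
                a._accumulate(grad.transpose(inv) if ax else grad.T)

        return Tensor._from_op(self.data.transpose(axes), (self,), backward)

    @property
    def T(self):
        return self.transpose()

    # -- backward pass --------------------------------------------------------

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(grad, dtype=np.float64)
        else:
            self.grad += grad

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        order: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for parent in node._parents:
                if id(parent) not in seen:
                    stack.append((parent, False))
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    def __repr__(self):  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._coerce(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(grad, ts=tensors, offs=offsets, ax=axis):
        for t, lo, hi in zip(ts, offs[:-1], offs[1:]):
            if t.requires_grad:
                idx = [slice(None)] * grad.ndim
                idx[ax] = slice(lo, hi)
                t._accumulate(grad[tuple(idx)])

    return Tensor._from_op(
        np.concatenate([t.data for t in tensors], axis=axis), tensors, backward
    )


def conv2d(x: Tensor, weight: Tensor, bias: Tensor, stride: int = 1, padding: int = 0) -> Tensor:
    """2-D cross-correlation on NCHW input via im2col.

    ``weight`` is (out_channels, in_channels, kh, kw); ``bias`` (out_channels,).
    """
    n, c, h, w = x.shape
    oc, ic, kh, kw = weight.shape
    if ic != c:
        raise ValueError(f"channel mismatch: input has {c}, kernel expects {ic}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    hp, wp = xp.shape[2], xp.shape[3]
    ho = (hp - kh) // stride + 1
    wo = (wp - kw) // stride + 1
    windows = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    windows = windows[:, :, ::stride, ::stride]  # (n, c, ho, wo, kh, kw)
    cols = windows.transpose(0, 2, 3, 1, 4, 5).reshape(n, ho, wo, c * kh * kw)
    wmat = weight.data.reshape(oc, -1)
    out = cols @ wmat.T + bias.data  # (n, ho, wo, oc)
    out = np.ascontiguousarray(out.transpose(0, 3, 1, 2))

    def backward(grad, x=x, weight=weight, bias=bias, cols=cols, wmat=wmat):
        g = grad.transpose(0, 2, 3, 1)  # (n, ho, wo, oc)
        if bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 1, 2)))
        if weight.requires_grad:
            gw = g.reshape(-1, oc).T @ cols.reshape(-1, c * kh * kw)
            weight._accumulate(gw.reshape(weight.shape))
        if x.requires_grad:
            gcols = (g @ wmat).reshape(n, ho, wo, c, kh, kw)
            gxp = np.zeros((n, c, hp, wp))
            for i in range(kh):
                for j in range(kw):
                    gxp[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += (
                        gcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
                    )
            if padding:
                gxp = gxp[:, :, padding:-padding, padding:-padding]
            x._accumulate(gxp)

    return Tensor._from_op(out, (x, weight, bias), backward)
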