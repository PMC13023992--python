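"""Minimal reverse-mode automatic differentiation on numpy arrays.

Define-by-run: every operation returns a new :class:`Tensor` holding its
parents and a closure that propagates the upstream gradient.  ``backward``
walks the graph in reverse topological order.  Only the operations needed by
the dual-stream network are implemented; each op's gradient is exercised by
finite-difference checks in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "stack_last", "no_grad"]


class _NoGrad:
    enabled = False

    def __enter__(self):
        self.prev = _NoGrad.enabled
        _NoGrad.enabled = True
        return self

    def __exit__(self, *exc):
        _NoGrad.enabled = self.prev
        return False


def no_grad() -> _NoGrad:
    return _NoGrad()


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum a broadcast gradient back down to ``shape``."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward", "name")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None,
                 name: str = ""):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad) and not _NoGrad.enabled
        self.grad: np.ndarray | None = None
        self._parents = parents if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None
        self.name = name

    # ---- bookkeeping ------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad=None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, grad: np.ndarray) -> None:
        grad = _unbroadcast(np.asarray(grad, dtype=np.float64), self.data.shape)
        self.grad = grad if self.grad is None else self.grad + grad

    # ---- elementwise arithmetic ------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data + other.data,
                     requires_grad=self.requires_grad or other.requires_grad,
                     parents=(self, other))
        if out.requires_grad:
            def bwd(g, a=self, b=other):
                if a.requires_grad:
                    a._accum(g)
                if b.requires_grad:
                    b._accum(g)
            out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, requires_grad=self.requires_grad, parents=(self,))
        if out.requires_grad:
            out._backward = lambda g, a=self: a._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return Tensor._lift(other) + (-self)

    def __mul__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data * other.data,
                     requires_grad=self.requires_grad or other.requires_grad,
                     parents=(self, other))
        if out.requires_grad:
            def bwd(g, a=self, b=other):
                if a.requires_grad:
                    a._accum(g * b.data)
                if b.requires_grad:
                    b._accum(g * a.data)
            out._backward = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data / other.data,
                     requires_grad=self.requires_grad or other.requires_grad,
                     parents=(self, other))
        if out.requires_grad:
            def bwd(g, a=self, b=other):
                if a.requires_grad:
                    a._accum(g / b.data)
                if b.requires_grad:
                    b._accum(-g * a.data / (b.data ** 2))
            out._backward = bwd
        return out

    def __rtruediv__(self, other):
        return Tensor._lift(other) / self

    def pow(self, exponent: float) -> "Tensor":
        out = Tensor(self.data ** exponent, requires_grad=self.requires_grad,
                     parents=(self,))
        if out.requires_grad:
            out._backward = lambda g, a=self, e=exponent: a._accum(
                g * e * a.data ** (e - 1))
        return out

    def sqrt(self) -> "Tensor":
        return self.pow(0.5)

    def exp(self) -> "Tensor":
        val = np.exp(self.data)
        out = Tensor(val, requires_grad=self.requires_grad, parents=(self,))
        if out.requires_grad:
            out._backward = lambda g, a=self, v=val: a._accum(g * v)
        return out

    def log(self) -> "Tensor":
        out = Tensor(np.log(self.data), requires_grad=self.requires_grad, parents=(self,))
        if out.requires_grad:
            out._backward = lambda g, a=self: a._accum(g / a.data)
        return out

    def clip(self, lo: float, hi: float) -> "Tensor":
        val = np.clip(self.data, lo, hi)
        out = Tensor(val, requires_grad=self.requires_grad, parents=(self,))
        if out.requires_grad:
            inside = (self.data > lo) & (self.data < hi)
            out._backward = lambda g, a=self, m=inside: a._accum(g * m)
        return out

    def relu(self) -> "Tensor":
        mask = self.data > 0
        out = Tensor(self.data * mask, requires_grad=self.requires_grad, parents=(self,))
        if out.requires_grad:
            out._backward = lambda g, a=self, m=mask: a._accum(g * m)
        return out

    def sigmoid(self) -> "Tensor":
        val = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(val, requires_grad=self.requires_grad, parents=(self,))
        if out.requires_grad:
            out._backward = lambda g, a=self, v=val: a._accum(g * v * (1.0 - v))
        return out

    def softplus(self) -> "Tensor":
        # numerically stable log(1 + exp(x))
        val = np.logaddexp(0.0, self.data)
        out = Tensor(val, requires_grad=self.requires_grad, parents=(self,))
        if out.requires_grad:
            sig = 1.0 / (1.0 + np.exp(-self.data))
            out._backward = lambda g, a=self, s=sig: a._accum(g * s)
        return out

    def tanh(self) -> "Tensor":
        val = np.tanh(self.data)
        out = Tensor(val, requires_grad=self.requires_grad, parents=(self,))
        if out.requires_grad:
            out._backward = lambda g, a=self, v=val: a._accum(g * (1.0 - v ** 2))
        return out

    # ---- reductions / shaping --------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                     requires_grad=self.requires_grad, parents=(self,))
        if out.requires_grad:
            def bwd(g, a=self, ax=axis, kd=keepdims):
                if ax is not None and not kd:
                    g = np.expand_dims(g, ax)
                a._accum(np.broadcast_to(g, a.data.shape))
            out._backward = bwd
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max(self, axis: int, keepdims: bool = False) -> "Tensor":
        val = self.data.max(axis=axis, keepdims=True)
        out_val = val if keepdims else np.squeeze(val, axis=axis)
        out = Tensor(out_val, requires_grad=self.requires_grad, parents=(self,))
        if out.requires_grad:
            mask = (self.data == val)
            mask = mask / mask.sum(axis=axis, keepdims=True)  # split ties
            def bwd(g, a=self, m=mask, ax=axis, kd=keepdims):
                if not kd:
                    g = np.expand_dims(g, ax)
                a._accum(g * m)
            out._backward = bwd
        return out

    def reshape(self, *shape) -> "Tensor":
        out = Tensor(self.data.reshape(*shape), requires_grad=self.requires_grad,
                     parents=(self,))
        if out.requires_grad:
            out._backward = lambda g, a=self: a._accum(g.reshape(a.data.shape))
        return out

    def transpose(self, *axes) -> "Tensor":
        out = Tensor(self.data.transpose(*axes), requires_grad=self.requires_grad,
                     parents=(self,))
        if out.requires_grad:
            inv = np.argsort(axes)
            out._backward = lambda g, a=self, iv=inv: a._accum(g.transpose(iv))
        return out

    def __getitem__(self, idx) -> "Tensor":
        out = Tensor(self.data[idx], requires_grad=self.requires_grad, parents=(self,))
        if out.requires_grad:
            def bwd(g, a=self, i=idx):
                full = np.zeros_like(a.data)
                np.add.at(full, i, g)
                a._accum(full)
            out._backward = bwd
        return out

    # ---- linear algebra ---------------------------------------------------
    def matmul(self, other: "Tensor") -> "Tensor":
        other = Tensor._lift(other)
        out = Tensor(self.data @ other.data,
                     requires_grad=self.requires_grad or other.requires_grad,
                     parents=(self, other))
        if out.requires_grad:
            def bwd(g, a=self, b=other):
                if a.requires_grad:
                    ga = g @ np.swapaxes(b.data, -1, -2)
                    a._accum(_unbroadcast(ga, a.data.shape))
                if b.requires_grad:
                    gb = np.swapaxes(a.data, -1, -2) @ g
                    b._accum(_unbroadcast(gb, b.data.shape))
            out._backward = bwd
        return out

    __matmul__ = matmul


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 requires_grad=any(t.requires_grad for t in tensors),
                 parents=tuple(tensors))
    if out.requires_grad:
        sizes = [t.data.shape[axis] for t in tensors]
        splits = np.cumsum(sizes)[:-1]
        def bwd(g, ts=tensors, sp=splits, ax=axis):
            for t, piece in zip(ts, np.split(g, sp, axis=ax)):
                if t.requires_grad:
                    t._accum(piece)
        out._backward = bwd
    return out


def stack_last(tensors: list[Tensor]) -> Tensor:
    """Stack along a new trailing axis."""
    return concat([t.reshape(*t.shape, 1) for t in tensors], axis=-1)
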