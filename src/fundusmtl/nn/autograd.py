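"""Minimal reverse-mode automatic differentiation on numpy arrays.

The package's networks are small enough (10^4-10^6 parameters, 64-224 px
inputs) that a tape-based numpy engine is adequate on a single CPU.  Only the
operations the encoder-decoder architecture needs are provided: broadcasted
arithmetic, matmul, reductions, concatenation, (transposed) convolution via
im2col, pooling, bilinear upsampling, and pointwise nonlinearities.

All tensors are float32 by default.  Gradients are accumulated into
``Tensor.grad`` by :meth:`Tensor.backward` through a topological sort of the
recorded graph.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "no_grad"]

_GRAD_ENABLED = [True]


class no_grad:
    """Context manager disabling graph recording (inference mode)."""

    def __enter__(self):
        _GRAD_ENABLED.append(False)
        return self

    def __exit__(self, *exc):
        _GRAD_ENABLED.pop()
        return False


def _as_array(x) -> np.ndarray:
    a = np.asarray(x)
    if a.dtype == np.float64:       # explicit float64 is preserved so
        return a                    # gradients can be verified tightly
    if a.dtype != np.float32:
        a = a.astype(np.float32)
    return a


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents", "name")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        self.data = _as_array(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) and _GRAD_ENABLED[-1]
        self._parents = _parents if self.requires_grad else ()
        self._backward = _backward if self.requires_grad else None
        self.name = None

    # ------------------------------------------------------------------ utils
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    def numpy(self) -> np.ndarray:
        return self.data

    def zero_grad(self):
        self.grad = None

    def _accumulate(self, g: np.ndarray):
        if self.grad is None:
            self.grad = np.array(g, dtype=self.data.dtype)
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None):
        """Backpropagate from this tensor (default seed: ones)."""
        if not self.requires_grad:
            raise RuntimeError("backward() on a tensor that does not require grad")
        if grad is None:
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
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # ------------------------------------------------------------- arithmetic
    @staticmethod
    def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
        """Sum gradient ``g`` down to ``shape`` (reverse numpy broadcasting)."""
        if g.shape == shape:
            return g
        extra = g.ndim - len(shape)
        if extra > 0:
            g = g.sum(axis=tuple(range(extra)))
        axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
        if axes:
            g = g.sum(axis=axes, keepdims=True)
        return g

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _binary(self, other, fwd, bwd_a, bwd_b) -> "Tensor":
        other = Tensor._lift(other)
        out_data = fwd(self.data, other.data)
        req = self.requires_grad or other.requires_grad
        out = Tensor(out_data, requires_grad=req, _parents=(self, other))
        if out.requires_grad:
            def _backward(g, a=self, b=other):
                if a.requires_grad:
                    a._accumulate(Tensor._unbroadcast(bwd_a(g, a.data, b.data), a.data.shape))
                if b.requires_grad:
                    b._accumulate(Tensor._unbroadcast(bwd_b(g, a.data, b.data), b.data.shape))
            out._backward = _backward
        return out

    def __add__(self, other):
        return self._binary(other, lambda a, b: a + b,
                            lambda g, a, b: g, lambda g, a, b: g)

    __radd__ = __add__

    def __sub__(self, other):
        return self._binary(other, lambda a, b: a - b,
                            lambda g, a, b: g, lambda g, a, b: -g)

    def __rsub__(self, other):
        return Tensor._lift(other).__sub__(self)

    def __mul__(self, other):
        return self._binary(other, lambda a, b: a * b,
                            lambda g, a, b: g * b, lambda g, a, b: g * a)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self._binary(other, lambda a, b: a / b,
                            lambda g, a, b: g / b,
                            lambda g, a, b: -g * a / (b * b))

    def __rtruediv__(self, other):
        return Tensor._lift(other).__truediv__(self)

    def __neg__(self):
        return self * (-1.0)

    def __pow__(self, p: float):
        p = float(p)
        out = Tensor(self.data ** p, requires_grad=self.requires_grad, _parents=(self,))
        if out.requires_grad:
            def _backward(g, a=self):
                a._accumulate(g * p * a.data ** (p - 1.0))
            out._backward = _backward
        return out

    def __matmul__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data @ other.data,
                     requires_grad=self.requires_grad or other.requires_grad,
                     _parents=(self, other))
        if out.requires_grad:
            def _backward(g, a=self, b=other):
                if a.requires_grad:
                    a._accumulate(g @ b.data.T)
                if b.requires_grad:
                    b._accumulate(a.data.T @ g)
            out._backward = _backward
        return out

    # -------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                     requires_grad=self.requires_grad, _parents=(self,))
        if out.requires_grad:
            def _backward(g, a=self, axis=axis, keepdims=keepdims):
                if axis is not None and not keepdims:
                    g = np.expand_dims(g, axis)
                a._accumulate(np.broadcast_to(g, a.data.shape).copy())
            out._backward = _backward
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # ------------------------------------------------------------ shape manip
    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), requires_grad=self.requires_grad,
                     _parents=(self,))
        if out.requires_grad:
            def _backward(g, a=self):
                a._accumulate(g.reshape(a.data.shape))
            out._backward = _backward
        return out

    def transpose(self, axes) -> "Tensor":
        out = Tensor(self.data.transpose(axes), requires_grad=self.requires_grad,
                     _parents=(self,))
        if out.requires_grad:
            inv = np.argsort(axes)
            def _backward(g, a=self, inv=tuple(inv)):
                a._accumulate(g.transpose(inv))
            out._backward = _backward
        return out

    # ---------------------------------------------------------- nonlinearities
    def relu(self) -> "Tensor":
        out = Tensor(np.maximum(self.data, 0.0), requires_grad=self.requires_grad,
                     _parents=(self,))
        if out.requires_grad:
            mask = self.data > 0
            def _backward(g, a=self, mask=mask):
                a._accumulate(g * mask)
            out._backward = _backward
        return out

    def sigmoid(self) -> "Tensor":
        s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60.0, 60.0)))
        out = Tensor(s, requires_grad=self.requires_grad, _parents=(self,))
        if out.requires_grad:
            def _backward(g, a=self, s=s):
                a._accumulate(g * s * (1.0 - s))
            out._backward = _backward
        return out

    def log(self) -> "Tensor":
        out = Tensor(np.log(self.data), requires_grad=self.requires_grad,
                     _parents=(self,))
        if out.requires_grad:
            def _backward(g, a=self):
                a._accumulate(g / a.data)
            out._backward = _backward
        return out

    def clip(self, lo: float, hi: float) -> "Tensor":
        """Clamp values; gradient passes only through the unclipped region."""
        out = Tensor(np.clip(self.data, lo, hi), requires_grad=self.requires_grad,
                     _parents=(self,))
        if out.requires_grad:
            mask = (self.data >= lo) & (self.data <= hi)
            def _backward(g, a=self, mask=mask):
                a._accumulate(g * mask)
            out._backward = _backward
        return out


# -------------------------------------------------------------------- helpers
def concat(tensors: list, axis: int = 1) -> Tensor:
    """Concatenate tensors along ``axis`` (differentiable)."""
    datas = [t.data for t in tensors]
    out = Tensor(np.concatenate(datas, axis=axis),
                 requires_grad=any(t.requires_grad for t in tensors),
                 _parents=tuple(tensors))
    if out.requires_grad:
        sizes = [d.shape[axis] for d in datas]
        splits = np.cumsum(sizes)[:-1]
        def _backward(g, ts=tensors, splits=splits, axis=axis):
            for t, piece in zip(ts, np.split(g, splits, axis=axis)):
                if t.requires_grad:
                    t._accumulate(piece)
        out._backward = _backward
    return out
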