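"""Minimal reverse-mode automatic differentiation over numpy arrays.

The package's physics-informed training needs gradients of a composite loss
with respect to recurrent-network weights and musculoskeletal parameters.
This module provides a small dynamic tape: :class:`Tensor` wraps an
``ndarray`` and records the operations applied to it; :meth:`Tensor.backward`
accumulates vector-Jacobian products in reverse topological order.

Design constraints:

* floating dtypes are preserved (float64 default; the training hot path may
  run in float32 for speed, while gradient-vs-finite-difference checks use
  float64 tensors);
* every elementwise primitive (`exp`, `sin`, `where`, ...) also accepts plain
  numpy inputs and falls back to numpy, so physical-model code written against
  this module runs identically inside and outside the tape;
* broadcasting follows numpy semantics; gradients of broadcast operands are
  summed back to the operand's shape.

Hot loops may additionally register fused primitives with hand-written VJPs
(see :func:`mskpinn.cells.gru_window_forward`); those are cross-checked
against the unfused op-by-op path in the tests.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "asarray",
    "is_tensor",
    "value_of",
    "exp",
    "log",
    "sqrt",
    "sin",
    "cos",
    "tanh",
    "sigmoid",
    "where",
    "maximum",
    "minimum",
    "clip",
    "matmul",
    "concatenate",
    "mean",
    "total",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` over axes that were broadcast from ``shape``."""
    if grad.shape == shape:
        return grad
    # leading axes added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # axes of size 1 that were stretched
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A node of the autodiff tape wrapping a floating-point numpy array."""

    __slots__ = ("value", "grad", "_parents", "requires_grad")

    # make numpy defer to the reflected operators instead of broadcasting
    # over Tensor as an object scalar
    __array_ufunc__ = None
    __array_priority__ = 1000

    def __init__(self, value, requires_grad: bool = False, parents=()):
        value = np.asarray(value)
        if not np.issubdtype(value.dtype, np.floating):
            value = value.astype(np.float64)
        self.value = value
        self.grad = None
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p, _ in parents
        )
        # parents: sequence of (Tensor, vjp) where vjp(upstream) -> grad wrt parent
        self._parents = tuple(parents) if self.requires_grad else ()

    # -- basic protocol ----------------------------------------------------
    @property
    def shape(self):
        return self.value.shape

    @property
    def ndim(self):
        return self.value.ndim

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.value.shape}, requires_grad={self.requires_grad})"

    # -- graph construction ------------------------------------------------
    def _binary(self, other, fwd, vjp_self, vjp_other):
        other_t = other if isinstance(other, Tensor) else Tensor(other)
        out_val = fwd(self.value, other_t.value)
        parents = []
        if self.requires_grad:
            parents.append((self, lambda g: _unbroadcast(vjp_self(g, self.value, other_t.value), self.value.shape)))
        if other_t.requires_grad:
            parents.append((other_t, lambda g: _unbroadcast(vjp_other(g, self.value, other_t.value), other_t.value.shape)))
        return Tensor(out_val, parents=parents)

    def __add__(self, other):
        return self._binary(other, lambda a, b: a + b, lambda g, a, b: g, lambda g, a, b: g)

    __radd__ = __add__

    def __sub__(self, other):
        return self._binary(other, lambda a, b: a - b, lambda g, a, b: g, lambda g, a, b: -g)

    def __rsub__(self, other):
        return (-self).__add__(other)

    def __mul__(self, other):
        return self._binary(other, lambda a, b: a * b, lambda g, a, b: g * b, lambda g, a, b: g * a)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self._binary(
            other,
            lambda a, b: a / b,
            lambda g, a, b: g / b,
            lambda g, a, b: -g * a / (b * b),
        )

    def __rtruediv__(self, other):
        return Tensor(other).__truediv__(self)

    def __neg__(self):
        parents = [(self, lambda g: -g)] if self.requires_grad else []
        return Tensor(-self.value, parents=parents)

    def __pow__(self, exponent):
        if not np.isscalar(exponent):
            raise TypeError("only scalar exponents are supported")
        out = Tensor(
            self.value**exponent,
            parents=[(self, lambda g: g * exponent * self.value ** (exponent - 1))]
            if self.requires_grad
            else [],
        )
        return out

    def __matmul__(self, other):
        other_t = other if isinstance(other, Tensor) else Tensor(other)
        out_val = self.value @ other_t.value
        parents = []
        if self.requires_grad:
            parents.append((self, lambda g: g @ other_t.value.T))
        if other_t.requires_grad:
            parents.append((other_t, lambda g: self.value.T @ g))
        return Tensor(out_val, parents=parents)

    def __rmatmul__(self, other):
        return Tensor(other).__matmul__(self)

    def __getitem__(self, idx):
        def vjp(g):
            out = np.zeros_like(self.value)
            np.add.at(out, idx, g)
            return out

        parents = [(self, vjp)] if self.requires_grad else []
        return Tensor(self.value[idx], parents=parents)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], tuple):
            shape = shape[0]
        parents = (
            [(self, lambda g: g.reshape(self.value.shape))] if self.requires_grad else []
        )
        return Tensor(self.value.reshape(shape), parents=parents)

    def sum(self, axis=None, keepdims=False):
        out_val = self.value.sum(axis=axis, keepdims=keepdims)

        def vjp(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return np.broadcast_to(g, self.value.shape).copy()

        parents = [(self, vjp)] if self.requires_grad else []
        return Tensor(out_val, parents=parents)

    def mean(self, axis=None, keepdims=False):
        n = self.value.size if axis is None else self.value.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / n

    # -- backward pass -----------------------------------------------------
    def backward(self, grad=None):
        """Accumulate gradients of ``self`` (summed if non-scalar) into leaves."""
        if grad is None:
            grad = np.ones_like(self.value)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for parent, _ in node._parents:
                stack.append((parent, False))
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.grad is None:
                node.grad = g.copy() if node._parents == () else g
            else:
                node.grad = node.grad + g
            for parent, vjp in node._parents:
                contrib = vjp(g)
                if id(parent) in grads:
                    grads[id(parent)] = grads[id(parent)] + contrib
                else:
                    grads[id(parent)] = contrib

    def zero_grad(self):
        self.grad = None


# -- dispatching helpers ----------------------------------------------------

def is_tensor(x) -> bool:
    return isinstance(x, Tensor)


def value_of(x) -> np.ndarray:
    return x.value if isinstance(x, Tensor) else np.asarray(x)


def asarray(x, requires_grad: bool = False) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x, requires_grad=requires_grad)


def _unary(x, fwd, dfwd):
    if isinstance(x, Tensor):
        out_val = fwd(x.value)
        parents = [(x, lambda g: g * dfwd(x.value, out_val))] if x.requires_grad else []
        return Tensor(out_val, parents=parents)
    x = np.asarray(x)
    if not np.issubdtype(x.dtype, np.floating):
        x = x.astype(np.float64)
    return fwd(x)


def exp(x):
    return _unary(x, np.exp, lambda v, o: o)


def log(x):
    return _unary(x, np.log, lambda v, o: 1.0 / v)


def sqrt(x):
    return _unary(x, np.sqrt, lambda v, o: 0.5 / o)


def sin(x):
    return _unary(x, np.sin, lambda v, o: np.cos(v))


def cos(x):
    return _unary(x, np.cos, lambda v, o: -np.sin(v))


def tanh(x):
    return _unary(x, np.tanh, lambda v, o: 1.0 - o * o)


def _sigmoid_np(v):
    # numerically stable logistic: exp only of non-positive arguments
    v = np.asarray(v)
    e = np.exp(-np.abs(v))
    return np.where(v >= 0, 1.0 / (1.0 + e), e / (1.0 + e))


def sigmoid(x):
    if isinstance(x, Tensor):
        out_val = _sigmoid_np(x.value)
        parents = (
            [(x, lambda g: g * out_val * (1.0 - out_val))] if x.requires_grad else []
        )
        return Tensor(out_val, parents=parents)
    return _sigmoid_np(np.asarray(x))


def where(cond, a, b):
    cond = value_of(cond).astype(bool)
    if not (isinstance(a, Tensor) or isinstance(b, Tensor)):
        return np.where(cond, a, b)
    a_t = asarray(a)
    b_t = asarray(b)
    out_val = np.where(cond, a_t.value, b_t.value)
    parents = []
    if a_t.requires_grad:
        parents.append((a_t, lambda g: _unbroadcast(np.where(cond, g, 0.0), a_t.value.shape)))
    if b_t.requires_grad:
        parents.append((b_t, lambda g: _unbroadcast(np.where(cond, 0.0, g), b_t.value.shape)))
    return Tensor(out_val, parents=parents)


def maximum(a, b):
    return where(value_of(a) >= value_of(b), a, b)


def minimum(a, b):
    return where(value_of(a) <= value_of(b), a, b)


def clip(x, lo, hi):
    return minimum(maximum(x, lo), hi)


def matmul(a, b):
    if isinstance(a, Tensor) or isinstance(b, Tensor):
        return asarray(a) @ asarray(b)
    return np.asarray(a) @ np.asarray(b)


def concatenate(parts, axis=0):
    if not any(isinstance(p, Tensor) for p in parts):
        return np.concatenate(parts, axis=axis)
    tensors = [asarray(p) for p in parts]
    out_val = np.concatenate([t.value for t in tensors], axis=axis)
    parents = []
    offset = 0
    for t in tensors:
        size = t.value.shape[axis]
        sl = [slice(None)] * out_val.ndim
        sl[axis] = slice(offset, offset + size)
        sl = tuple(sl)
        if t.requires_grad:
            parents.append((t, lambda g, sl=sl: g[sl]))
        offset += size
    return Tensor(out_val, parents=parents)


def mean(x, axis=None):
    if isinstance(x, Tensor):
        return x.mean(axis=axis)
    return np.mean(x, axis=axis)


def total(x, axis=None):
    """Sum that dispatches on Tensor/ndarray (``sum`` shadows the builtin)."""
    if isinstance(x, Tensor):
        return x.sum(axis=axis)
    return np.sum(x, axis=axis)
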