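"""Minimal reverse-mode automatic differentiation on numpy arrays.

This is the differentiation core behind the descriptor regressor and the
evidential loss functions. It supports exactly the operations those modules
need (dense linear algebra on small arrays, smooth elementwise functions,
reductions) and nothing more. Gradients are accumulated by a topological
backward sweep; broadcasting is handled by summing gradients over the
broadcast axes.

All free functions (``log``, ``exp``, ``tanh``, ``softplus``, ``lgamma``,
``absolute`` ...) dispatch on their argument: they accept either a
:class:`Tensor` (returning a graph node) or a plain numpy array / scalar
(returning numpy values). The evidential loss formulas are written once
against this interface and serve both training (graph mode) and evaluation
(plain numpy).
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln as _gammaln, psi as _psi


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce ``grad`` so its shape matches ``shape`` after broadcasting."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    # sum over axes that were size-1 in the original
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A node in the computation graph wrapping a numpy array."""

    __slots__ = ("value", "grad", "_parents", "_backward", "requires_grad")

    # make numpy defer to the reflected operators instead of building
    # object arrays when an ndarray meets a Tensor
    __array_ufunc__ = None

    def __init__(self, value, parents=(), backward=None, requires_grad=True):
        self.value = np.asarray(value, dtype=float)
        self.grad = None
        self._parents = tuple(parents)
        self._backward = backward
        self.requires_grad = requires_grad

    # -- graph plumbing ---------------------------------------------------
    @property
    def shape(self):
        return self.value.shape

    def backward(self):
        if self.value.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo, seen = [], set()

        def visit(node):
            if id(node) in seen:
                return
            seen.add(id(node))
            for p in node._parents:
                visit(p)
            topo.append(node)

        visit(self)
        for node in topo:
            node.grad = np.zeros_like(node.value)
        self.grad = np.ones_like(self.value)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other):
        other = _as_tensor(other)

        def bwd(g):
            self.grad += _unbroadcast(g, self.shape)
            other.grad += _unbroadcast(g, other.shape)

        return Tensor(self.value + other.value, (self, other), bwd)

    __radd__ = __add__

    def __neg__(self):
        def bwd(g):
            self.grad += -g

        return Tensor(-self.value, (self,), bwd)

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __mul__(self, other):
        other = _as_tensor(other)

        def bwd(g):
            self.grad += _unbroadcast(g * other.value, self.shape)
            other.grad += _unbroadcast(g * self.value, other.shape)

        return Tensor(self.value * other.value, (self, other), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _as_tensor(other)

        def bwd(g):
            self.grad += _unbroadcast(g / other.value, self.shape)
            other.grad += _unbroadcast(-g * self.value / other.value**2, other.shape)

        return Tensor(self.value / other.value, (self, other), bwd)

    def __rtruediv__(self, other):
        return _as_tensor(other) / self

    def __pow__(self, p):
        if not np.isscalar(p):
            raise TypeError("only scalar exponents are supported")

        def bwd(g):
            self.grad += g * p * self.value ** (p - 1)

        return Tensor(self.value**p, (self,), bwd)

    def __matmul__(self, other):
        other = _as_tensor(other)

        def bwd(g):
            self.grad += g @ other.value.T
            other.grad += self.value.T @ g

        return Tensor(self.value @ other.value, (self, other), bwd)

    def __rmatmul__(self, other):
        return _as_tensor(other) @ self

    @property
    def T(self):
        def bwd(g):
            self.grad += g.T

        return Tensor(self.value.T, (self,), bwd)

    def __getitem__(self, idx):
        def bwd(g):
            np.add.at(self.grad, idx, g)

        return Tensor(self.value[idx], (self,), bwd)

    def reshape(self, *shape):
        def bwd(g):
            self.grad += g.reshape(self.shape)

        return Tensor(self.value.reshape(*shape), (self,), bwd)

    def sum(self, axis=None, keepdims=False):
        def bwd(g):
            if axis is None:
                self.grad += np.broadcast_to(g, self.shape)
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self.grad += np.broadcast_to(gg, self.shape)

        return Tensor(self.value.sum(axis=axis, keepdims=keepdims), (self,), bwd)

    def mean(self, axis=None, keepdims=False):
        n = self.value.size if axis is None else self.value.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / n


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x, requires_grad=False)


def constant(x) -> Tensor:
    """Wrap an array as a non-learnable graph node."""
    return Tensor(x, requires_grad=False)


# -- elementwise functions, dispatching on Tensor vs ndarray ---------------

def _unary(x, fval, fgrad):
    if isinstance(x, Tensor):
        out_val = fval(x.value)

        def bwd(g):
            x.grad += g * fgrad(x.value, out_val)

        return Tensor(out_val, (x,), bwd)
    xv = np.asarray(x, dtype=float)
    return fval(xv)


def tanh(x):
    return _unary(x, np.tanh, lambda v, o: 1.0 - o**2)


def exp(x):
    return _unary(x, np.exp, lambda v, o: o)


def log(x):
    return _unary(x, np.log, lambda v, o: 1.0 / v)


def sqrt(x):
    return _unary(x, np.sqrt, lambda v, o: 0.5 / o)


def absolute(x):
    return _unary(x, np.abs, lambda v, o: np.sign(v))


def softplus(x):
    """log(1 + exp(x)), computed in an overflow-safe form."""

    def fval(v):
        return np.logaddexp(0.0, v)

    def fgrad(v, o):
        return 1.0 / (1.0 + np.exp(-v))  # sigmoid

    return _unary(x, fval, fgrad)


def lgamma(x):
    return _unary(x, _gammaln, lambda v, o: _psi(v))


def pair_contract(jac: np.ndarray, g):
    """Contract a constant pair Jacobian with descriptor gradients.

    ``jac`` has shape (B, P, K) — the derivative of each of P descriptor
    components with respect to the K flattened Cartesian coordinates; ``g``
    has shape (B, P). Returns shape (B, K). Used to map dE/d(descriptor)
    to Cartesian gradients.
    """
    if isinstance(g, Tensor):
        out_val = np.einsum("bpk,bp->bk", jac, g.value)

        def bwd(grad):
            g.grad += np.einsum("bpk,bk->bp", jac, grad)

        return Tensor(out_val, (g,), bwd)
    return np.einsum("bpk,bp->bk", jac, np.asarray(g, dtype=float))


def value_of(x) -> np.ndarray:
    """The underlying numpy value of a Tensor, or the input itself."""
    return x.value if isinstance(x, Tensor) else np.asarray(x, dtype=float)
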