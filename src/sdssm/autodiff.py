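"""Reverse-mode automatic differentiation on NumPy arrays.

A small tape-based engine in the micrograd/autograd lineage, sized for the
per-timestep dense/recurrent conditioner networks used by the state-space
models in this package.  Every operation either returns a plain ``float`` /
``ndarray`` (when no argument tracks gradients) or a :class:`Tensor` node
recording its parents and a local backward rule.  Broadcasting follows NumPy
semantics; gradients of broadcast operands are summed back to their shape.

Graphs are walked iteratively in :meth:`Tensor.backward`, so sequence models
with tens of thousands of nodes do not hit the recursion limit.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "parameter",
    "constant",
    "add", "sub", "mul", "div", "neg", "power", "matmul",
    "exp", "log", "tanh", "sigmoid", "relu", "clip", "square", "sqrt",
    "sum_", "mean_", "concat", "reshape", "getitem",
    "softmax", "log_softmax", "logsumexp",
    "value_of",
]


def _asarray(x) -> np.ndarray:
    if isinstance(x, np.ndarray) and x.dtype == np.float64:
        return x
    return np.asarray(x, dtype=np.float64)


def value_of(x):
    """Underlying ndarray of a Tensor, or the input coerced to float64."""
    return x.value if isinstance(x, Tensor) else _asarray(x)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` over axes that were broadcast to reach ``grad.shape``."""
    grad = _asarray(grad)
    if grad.shape == shape:
        return grad
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A node in the computation graph: a value plus backward bookkeeping."""

    __slots__ = ("value", "grad", "_links", "requires_grad")

    def __init__(self, value, requires_grad: bool = False, _links=()):
        self.value = _asarray(value)
        self.grad = None
        if requires_grad:
            self.requires_grad = True
            self._links = ()
        else:
            # _links: (parent Tensor, fn(out_grad) -> grad wrt parent)
            links = [lk for lk in _links if lk[0].requires_grad]
            self.requires_grad = bool(links)
            self._links = tuple(links)

    # -- graph traversal ---------------------------------------------------
    def backward(self, grad=None) -> None:
        """Accumulate gradients of this (scalar) node into its ancestors."""
        if grad is None:
            if self.value.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.value)
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
            for parent, _ in node._links:
                if id(parent) not in seen:
                    stack.append((parent, False))
        self.grad = _asarray(grad)
        for node in reversed(order):
            if node.grad is None:
                continue
            for parent, fn in node._links:
                g = _unbroadcast(fn(node.grad), parent.value.shape)
                parent.grad = g if parent.grad is None else parent.grad + g

    def zero_grad(self) -> None:
        self.grad = None

    # -- conveniences ------------------------------------------------------
    @property
    def shape(self):
        return self.value.shape

    @property
    def ndim(self):
        return self.value.ndim

    def item(self) -> float:
        return float(self.value)

    def __repr__(self):
        return f"Tensor(shape={self.value.shape}, requires_grad={self.requires_grad})"

    # operators
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __sub__(self, other):
        return sub(self, other)

    def __rsub__(self, other):
        return sub(other, self)

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return div(self, other)

    def __rtruediv__(self, other):
        return div(other, self)

    def __neg__(self):
        return neg(self)

    def __pow__(self, exponent):
        return power(self, exponent)

    def __matmul__(self, other):
        return matmul(self, other)

    def __getitem__(self, key):
        return getitem(self, key)


def parameter(value, rng=None) -> Tensor:
    """A leaf tensor that accumulates gradients (a trainable weight)."""
    return Tensor(value, requires_grad=True)


def constant(value) -> Tensor:
    return Tensor(value, requires_grad=False)


def _binary(a, b, out, grad_a, grad_b):
    links = []
    if isinstance(a, Tensor):
        links.append((a, grad_a))
    if isinstance(b, Tensor):
        links.append((b, grad_b))
    if not links:
        return out
    return Tensor(out, _links=links)


def _unary(a, out, grad_a):
    if not isinstance(a, Tensor):
        return out
    return Tensor(out, _links=[(a, grad_a)])


# -- arithmetic -----------------------------------------------------------

def add(a, b):
    av, bv = value_of(a), value_of(b)
    return _binary(a, b, av + bv, lambda g: g, lambda g: g)


def sub(a, b):
    av, bv = value_of(a), value_of(b)
    return _binary(a, b, av - bv, lambda g: g, lambda g: -g)


def mul(a, b):
    av, bv = value_of(a), value_of(b)
    return _binary(a, b, av * bv, lambda g: g * bv, lambda g: g * av)


def div(a, b):
    av, bv = value_of(a), value_of(b)
    return _binary(a, b, av / bv,
                   lambda g: g / bv,
                   lambda g: -g * av / (bv * bv))


def neg(a):
    return _unary(a, -value_of(a), lambda g: -g)


def power(a, exponent: float):
    av = value_of(a)
    e = float(exponent)
    out = av ** e
    return _unary(a, out, lambda g: g * e * av ** (e - 1.0))


def matmul(a, b):
    av, bv = value_of(a), value_of(b)
    out = av @ bv
    return _binary(
        a, b, out,
        lambda g: g @ bv.swapaxes(-1, -2),
        lambda g: av.swapaxes(-1, -2) @ g,
    )


# -- elementwise nonlinearities -------------------------------------------

def exp(a):
    out = np.exp(value_of(a))
    return _unary(a, out, lambda g: g * out)


def log(a):
    av = value_of(a)
    return _unary(a, np.log(av), lambda g: g / av)


def sqrt(a):
    out = np.sqrt(value_of(a))
    return _unary(a, out, lambda g: g * 0.5 / out)


def square(a):
    av = value_of(a)
    return _unary(a, av * av, lambda g: g * 2.0 * av)


def tanh(a):
    out = np.tanh(value_of(a))
    return _unary(a, out, lambda g: g * (1.0 - out * out))


def sigmoid(a):
    av = value_of(a)
    out = np.where(av >= 0, 1.0 / (1.0 + np.exp(-av)),
                   np.exp(av) / (1.0 + np.exp(av)))
    return _unary(a, out, lambda g: g * out * (1.0 - out))


def relu(a):
    av = value_of(a)
    mask = av > 0
    return _unary(a, av * mask, lambda g: g * mask)


def clip(a, lo: float, hi: float):
    """Clamp values; the gradient passes through only inside [lo, hi]."""
    av = value_of(a)
    inside = (av >= lo) & (av <= hi)
    return _unary(a, np.clip(av, lo, hi), lambda g: g * inside)


# -- reductions / shape ----------------------------------------------------

def sum_(a, axis=None, keepdims: bool = False):
    av = value_of(a)
    out = av.sum(axis=axis, keepdims=keepdims)

    def grad_fn(g):
        if axis is None:
            return np.broadcast_to(g, av.shape)
        g_exp = g if keepdims else np.expand_dims(g, axis)
        return np.broadcast_to(g_exp, av.shape)

    return _unary(a, out, grad_fn)


def mean_(a, axis=None, keepdims: bool = False):
    av = value_of(a)
    n = av.size if axis is None else av.shape[axis]
    return div(sum_(a, axis=axis, keepdims=keepdims), float(n))


def reshape(a, shape):
    av = value_of(a)
    return _unary(a, av.reshape(shape), lambda g: g.reshape(av.shape))


def getitem(a, key):
    av = value_of(a)
    out = av[key]

    def grad_fn(g):
        full = np.zeros_like(av)
        np.add.at(full, key, g)
        return full

    return _unary(a, out, grad_fn)


def concat(parts, axis: int = -1):
    values = [value_of(p) for p in parts]
    out = np.concatenate(values, axis=axis)
    links = []
    offset = 0
    ax = axis if axis >= 0 else out.ndim + axis
    for part, val in zip(parts, values):
        size = val.shape[ax]
        if isinstance(part, Tensor):
            sl = [slice(None)] * out.ndim
            sl[ax] = slice(offset, offset + size)
            sl = tuple(sl)
            links.append((part, lambda g, sl=sl: g[sl]))
        offset += size
    if not links:
        return out
    return Tensor(out, _links=links)


# -- softmax family --------------------------------------------------------

def logsumexp(a, axis: int = -1, keepdims: bool = False):
    av = value_of(a)
    shift = np.max(av, axis=axis, keepdims=True)  # constant wrt gradient
    shifted = sub(a, shift)
    out = add(log(sum_(exp(shifted), axis=axis, keepdims=True)), shift)
    if not keepdims:
        out = reshape(out, np.squeeze(value_of(out), axis=axis).shape)
    return out


def log_softmax(a, axis: int = -1):
    return sub(a, logsumexp(a, axis=axis, keepdims=True))


def softmax(a, axis: int = -1):
    return exp(log_softmax(a, axis=axis))
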