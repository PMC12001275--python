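"""Minimal vectorized reverse-mode automatic differentiation on numpy arrays.

Supports exactly the operations the encoder networks and the variational
loss need: broadcasting arithmetic, matmul, exp/log/tanh/sigmoid/softplus,
reductions, slicing, concatenation and custom ops with user-supplied
vector-Jacobian products (used to backpropagate through ODE solutions).
Gradients are checked against central finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad, shape):
    """Sum a broadcast gradient back down to ``shape``."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for i, (g, s) in enumerate(zip(grad.shape, shape)):
        if s == 1 and g != 1:
            grad = grad.sum(axis=i, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad=False, _prev=(), _backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in _prev)
        self._prev = tuple(_prev)
        self._backward = _backward

    @property
    def shape(self):
        return self.data.shape

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- graph mechanics ----------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._prev:
                visit(p)
            topo.append(t)

        visit(self)
        for t in topo:
            t.grad = np.zeros_like(t.data)
        self.grad = np.asarray(grad, dtype=np.float64)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)

    def zero_grad(self):
        self.grad = None

    # -- arithmetic ---------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data + other.data, _prev=(self, other))

        def back(g):
            if self.requires_grad:
                self.grad += _unbroadcast(g, self.data.shape)
            if other.requires_grad:
                other.grad += _unbroadcast(g, other.data.shape)
        out._backward = back
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, _prev=(self,))

        def back(g):
            if self.requires_grad:
                self.grad += _unbroadcast(-g, self.data.shape)
        out._backward = back
        return out

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data * other.data, _prev=(self, other))

        def back(g):
            if self.requires_grad:
                self.grad += _unbroadcast(g * other.data, self.data.shape)
            if other.requires_grad:
                other.grad += _unbroadcast(g * self.data, other.data.shape)
        out._backward = back
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data / other.data, _prev=(self, other))

        def back(g):
            if self.requires_grad:
                self.grad += _unbroadcast(g / other.data, self.data.shape)
            if other.requires_grad:
                other.grad += _unbroadcast(
                    -g * self.data / other.data ** 2, other.data.shape)
        out._backward = back
        return out

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, exponent):
        assert np.isscalar(exponent)
        out = Tensor(self.data ** exponent, _prev=(self,))

        def back(g):
            if self.requires_grad:
                self.grad += _unbroadcast(
                    g * exponent * self.data ** (exponent - 1), self.data.shape)
        out._backward = back
        return out

    def __matmul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data @ other.data, _prev=(self, other))

        def back(g):
            a, b = self.data, other.data
            if self.requires_grad:
                if a.ndim == 1 and b.ndim == 1:
                    self.grad += g * b
                elif a.ndim == 1:                 # (n,) @ (n,m) -> (m,)
                    self.grad += b @ g
                elif b.ndim == 1:                 # (B,n) @ (n,) -> (B,)
                    self.grad += np.outer(g, b)
                else:                             # (B,n) @ (n,m) -> (B,m)
                    self.grad += g @ b.T
            if other.requires_grad:
                if a.ndim == 1 and b.ndim == 1:
                    other.grad += g * a
                elif a.ndim == 1:
                    other.grad += np.outer(a, g)
                else:
                    other.grad += a.T @ g
        out._backward = back
        return out

    # -- elementwise nonlinearities ----------------------------------------
    def exp(self):
        out = Tensor(np.exp(self.data), _prev=(self,))

        def back(g):
            if self.requires_grad:
                self.grad += g * out.data
        out._backward = back
        return out

    def log(self):
        out = Tensor(np.log(self.data), _prev=(self,))

        def back(g):
            if self.requires_grad:
                self.grad += g / self.data
        out._backward = back
        return out

    def tanh(self):
        out = Tensor(np.tanh(self.data), _prev=(self,))

        def back(g):
            if self.requires_grad:
                self.grad += g * (1.0 - out.data ** 2)
        out._backward = back
        return out

    def sigmoid(self):
        out = Tensor(1.0 / (1.0 + np.exp(-self.data)), _prev=(self,))

        def back(g):
            if self.requires_grad:
                self.grad += g * out.data * (1.0 - out.data)
        out._backward = back
        return out

    def softplus(self):
        # numerically stable log(1 + exp(x))
        out = Tensor(np.logaddexp(0.0, self.data), _prev=(self,))

        def back(g):
            if self.requires_grad:
                self.grad += g / (1.0 + np.exp(-self.data))
        out._backward = back
        return out

    def silu(self):
        """x * sigmoid(x): the smooth nonsaturating activation of the encoders."""
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(self.data * s, _prev=(self,))

        def back(g):
            if self.requires_grad:
                self.grad += g * (s + self.data * s * (1.0 - s))
        out._backward = back
        return out

    # -- reductions / shaping ----------------------------------------------
    def sum(self, axis=None):
        out = Tensor(self.data.sum(axis=axis), _prev=(self,))

        def back(g):
            if self.requires_grad:
                if axis is None:
                    self.grad += np.broadcast_to(g, self.data.shape)
                else:
                    self.grad += np.broadcast_to(
                        np.expand_dims(g, axis), self.data.shape)
        out._backward = back
        return out

    def mean(self, axis=None):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis) * (1.0 / n)

    def __getitem__(self, key):
        out = Tensor(self.data[key], _prev=(self,))

        def back(g):
            if self.requires_grad:
                np.add.at(self.grad, key, g)
        out._backward = back
        return out

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), _prev=(self,))

        def back(g):
            if self.requires_grad:
                self.grad += g.reshape(self.data.shape)
        out._backward = back
        return out


def as_tensor(x):
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors, axis=0):
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 _prev=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def back(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t.grad += g[tuple(sl)]
    out._backward = back
    return out


def stack(tensors, axis=0):
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(np.stack([t.data for t in tensors], axis=axis),
                 _prev=tuple(tensors))

    def back(g):
        for i, t in enumerate(tensors):
            if t.requires_grad:
                t.grad += np.take(g, i, axis=axis)
    out._backward = back
    return out


def custom_op(inputs, value, vjp):
    """Insert a node with externally computed forward value and VJP.

    ``vjp(grad_out)`` must return one gradient array per input, aligned with
    ``inputs``; used for ODE-solution nodes whose Jacobian is obtained by
    finite differences.
    """
    inputs = [as_tensor(t) for t in inputs]
    out = Tensor(value, _prev=tuple(inputs))

    def back(g):
        grads = vjp(g)
        for t, gi in zip(inputs, grads):
            if t.requires_grad and gi is not None:
                t.grad += _unbroadcast(np.asarray(gi, dtype=np.float64),
                                       t.data.shape)
    out._backward = back
    return out


class Parameter(Tensor):
    """A trainable leaf tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Adam:
    """Adam with optional global gradient-norm clipping."""

    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8,
                 clip_norm=1.0):
        self.params = list(params)
        self.lr, self.betas, self.eps, self.clip_norm = lr, betas, eps, clip_norm
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        grads = [p.grad if p.grad is not None else np.zeros_like(p.data)
                 for p in self.params]
        if self.clip_norm is not None:
            total = np.sqrt(sum(float((g ** 2).sum()) for g in grads))
            if total > self.clip_norm:
                grads = [g * (self.clip_norm / (total + 1e-12)) for g in grads]
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g ** 2
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
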