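"""Compact reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations the recurrent feature extractor and the
spectral graph network need: broadcasting arithmetic, (batched) matrix
products, the sigmoid/tanh/softplus/exp/log nonlinearities, reductions,
concatenation/stacking, basic indexing, block max-pooling and the
permute-with-fake-padding gather used by graph pooling.  Everything is
float64; gradients are accumulated by topological traversal of the tape.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "tensor",
    "sigmoid",
    "tanh",
    "softplus",
    "exp",
    "log",
    "concat",
    "stack",
    "maxpool_blocks",
    "pad_permute",
    "softmax",
    "Adam",
]


def _sum_to_shape(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce a broadcast gradient back to the operand's shape."""
    if grad.shape == shape:
        return grad
    # sum over leading broadcast axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """An array node on the autodiff tape."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = requires_grad
        self.grad = None
        self._backward = None
        self._parents: tuple = ()

    # -- construction helpers -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- graph machinery ------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        for t in topo:
            t.grad = None
        self.grad = np.asarray(grad, dtype=np.float64)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def _accum(self, grad):
        grad = _sum_to_shape(np.asarray(grad, float), self.data.shape)
        self.grad = grad if self.grad is None else self.grad + grad

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = tensor(other)
        out = Tensor(self.data + other.data)
        out._parents = (self, other)

        def back(g):
            self._accum(g)
            other._accum(g)

        out._backward = back
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data)
        out._parents = (self,)
        out._backward = lambda g: self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-tensor(other))

    def __rsub__(self, other):
        return tensor(other) + (-self)

    def __mul__(self, other):
        other = tensor(other)
        out = Tensor(self.data * other.data)
        out._parents = (self, other)

        def back(g):
            self._accum(g * other.data)
            other._accum(g * self.data)

        out._backward = back
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = tensor(other)
        out = Tensor(self.data / other.data)
        out._parents = (self, other)

        def back(g):
            self._accum(g / other.data)
            other._accum(-g * self.data / other.data**2)

        out._backward = back
        return out

    def __pow__(self, p: float):
        out = Tensor(self.data**p)
        out._parents = (self,)
        out._backward = lambda g: self._accum(g * p * self.data ** (p - 1))
        return out

    def __matmul__(self, other):
        other = tensor(other)
        out = Tensor(np.matmul(self.data, other.data))
        out._parents = (self, other)
        a, b = self.data, other.data

        def back(g):
            self._accum(np.matmul(g, np.swapaxes(b, -1, -2)))
            other._accum(np.matmul(np.swapaxes(a, -1, -2), g))

        out._backward = back
        return out

    # -- reductions / shaping -------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims))
        out._parents = (self,)

        def back(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape))
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accum(np.broadcast_to(gg, self.data.shape))

        out._backward = back
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape))
        out._parents = (self,)
        out._backward = lambda g: self._accum(g.reshape(self.data.shape))
        return out

    def __getitem__(self, key):
        out = Tensor(self.data[key])
        out._parents = (self,)

        def back(g):
            gx = np.zeros_like(self.data)
            np.add.at(gx, key, g)
            self.grad = gx if self.grad is None else self.grad + gx

        out._backward = back
        return out


def tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unary(x: Tensor, value: np.ndarray, dfn) -> Tensor:
    out = Tensor(value)
    out._parents = (x,)
    out._backward = lambda g: x._accum(g * dfn(value))
    return out


def sigmoid(x: Tensor) -> Tensor:
    x = tensor(x)
    v = 0.5 * (1.0 + np.tanh(0.5 * x.data))  # stable logistic
    return _unary(x, v, lambda v: v * (1.0 - v))


def tanh(x: Tensor) -> Tensor:
    x = tensor(x)
    return _unary(x, np.tanh(x.data), lambda v: 1.0 - v**2)


def softplus(x: Tensor) -> Tensor:
    x = tensor(x)
    v = np.logaddexp(0.0, x.data)
    sig = 0.5 * (1.0 + np.tanh(0.5 * x.data))
    out = Tensor(v)
    out._parents = (x,)
    out._backward = lambda g: x._accum(g * sig)
    return out


def exp(x: Tensor) -> Tensor:
    x = tensor(x)
    return _unary(x, np.exp(x.data), lambda v: v)


def log(x: Tensor) -> Tensor:
    x = tensor(x)
    out = Tensor(np.log(x.data))
    out._parents = (x,)
    out._backward = lambda g: x._accum(g / x.data)
    return out


def concat(xs, axis: int = -1) -> Tensor:
    xs = [tensor(x) for x in xs]
    out = Tensor(np.concatenate([x.data for x in xs], axis=axis))
    out._parents = tuple(xs)
    sizes = [x.data.shape[axis] for x in xs]
    offsets = np.cumsum([0] + sizes)

    def back(g):
        for x, a, b in zip(xs, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis if axis >= 0 else g.ndim + axis] = slice(a, b)
            x._accum(g[tuple(sl)])

    out._backward = back
    return out


def stack(xs, axis: int = 0) -> Tensor:
    xs = [tensor(x) for x in xs]
    out = Tensor(np.stack([x.data for x in xs], axis=axis))
    out._parents = tuple(xs)

    def back(g):
        for i, x in enumerate(xs):
            x._accum(np.take(g, i, axis=axis))

    out._backward = back
    return out


def maxpool_blocks(x: Tensor, pool: int) -> Tensor:
    """Non-overlapping max over consecutive blocks along axis 1.

    `x` has shape (batch, nodes, channels) with nodes divisible by `pool`.
    """
    x = tensor(x)
    B, n, f = x.data.shape
    if n % pool:
        raise ValueError(f"signal length {n} not divisible by pool size {pool}")
    blocks = x.data.reshape(B, n // pool, pool, f)
    arg = blocks.argmax(axis=2)
    out = Tensor(blocks.max(axis=2))
    out._parents = (x,)

    def back(g):
        gb = np.zeros_like(blocks)
        np.put_along_axis(gb, arg[:, :, None, :], g[:, :, None, :], axis=2)
        x._accum(gb.reshape(B, n, f))

    out._backward = back
    return out


def pad_permute(x: Tensor, perm: np.ndarray) -> Tensor:
    """Reorder node axis 1 by `perm`; positions with perm < 0 are fake, set 0.

    Real indices in `perm` must form a bijection onto range(n_real).
    """
    x = tensor(x)
    B, n, f = x.data.shape
    perm = np.asarray(perm)
    real = perm >= 0
    out_data = np.zeros((B, len(perm), f))
    out_data[:, real, :] = x.data[:, perm[real], :]
    out = Tensor(out_data)
    out._parents = (x,)

    def back(g):
        gx = np.zeros_like(x.data)
        gx[:, perm[real], :] = g[:, real, :]
        x._accum(gx)

    out._backward = back
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable softmax (shift by a detached max)."""
    x = tensor(x)
    shift = x.data.max(axis=axis, keepdims=True)
    e = exp(x - Tensor(shift))
    return e / e.sum(axis=axis, keepdims=True)


class Adam:
    """Adaptive-moment estimation optimizer."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = [p for p in params if p.requires_grad]
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            g = p.grad
            if g is None:
                continue
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
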