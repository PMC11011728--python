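"""Minimal reverse-mode automatic differentiation on numpy arrays.

The package trains small transformer towers on the CPU; this module provides
the tensor graph, the handful of primitive operations those models need, a
`Module`/`Parameter` container system and a plain stochastic-gradient-descent
optimizer with L2 weight decay and optional momentum.  All arithmetic is
float64 so that finite-difference gradient checks are meaningful at tight
tolerances.  Gradients are only propagated into tensors that require them
(Parameters and their descendants); graph constants cost nothing on the
backward pass.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for i, s in enumerate(shape):
        if s == 1 and grad.shape[i] != 1:
            grad = grad.sum(axis=i, keepdims=True)
    return grad


class Tensor:
    """A numpy array plus the closure needed to backpropagate through it."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_bwd")

    def __init__(self, data, _parents=(), _bwd=None, requires_grad=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self._parents = _parents
        self._bwd = _bwd
        if requires_grad is None:
            requires_grad = any(p.requires_grad for p in _parents)
        self.requires_grad = requires_grad

    # ------------------------------------------------------------------ info
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape})"

    # ------------------------------------------------------------ arithmetic
    def __add__(self, other):
        if isinstance(other, (int, float)):
            return Tensor(self.data + other, (self,), lambda g: (g,))
        other = _as_tensor(other)
        a, b = self, other

        def bwd(g):
            return (
                _unbroadcast(g, a.data.shape) if a.requires_grad else None,
                _unbroadcast(g, b.data.shape) if b.requires_grad else None,
            )

        return Tensor(a.data + b.data, (a, b), bwd)

    __radd__ = __add__

    def __neg__(self):
        return Tensor(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        if isinstance(other, (int, float)):
            return Tensor(self.data - other, (self,), lambda g: (g,))
        other = _as_tensor(other)
        a, b = self, other

        def bwd(g):
            return (
                _unbroadcast(g, a.data.shape) if a.requires_grad else None,
                _unbroadcast(-g, b.data.shape) if b.requires_grad else None,
            )

        return Tensor(a.data - b.data, (a, b), bwd)

    def __rsub__(self, other):
        return (-self) + other

    def __mul__(self, other):
        if isinstance(other, (int, float)):
            return Tensor(self.data * other, (self,), lambda g: (g * other,))
        other = _as_tensor(other)
        a, b = self, other

        def bwd(g):
            return (
                _unbroadcast(g * b.data, a.data.shape)
                if a.requires_grad else None,
                _unbroadcast(g * a.data, b.data.shape)
                if b.requires_grad else None,
            )

        return Tensor(a.data * b.data, (a, b), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, (int, float)):
            return self * (1.0 / other)
        other = _as_tensor(other)
        a, b = self, other

        def bwd(g):
            return (
                _unbroadcast(g / b.data, a.data.shape)
                if a.requires_grad else None,
                _unbroadcast(-g * a.data / (b.data * b.data), b.data.shape)
                if b.requires_grad else None,
            )

        return Tensor(a.data / b.data, (a, b), bwd)

    def __pow__(self, p):
        a = self.data
        return Tensor(a**p, (self,), lambda g: (g * p * a ** (p - 1),))

    def __matmul__(self, other):
        other = _as_tensor(other)
        a, b = self, other

        def bwd(g):
            ga = gb = None
            if a.requires_grad:
                ga = _unbroadcast(g @ np.swapaxes(b.data, -1, -2), a.data.shape)
            if b.requires_grad:
                gb = _unbroadcast(np.swapaxes(a.data, -1, -2) @ g, b.data.shape)
            return ga, gb

        return Tensor(a.data @ b.data, (a, b), bwd)

    # ------------------------------------------------------------ unary ops
    def exp(self):
        val = np.exp(self.data)
        return Tensor(val, (self,), lambda g: (g * val,))

    def log(self):
        a = self.data
        return Tensor(np.log(a), (self,), lambda g: (g / a,))

    def sqrt(self):
        val = np.sqrt(self.data)
        return Tensor(val, (self,), lambda g: (g * 0.5 / val,))

    def relu(self):
        mask = self.data > 0
        return Tensor(self.data * mask, (self,), lambda g: (g * mask,))

    # -------------------------------------------------------------- reduces
    def sum(self, axis=None, keepdims=False):
        val = self.data.sum(axis=axis, keepdims=keepdims)
        shape = self.data.shape

        def bwd(g):
            g = np.asarray(g, dtype=np.float64)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, shape),)

        return Tensor(val, (self,), bwd)

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # --------------------------------------------------------------- shapes
    def reshape(self, shape):
        orig = self.data.shape
        return Tensor(
            self.data.reshape(shape), (self,), lambda g: (g.reshape(orig),)
        )

    def transpose(self, axes):
        inv = np.argsort(axes)
        return Tensor(
            self.data.transpose(axes), (self,), lambda g: (g.transpose(inv),)
        )

    def __getitem__(self, idx):
        shape = self.data.shape

        def bwd(g):
            out = np.zeros(shape, dtype=np.float64)
            np.add.at(out, idx, g)
            return (out,)

        return Tensor(self.data[idx], (self,), bwd)

    # ------------------------------------------------------------- backward
    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        # iterative topological sort over the grad-requiring subgraph
        topo, visited, stack = [], set(), [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in visited:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._bwd is None or node.grad is None:
                continue
            for parent, g in zip(node._parents, node._bwd(node.grad)):
                if g is None or not parent.requires_grad:
                    continue
                if parent.grad is None:
                    parent.grad = np.zeros_like(parent.data)
                parent.grad += g


class Parameter(Tensor):
    """A Tensor that an optimizer updates."""

    __slots__ = ()

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def constant(x) -> Tensor:
    """Wrap an array as a graph constant (no gradient tracked past it)."""
    return Tensor(x)


def concat(tensors, axis=0) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor(
        np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), bwd
    )


def softmax(x: Tensor, axis=-1) -> Tensor:
    m = x.data.max(axis=axis, keepdims=True)
    e = np.exp(x.data - m)
    p = e / e.sum(axis=axis, keepdims=True)

    def bwd(g):
        return (p * (g - (g * p).sum(axis=axis, keepdims=True)),)

    return Tensor(p, (x,), bwd)


def log_softmax(x: Tensor, axis=-1) -> Tensor:
    m = x.data.max(axis=axis, keepdims=True)
    s = x.data - m
    lse = np.log(np.exp(s).sum(axis=axis, keepdims=True))
    out = s - lse
    p = np.exp(out)

    def bwd(g):
        return (g - p * g.sum(axis=axis, keepdims=True),)

    return Tensor(out, (x,), bwd)


def embedding_lookup(table: Tensor, ids: np.ndarray) -> Tensor:
    ids = np.asarray(ids)
    shape = table.data.shape

    def bwd(g):
        out = np.zeros(shape, dtype=np.float64)
        np.add.at(out, ids, g)
        return (out,)

    return Tensor(table.data[ids], (table,), bwd)


# --------------------------------------------------------------------- layers
class Module:
    """Container of Parameters and sub-Modules; mirrors the usual NN idiom."""

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def named_parameters(self, prefix=""):
        out = []
        for name, v in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(v, Parameter):
                out.append((key, v))
            elif isinstance(v, Module):
                out.extend(v.named_parameters(prefix=key + "."))
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        out.extend(item.named_parameters(prefix=f"{key}.{i}."))
                    elif isinstance(item, Parameter):
                        out.append((f"{key}.{i}", item))
        return out

    def set_training(self, flag: bool):
        for v in vars(self).values():
            if isinstance(v, Module):
                v.set_training(flag)
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        item.set_training(flag)
        self.training = flag
        return self

    def state_dict(self) -> dict:
        return {k: v.data.copy() for k, v in self.named_parameters()}

    def load_state_dict(self, state: dict):
        for k, v in self.named_parameters():
            v.data = np.array(state[k], dtype=np.float64)


def init_uniform(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    bound = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=shape)


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator, bias=True):
        self.w = Parameter(init_uniform(rng, (d_in, d_out), d_in))
        self.b = Parameter(np.zeros(d_out)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = _as_tensor(x) @ self.w
        if self.b is not None:
            out = out + self.b
        return out


class LayerNorm(Module):
    def __init__(self, d: int, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(d))
        self.beta = Parameter(np.zeros(d))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        xn = xc / (var + self.eps).sqrt()
        return xn * self.gamma + self.beta


class SGD:
    """Plain stochastic gradient descent with L2 weight decay and optional
    momentum.

    `lr` is mutable so a schedule can set it per step; with lr == 0 the
    parameters are provably left untouched regardless of weight decay.
    """

    def __init__(self, params, lr: float, weight_decay: float = 0.0,
                 momentum: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.weight_decay = weight_decay
        self.momentum = momentum
        self._velocity = [None] * len(self.params)

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        if self.lr == 0.0:
            return
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad + self.weight_decay * p.data
            if self.momentum > 0.0:
                v = self._velocity[i]
                v = g if v is None else self.momentum * v + g
                self._velocity[i] = v
                g = v
            p.data -= self.lr * g
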