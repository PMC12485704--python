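"""Minimal reverse-mode automatic differentiation on numpy arrays.

Supports exactly the operations the flexibility models need — dense and
batched matrix products, 1-D convolution, pointwise nonlinearities,
reductions, slicing — with gradients that flow to both parameters and
inputs (the latter is what Integrated Gradients differentiates).  Single
threaded numpy keeps runs bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading extra axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, (g, s) in enumerate(zip(grad.shape, shape)):
        if s == 1 and g != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """An array node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=float)
        self.grad = None
        self.requires_grad = requires_grad
        self._parents = ()
        self._backward = None

    @property
    def shape(self):
        return self.data.shape

    # -- graph construction helpers -------------------------------------

    @staticmethod
    def _node(data, parents, backward):
        out = Tensor(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = parents
            out._backward = backward
        return out

    @staticmethod
    def _lift(x):
        return x if isinstance(x, Tensor) else Tensor(x)

    # -- arithmetic ------------------------------------------------------

    def __add__(self, other):
        other = Tensor._lift(other)
        def backward(g):
            return (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape))
        return Tensor._node(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        return Tensor._node(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return Tensor._lift(other) + (-self)

    def __mul__(self, other):
        other = Tensor._lift(other)
        def backward(g):
            return (
                _unbroadcast(g * other.data, self.shape),
                _unbroadcast(g * self.data, other.shape),
            )
        return Tensor._node(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._lift(other)
        def backward(g):
            return (
                _unbroadcast(g / other.data, self.shape),
                _unbroadcast(-g * self.data / other.data**2, other.shape),
            )
        return Tensor._node(self.data / other.data, (self, other), backward)

    def matmul(self, other):
        other = Tensor._lift(other)
        def backward(g):
            a, b = self.data, other.data
            ga = np.matmul(g, np.swapaxes(b, -1, -2))
            gb = np.matmul(np.swapaxes(a, -1, -2), g)
            return (_unbroadcast(ga, a.shape), _unbroadcast(gb, b.shape))
        return Tensor._node(np.matmul(self.data, other.data), (self, other), backward)

    __matmul__ = matmul

    # -- pointwise nonlinearities -----------------------------------------

    def relu(self):
        mask = self.data > 0
        return Tensor._node(self.data * mask, (self,), lambda g: (g * mask,))

    def tanh(self):
        out = np.tanh(self.data)
        return Tensor._node(out, (self,), lambda g: (g * (1.0 - out**2),))

    def sigmoid(self):
        out = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))
        return Tensor._node(out, (self,), lambda g: (g * out * (1.0 - out),))

    def exp(self):
        out = np.exp(self.data)
        return Tensor._node(out, (self,), lambda g: (g * out,))

    def log(self):
        return Tensor._node(np.log(self.data), (self,), lambda g: (g / self.data,))

    # -- reductions & shaping ---------------------------------------------

    def sum(self, axis=None, keepdims=False):
        def backward(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, self.shape).copy(),)
        return Tensor._node(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims=False):
        count = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    def reshape(self, *shape):
        orig = self.shape
        return Tensor._node(
            self.data.reshape(*shape), (self,), lambda g: (g.reshape(orig),)
        )

    def swapaxes(self, a, b):
        return Tensor._node(
            np.swapaxes(self.data, a, b), (self,), lambda g: (np.swapaxes(g, a, b),)
        )

    def __getitem__(self, key):
        def backward(g):
            out = np.zeros_like(self.data)
            out[key] = g
            return (out,)
        return Tensor._node(self.data[key], (self,), backward)

    def softmax(self, axis=-1):
        """Numerically stable softmax along ``axis``."""
        shifted = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(shifted)
        out = e / e.sum(axis=axis, keepdims=True)
        def backward(g):
            dot = (g * out).sum(axis=axis, keepdims=True)
            return (out * (g - dot),)
        return Tensor._node(out, (self,), backward)

    # -- backprop ---------------------------------------------------------

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient needs a scalar")
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(node):
            if id(node) in seen or not node.requires_grad:
                return
            seen.add(id(node))
            for p in node._parents:
                visit(p)
            topo.append(node)

        visit(self)
        grads = {id(self): np.asarray(grad, dtype=float)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.grad is None:
                node.grad = g.copy()
            else:
                node.grad = node.grad + g
            if node._backward is None:
                continue
            parent_grads = node._backward(g)
            for p, pg in zip(node._parents, parent_grads):
                if not p.requires_grad or pg is None:
                    continue
                if id(p) in grads:
                    grads[id(p)] = grads[id(p)] + pg
                else:
                    grads[id(p)] = pg


def conv1d(x: Tensor, w: Tensor, b: Tensor, padding: int = 1) -> Tensor:
    """1-D convolution, stride 1: x (B, Cin, L), w (Cout, Cin, K), b (Cout,)."""
    B, Cin, L = x.shape
    Cout, Cin_w, K = w.shape
    assert Cin == Cin_w
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding)))
    Lout = L + 2 * padding - K + 1
    patches = np.stack([xp[:, :, k:k + Lout] for k in range(K)], axis=2)  # (B,Cin,K,Lout)
    out = np.einsum("bckl,ock->bol", patches, w.data, optimize=True) + b.data[:, None]

    def backward(g):
        gw = np.einsum("bol,bckl->ock", g, patches, optimize=True)
        gb = g.sum(axis=(0, 2))
        gxp = np.zeros_like(xp)
        for k in range(K):
            gxp[:, :, k:k + Lout] += np.einsum(
                "bol,oc->bcl", g, w.data[:, :, k], optimize=True
            )
        gx = gxp[:, :, padding:padding + L] if padding else gxp
        return (gx, gw, gb)

    return Tensor._node(out, (x, w, b), backward)


def bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean binary cross-entropy on logits (numerically stable)."""
    z = logits.data
    y = np.asarray(targets, dtype=float)
    loss = np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))
    n = z.size

    def backward(g):
        p = 1.0 / (1.0 + np.exp(-z))
        return (g * (p - y) / n,)

    return Tensor._node(loss.mean(), (logits,), backward)


def mse_loss(pred: Tensor, targets: np.ndarray) -> Tensor:
    diff = pred - Tensor(np.asarray(targets, dtype=float))
    return (diff * diff).mean()


class Adam:
    """Adam with L2 weight decay added to the gradient (torch-style)."""

    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8, weight_decay=0.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad + self.weight_decay * p.data
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g**2
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
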