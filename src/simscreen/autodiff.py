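"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Supports exactly the operations the transformer autoencoder and its losses
need: broadcasting arithmetic, matmul (batched), reductions, elementwise
transcendentals, embedding lookup, reshaping/transposition and slicing.
Gradients are accumulated in float64.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "astensor", "embedding", "concat"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of NumPy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, (g, s) in enumerate(zip(grad.shape, shape)):
        if s == 1 and g != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """Node in the computation graph wrapping an ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        data = np.asarray(data)
        if not np.issubdtype(data.dtype, np.floating):
            data = data.astype(np.float64)
        self.data = data  # float dtype preserved (model runs float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents = parents
        self._backward = backward

    # ---- introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # ---- graph construction helpers ------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        req = any(p.requires_grad for p in parents)
        return Tensor(data, requires_grad=req,
                      parents=parents if req else (),
                      backward=backward if req else None)

    # ---- arithmetic -----------------------------------------------------
    def __add__(self, other):
        other = astensor(other)
        out = Tensor._make(self.data + other.data, (self, other), None)

        def backward(g):
            return (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape))

        out._backward = backward
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor._make(-self.data, (self,), None)
        out._backward = lambda g: (-g,)
        return out

    def __sub__(self, other):
        return self + (-astensor(other))

    def __rsub__(self, other):
        return astensor(other) + (-self)

    def __mul__(self, other):
        other = astensor(other)
        out = Tensor._make(self.data * other.data, (self, other), None)

        def backward(g):
            return (_unbroadcast(g * other.data, self.shape),
                    _unbroadcast(g * self.data, other.shape))

        out._backward = backward
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = astensor(other)
        out = Tensor._make(self.data / other.data, (self, other), None)

        def backward(g):
            return (_unbroadcast(g / other.data, self.shape),
                    _unbroadcast(-g * self.data / other.data ** 2, other.shape))

        out._backward = backward
        return out

    def __rtruediv__(self, other):
        return astensor(other) / self

    def __pow__(self, exponent: float):
        out = Tensor._make(self.data ** exponent, (self,), None)
        out._backward = lambda g: (g * exponent * self.data ** (exponent - 1),)
        return out

    def __matmul__(self, other):
        other = astensor(other)
        out = Tensor._make(self.data @ other.data, (self, other), None)

        def backward(g):
            ga = _unbroadcast(g @ np.swapaxes(other.data, -1, -2), self.shape)
            if other.data.ndim == 2 and self.data.ndim > 2:
                # common case x @ W: fold batch dims instead of allocating
                # a stacked [B, k, n] gradient and summing it afterwards
                k = self.data.shape[-1]
                n = g.shape[-1]
                gb = self.data.reshape(-1, k).T @ g.reshape(-1, n)
            else:
                gb = _unbroadcast(np.swapaxes(self.data, -1, -2) @ g,
                                  other.shape)
            return (ga, gb)

        out._backward = backward
        return out

    # ---- elementwise ----------------------------------------------------
    def exp(self):
        e = np.exp(self.data)
        out = Tensor._make(e, (self,), None)
        out._backward = lambda g: (g * e,)
        return out

    def log(self):
        out = Tensor._make(np.log(self.data), (self,), None)
        out._backward = lambda g: (g / self.data,)
        return out

    def sqrt(self):
        r = np.sqrt(self.data)
        out = Tensor._make(r, (self,), None)
        out._backward = lambda g: (g / (2.0 * r),)
        return out

    def abs(self):
        out = Tensor._make(np.abs(self.data), (self,), None)
        out._backward = lambda g: (g * np.sign(self.data),)
        return out

    def relu(self):
        mask = self.data > 0
        out = Tensor._make(self.data * mask, (self,), None)
        out._backward = lambda g: (g * mask,)
        return out

    def maximum(self, other):
        """Elementwise max; at ties the gradient goes to self (subgradient)."""
        other = astensor(other)
        take_self = self.data >= other.data
        out = Tensor._make(np.where(take_self, self.data, other.data),
                           (self, other), None)

        def backward(g):
            return (_unbroadcast(g * take_self, self.shape),
                    _unbroadcast(g * ~take_self, other.shape))

        out._backward = backward
        return out

    # ---- reductions -----------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)
        out = Tensor._make(out_data, (self,), None)

        def backward(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, self.shape).copy(),)

        out._backward = backward
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # ---- shape ----------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor._make(self.data.reshape(shape), (self,), None)
        out._backward = lambda g: (g.reshape(self.shape),)
        return out

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out = Tensor._make(self.data.transpose(axes), (self,), None)
        out._backward = lambda g: (g.transpose(inv),)
        return out

    def __getitem__(self, idx):
        out = Tensor._make(self.data[idx], (self,), None)

        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            return (full,)

        out._backward = backward
        return out

    # ---- composites ------------------------------------------------------
    def softmax(self, axis: int = -1):
        """Fused softmax with analytic backward (hot path in attention)."""
        shift = self.data.max(axis=axis, keepdims=True)
        e = np.exp(self.data - shift)
        out_data = e / e.sum(axis=axis, keepdims=True)
        out = Tensor._make(out_data, (self,), None)

        def backward(g):
            dot = (g * out_data).sum(axis=axis, keepdims=True)
            return (out_data * (g - dot),)

        out._backward = backward
        return out

    def log_softmax(self, axis: int = -1):
        shift = self.data.max(axis=axis, keepdims=True)
        z = self - shift
        return z - z.exp().sum(axis=axis, keepdims=True).log()

    # ---- backward pass ----------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)

        order: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative topo sort; graphs are deep during training
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))

        grads: dict[int, np.ndarray] = {
            id(self): np.asarray(grad, dtype=self.data.dtype)}
        for node in reversed(order):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            # non-inplace accumulation: g may be shared with another node
            node.grad = g if node.grad is None else node.grad + g
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


def astensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def embedding(weight: Tensor, ids: np.ndarray) -> Tensor:
    """Row gather `weight[ids]` with scatter-add backward.

    Backward sorts the flat ids and uses add.reduceat, which is much faster
    than np.add.at for the repeated-row access pattern of token batches.
    """
    ids = np.asarray(ids)
    out = Tensor._make(weight.data[ids], (weight,), None)

    def backward(g):
        d = weight.data.shape[-1]
        flat_ids = ids.reshape(-1)
        flat_g = g.reshape(-1, d)
        order = np.argsort(flat_ids, kind="stable")
        sorted_ids = flat_ids[order]
        starts = np.flatnonzero(np.r_[True, np.diff(sorted_ids) != 0])
        sums = np.add.reduceat(flat_g[order], starts, axis=0)
        full = np.zeros_like(weight.data)
        full[sorted_ids[starts]] = sums
        return (full,)

    out._backward = backward
    return out


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor,
               eps: float = 1e-6) -> Tensor:
    """Fused last-axis layer normalization with analytic backward."""
    x, gamma, beta = astensor(x), astensor(gamma), astensor(beta)
    mu = x.data.mean(axis=-1, keepdims=True)
    xc = x.data - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    out = Tensor._make(xhat * gamma.data + beta.data, (x, gamma, beta), None)
    d = x.data.shape[-1]

    def backward(g):
        g_gamma = _unbroadcast(g * xhat, gamma.shape)
        g_beta = _unbroadcast(g, beta.shape)
        gx_hat = g * gamma.data
        gx = inv * (gx_hat
                    - gx_hat.mean(axis=-1, keepdims=True)
                    - xhat * (gx_hat * xhat).mean(axis=-1, keepdims=True))
        return (gx, g_gamma, g_beta)

    out._backward = backward
    return out


def concat(tensors: list, axis: int = 0) -> Tensor:
    tensors = [astensor(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    out = Tensor._make(data, tuple(tensors), None)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    out._backward = backward
    return out
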