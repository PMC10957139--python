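"""Minimal reverse-mode automatic differentiation on numpy arrays.

Supports exactly the operations the lightweight classifiers need: broadcasted
arithmetic, matmul, tanh/sigmoid/relu/exp/log, reductions, slicing, stacked
causal dilated 1-D convolution, and fused stable softmax cross-entropy.
Gradients accumulate into ``Tensor.grad`` after ``backward()`` on a scalar.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "causal_conv1d", "softmax_cross_entropy", "stack_last"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
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
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=float)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents = parents
        self._backward = backward

    # -- construction helpers -------------------------------------------
    @staticmethod
    def param(data) -> "Tensor":
        return Tensor(data, requires_grad=True)

    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    @property
    def shape(self):
        return self.data.shape

    # -- autodiff plumbing ----------------------------------------------
    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        order: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS: graphs from long BPTT exceed recursion depth
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic ------------------------------------------------------
    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(
            self.data + other.data,
            requires_grad=self.requires_grad or other.requires_grad,
            parents=(self, other),
        )

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))

        out._backward = bw
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(
            self.data * other.data,
            requires_grad=self.requires_grad or other.requires_grad,
            parents=(self, other),
        )

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __matmul__(self, other):
        other = self._lift(other)
        out = Tensor(
            self.data @ other.data,
            requires_grad=self.requires_grad or other.requires_grad,
            parents=(self, other),
        )

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g @ np.swapaxes(other.data, -1, -2), self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(np.swapaxes(self.data, -1, -2) @ g, other.data.shape))

        out._backward = bw
        return out

    # -- elementwise nonlinearity ---------------------------------------
    def tanh(self):
        y = np.tanh(self.data)
        out = Tensor(y, self.requires_grad, (self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * (1 - y * y))

        out._backward = bw
        return out

    def sigmoid(self):
        y = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))
        out = Tensor(y, self.requires_grad, (self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * y * (1 - y))

        out._backward = bw
        return out

    def relu(self):
        mask = self.data > 0
        out = Tensor(self.data * mask, self.requires_grad, (self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * mask)

        out._backward = bw
        return out

    def exp(self):
        y = np.exp(np.clip(self.data, -700, 700))
        out = Tensor(y, self.requires_grad, (self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * y)

        out._backward = bw
        return out

    def log(self):
        out = Tensor(np.log(self.data), self.requires_grad, (self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g / self.data)

        out._backward = bw
        return out

    # -- reductions and shaping -----------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), self.requires_grad, (self,))

        def bw(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.data.shape).copy())
            else:
                if not keepdims:
                    g = np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(g, self.data.shape).copy())

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), self.requires_grad, (self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g.reshape(self.data.shape))

        out._backward = bw
        return out

    def transpose(self, *axes):
        axes = axes or None
        out = Tensor(self.data.transpose(axes), self.requires_grad, (self,))

        def bw(g):
            if self.requires_grad:
                inv = np.argsort(axes) if axes else None
                self._accumulate(g.transpose(inv))

        out._backward = bw
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], self.requires_grad, (self,))

        def bw(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accumulate(full)

        out._backward = bw
        return out


def stack_last(tensors: list[Tensor]) -> Tensor:
    """Stack same-shaped tensors along a new trailing axis."""
    data = np.stack([t.data for t in tensors], axis=-1)
    out = Tensor(data, any(t.requires_grad for t in tensors), tuple(tensors))

    def bw(g):
        for i, t in enumerate(tensors):
            if t.requires_grad:
                t._accumulate(g[..., i])

    out._backward = bw
    return out


def causal_conv1d(x: Tensor, weight: Tensor, bias: Tensor | None, dilation: int) -> Tensor:
    """Causal dilated 1-D convolution.

    x: (B, C_in, T); weight: (C_out, C_in, k); output: (B, C_out, T).
    The input is left-padded with (k-1)*dilation zeros, so output t depends
    only on inputs at times <= t.
    """
    B, Cin, T = x.data.shape
    Cout, Cin2, k = weight.data.shape
    if Cin != Cin2:
        raise ValueError("channel mismatch in causal_conv1d")
    pad = (k - 1) * dilation
    xpad = np.pad(x.data, ((0, 0), (0, 0), (pad, 0)))
    # gathered[b, c, j, t] = xpad[b, c, t + j*dilation]
    gathered = np.stack([xpad[:, :, j * dilation : j * dilation + T] for j in range(k)], axis=2)
    y = np.einsum("bcjt,fcj->bft", gathered, weight.data, optimize=True)
    if bias is not None:
        y = y + bias.data[None, :, None]
    parents = (x, weight) if bias is None else (x, weight, bias)
    out = Tensor(y, any(p.requires_grad for p in parents), parents)

    def bw(g):
        if weight.requires_grad:
            weight._accumulate(np.einsum("bcjt,bft->fcj", gathered, g, optimize=True))
        if bias is not None and bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 2)))
        if x.requires_grad:
            dxpad = np.zeros_like(xpad)
            for j in range(k):
                dxpad[:, :, j * dilation : j * dilation + T] += np.einsum(
                    "bft,fcj->bct", g, weight.data[:, :, j : j + 1], optimize=True
                )[:, :, :]
            x._accumulate(dxpad[:, :, pad:])

    out._backward = bw
    return out


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy of integer ``labels`` under softmax(logits)."""
    z = logits.data
    zmax = z.max(axis=1, keepdims=True)
    ez = np.exp(z - zmax)
    p = ez / ez.sum(axis=1, keepdims=True)
    n = len(labels)
    nll = -np.log(np.clip(p[np.arange(n), labels], 1e-12, None))
    out = Tensor(nll.mean(), logits.requires_grad, (logits,))

    def bw(g):
        if logits.requires_grad:
            grad = p.copy()
            grad[np.arange(n), labels] -= 1.0
            logits._accumulate(g * grad / n)

    out._backward = bw
    return out
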