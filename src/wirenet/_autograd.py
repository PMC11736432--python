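"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations the recurrent cells need: elementwise
arithmetic with broadcasting, matrix products, ReLU / sigmoid / tanh,
and a fused softmax cross-entropy loss. Gradients are accumulated by a
single topological-order sweep from the loss node.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "constant", "softmax_cross_entropy"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_bwd")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._parents: tuple[Tensor, ...] = ()
        self._bwd = None  # callable: out_grad -> tuple of parent grads

    # -- graph construction -------------------------------------------------

    @staticmethod
    def _op(data, parents, bwd) -> "Tensor":
        out = Tensor(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = tuple(parents)
            out._bwd = bwd
        return out

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))

    @property
    def shape(self):
        return self.data.shape

    # -- arithmetic ---------------------------------------------------------

    def __add__(self, other):
        other = Tensor._lift(other)
        a, b = self, other
        return Tensor._op(
            a.data + b.data,
            (a, b),
            lambda g: (_unbroadcast(g, a.data.shape), _unbroadcast(g, b.data.shape)),
        )

    __radd__ = __add__

    def __sub__(self, other):
        other = Tensor._lift(other)
        a, b = self, other
        return Tensor._op(
            a.data - b.data,
            (a, b),
            lambda g: (_unbroadcast(g, a.data.shape), _unbroadcast(-g, b.data.shape)),
        )

    def __rsub__(self, other):
        return Tensor._lift(other) - self

    def __mul__(self, other):
        other = Tensor._lift(other)
        a, b = self, other
        return Tensor._op(
            a.data * b.data,
            (a, b),
            lambda g: (
                _unbroadcast(g * b.data, a.data.shape),
                _unbroadcast(g * a.data, b.data.shape),
            ),
        )

    __rmul__ = __mul__

    def __neg__(self):
        return Tensor._op(-self.data, (self,), lambda g: (-g,))

    def __matmul__(self, other):
        other = Tensor._lift(other)
        a, b = self, other
        return Tensor._op(
            a.data @ b.data,
            (a, b),
            lambda g: (g @ b.data.T, a.data.T @ g),
        )

    # -- nonlinearities -----------------------------------------------------

    def relu(self) -> "Tensor":
        out_data = np.maximum(self.data, 0.0)
        return Tensor._op(out_data, (self,), lambda g: (g * (self.data > 0.0),))

    def sigmoid(self) -> "Tensor":
        s = 1.0 / (1.0 + np.exp(-self.data))
        return Tensor._op(s, (self,), lambda g: (g * s * (1.0 - s),))

    def tanh(self) -> "Tensor":
        t = np.tanh(self.data)
        return Tensor._op(t, (self,), lambda g: (g * (1.0 - t * t),))

    # -- autodiff -----------------------------------------------------------

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Accumulate gradients into every reachable node with requires_grad."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar output")
            grad = np.ones_like(self.data)

        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))

        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._bwd is None:  # leaf
                node.grad = g if node.grad is None else node.grad + g
                continue
            for parent, pg in zip(node._parents, node._bwd(g)):
                if not parent.requires_grad:
                    continue
                if id(parent) in grads:
                    grads[id(parent)] = grads[id(parent)] + pg
                else:
                    grads[id(parent)] = pg

    def zero_grad(self) -> None:
        self.grad = None


def constant(data) -> Tensor:
    return Tensor(data, requires_grad=False)


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy of softmax(logits) against integer class labels."""
    labels = np.asarray(labels)
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=1, keepdims=True)
    n = labels.shape[0]
    loss = -np.log(p[np.arange(n), labels] + 1e-300).mean()

    def bwd(g):
        d = p.copy()
        d[np.arange(n), labels] -= 1.0
        return (g * d / n,)

    return Tensor._op(np.asarray(loss), (logits,), bwd)
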