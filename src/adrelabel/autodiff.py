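"""A compact reverse-mode automatic differentiation core on numpy arrays.

Supports exactly the operations the auto-metric GNN needs: matrix
multiplication, broadcast addition, elementwise multiplication and
division, ReLU, softplus, reshape, axis sums, and a fused
softmax-cross-entropy loss.  Gradients are accumulated by reverse
topological traversal; correctness is guarded by finite-difference
checks in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "parameter", "cross_entropy", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum a gradient back down to the shape it was broadcast from."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=float)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    # -- graph construction -------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def backward(g):
            return (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape))
        out._backward = backward
        return out

    def __sub__(self, other):
        other = self._lift(other)
        out = Tensor(self.data - other.data, parents=(self, other))

        def backward(g):
            return (_unbroadcast(g, self.shape), _unbroadcast(-g, other.shape))
        out._backward = backward
        return out

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def backward(g):
            return (_unbroadcast(g * other.data, self.shape),
                    _unbroadcast(g * self.data, other.shape))
        out._backward = backward
        return out

    def __truediv__(self, other):
        other = self._lift(other)
        out = Tensor(self.data / other.data, parents=(self, other))

        def backward(g):
            return (_unbroadcast(g / other.data, self.shape),
                    _unbroadcast(-g * self.data / other.data**2, other.shape))
        out._backward = backward
        return out

    def matmul(self, other):
        other = self._lift(other)
        out = Tensor(self.data @ other.data, parents=(self, other))

        def backward(g):
            return (g @ other.data.T, self.data.T @ g)
        out._backward = backward
        return out

    __matmul__ = matmul

    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), parents=(self,))

        def backward(g):
            return (g * (self.data > 0),)
        out._backward = backward
        return out

    def softplus(self):
        # numerically stable log(1 + exp(x))
        out = Tensor(np.logaddexp(0.0, self.data), parents=(self,))

        def backward(g):
            return (g / (1.0 + np.exp(-self.data)),)
        out._backward = backward
        return out

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), parents=(self,))

        def backward(g):
            return (g.reshape(self.shape),)
        out._backward = backward
        return out

    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))

        def backward(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, self.shape).copy(),)
        out._backward = backward
        return out

    def concat(self, other, axis=1):
        other = self._lift(other)
        out = Tensor(np.concatenate([self.data, other.data], axis=axis),
                     parents=(self, other))
        split = self.data.shape[axis]

        def backward(g):
            ga, gb = np.split(g, [split], axis=axis)
            return (ga, gb)
        out._backward = backward
        return out

    # -- backward pass ------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient needs a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor) -> None:
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=float)}
        for t in reversed(topo):
            g = grads.pop(id(t), None)
            if g is None:
                continue
            if t._backward is not None:
                for p, pg in zip(t._parents, t._backward(g)):
                    if not p.requires_grad:
                        continue
                    if id(p) in grads:
                        grads[id(p)] = grads[id(p)] + pg
                    else:
                        grads[id(p)] = pg
            if not t._parents:  # leaf
                t.grad = g if t.grad is None else t.grad + g


def parameter(data) -> Tensor:
    return Tensor(np.asarray(data, dtype=float), requires_grad=True)


def cross_entropy(logits: Tensor, targets: np.ndarray,
                  mask: np.ndarray | None = None) -> Tensor:
    """Mean softmax cross-entropy over (optionally masked) rows.

    ``targets`` are integer class indices; the gradient is the familiar
    (softmax - onehot)/n restricted to the masked rows.
    """
    z = logits.data
    z = z - z.max(axis=1, keepdims=True)
    expz = np.exp(z)
    probs = expz / expz.sum(axis=1, keepdims=True)
    rows = np.arange(len(targets)) if mask is None else np.flatnonzero(mask)
    nll = -np.log(probs[rows, targets[rows]] + 1e-300)
    out = Tensor(nll.mean(), parents=(logits,))

    def backward(g):
        grad = np.zeros_like(probs)
        grad[rows] = probs[rows]
        grad[rows, targets[rows]] -= 1.0
        return (g * grad / len(rows),)
    out._backward = backward
    return out


def softmax_rows(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class Adam:
    """First-order adaptive gradient optimizer (bias-corrected moments)."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            self.m[i] = b1 * self.m[i] + (1 - b1) * p.grad
            self.v[i] = b2 * self.v[i] + (1 - b2) * p.grad**2
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
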