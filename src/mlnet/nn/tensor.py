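"""Minimal reverse-mode autodiff on numpy arrays.

Single-threaded, float32, deterministic: identical inputs and op order give
bitwise-identical gradients, which the training loops rely on for seeded
reproducibility. Only the ops needed by the 3D segmentation / classification
networks are implemented.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Parameter", "concat", "stack_losses"]


class Tensor:
    """A numpy array plus a gradient tape node."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents", "name")

    def __init__(self, data, requires_grad: bool = False, name: str = ""):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()
        self.name = name

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this tensor (defaults to d(self)/d(self) = 1)."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        if grad is None:
            grad = np.ones_like(self.data)
        self._accumulate(np.asarray(grad, dtype=np.float32))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.grad is not None})"

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = _as_tensor(other)
        out = Tensor(self.data + other.data)
        out._parents = (self, other)

        def _bw(g):
            self._accumulate(_unbroadcast(g, self.data.shape))
            other._accumulate(_unbroadcast(g, other.data.shape))

        out._backward = _bw
        return out

    def __sub__(self, other):
        other = _as_tensor(other)
        out = Tensor(self.data - other.data)
        out._parents = (self, other)

        def _bw(g):
            self._accumulate(_unbroadcast(g, self.data.shape))
            other._accumulate(_unbroadcast(-g, other.data.shape))

        out._backward = _bw
        return out

    def __mul__(self, other):
        other = _as_tensor(other)
        out = Tensor(self.data * other.data)
        out._parents = (self, other)

        def _bw(g):
            self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        out._backward = _bw
        return out

    __radd__ = __add__
    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def scale(self, c: float) -> "Tensor":
        out = Tensor(self.data * np.float32(c))
        out._parents = (self,)
        out._backward = lambda g: self._accumulate(g * np.float32(c))
        return out

    # -------------------------------------------------------------- reshaping
    def reshape(self, *shape) -> "Tensor":
        out = Tensor(self.data.reshape(*shape))
        out._parents = (self,)
        out._backward = lambda g: self._accumulate(g.reshape(self.data.shape))
        return out

    # ------------------------------------------------------------ reductions
    def sum(self) -> "Tensor":
        out = Tensor(self.data.sum())
        out._parents = (self,)
        out._backward = lambda g: self._accumulate(
            np.broadcast_to(g, self.data.shape).astype(np.float32)
        )
        return out

    def mean(self) -> "Tensor":
        n = self.data.size
        out = Tensor(self.data.mean())
        out._parents = (self,)
        out._backward = lambda g: self._accumulate(
            np.broadcast_to(g / n, self.data.shape).astype(np.float32)
        )
        return out

    # ---------------------------------------------------------- nonlinearity
    def relu(self) -> "Tensor":
        mask = self.data > 0
        out = Tensor(np.where(mask, self.data, 0.0))
        out._parents = (self,)
        out._backward = lambda g: self._accumulate(np.where(mask, g, 0.0))
        return out

    def sigmoid(self) -> "Tensor":
        s = _sigmoid(self.data)
        out = Tensor(s)
        out._parents = (self,)
        out._backward = lambda g: self._accumulate(g * s * (1.0 - s))
        return out

    def matmul(self, other: "Tensor") -> "Tensor":
        out = Tensor(self.data @ other.data)
        out._parents = (self, other)

        def _bw(g):
            self._accumulate(g @ other.data.T)
            other._accumulate(self.data.T @ g)

        out._backward = _bw
        return out


class Parameter(Tensor):
    """Trainable tensor."""

    def __init__(self, data, name: str = ""):
        super().__init__(data, requires_grad=True, name=name)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float32))


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce gradient g back to `shape` after numpy broadcasting."""
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g.astype(np.float32)


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    """Concatenate along `axis` (channel concat for feature injection)."""
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis))
    out._parents = tuple(tensors)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def _bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            t._accumulate(g[tuple(sl)])

    out._backward = _bw
    return out


def stack_losses(losses: list[Tensor], weights) -> Tensor:
    """Weighted sum of scalar losses."""
    w = np.asarray(weights, dtype=np.float32)
    if len(losses) != len(w):
        raise ValueError("losses and weights length mismatch")
    total = losses[0].scale(float(w[0]))
    for li, wi in zip(losses[1:], w[1:]):
        total = total + li.scale(float(wi))
    return total
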