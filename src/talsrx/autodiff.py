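"""A compact reverse-mode automatic-differentiation engine over numpy.

Supports exactly the vectorized operations the neural branches need —
broadcasting arithmetic, batched matmul, elementwise nonlinearities, axis
reductions, reshape/transpose, dropout masking and a stable softmax
cross-entropy — with gradients accumulated by reverse topological sweep.
Everything is plain numpy, so training is bit-reproducible under a seeded
``numpy.random.Generator``.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum a broadcast gradient back down to ``shape``."""
    if grad.shape == shape:
        return grad
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._prev: tuple[Tensor, ...] = ()

    @property
    def shape(self):
        return self.data.shape

    # -- graph plumbing -------------------------------------------------

    def _accumulate(self, g: np.ndarray) -> None:
        # always copy on first touch: g may alias another node's gradient
        if self.grad is None:
            self.grad = np.array(g, dtype=DTYPE)
        else:
            self.grad += g

    def backward(self) -> None:
        """Reverse sweep from a scalar output."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
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
            for p in node._prev:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic -----------------------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _binary(self, other, out_data, back):
        other = Tensor._lift(other)
        out = Tensor(out_data)
        out.requires_grad = self.requires_grad or other.requires_grad
        out._prev = (self, other)
        out._backward = back(self, other)
        return out

    def __add__(self, other):
        other = Tensor._lift(other)

        def back(a, b):
            def _bw(g):
                if a.requires_grad or a._prev:
                    a._accumulate(_unbroadcast(g, a.shape))
                if b.requires_grad or b._prev:
                    b._accumulate(_unbroadcast(g, b.shape))
            return _bw

        return self._binary(other, self.data + other.data, back)

    def __mul__(self, other):
        other = Tensor._lift(other)

        def back(a, b):
            def _bw(g):
                if a.requires_grad or a._prev:
                    a._accumulate(_unbroadcast(g * b.data, a.shape))
                if b.requires_grad or b._prev:
                    b._accumulate(_unbroadcast(g * a.data, b.shape))
            return _bw

        return self._binary(other, self.data * other.data, back)

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-Tensor._lift(other))

    __radd__ = __add__
    __rmul__ = __mul__

    def __matmul__(self, other):
        other = Tensor._lift(other)

        def back(a, b):
            def _bw(g):
                if a.requires_grad or a._prev:
                    ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
                    a._accumulate(_unbroadcast(ga, a.shape))
                if b.requires_grad or b._prev:
                    gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
                    b._accumulate(_unbroadcast(gb, b.shape))
            return _bw

        return self._binary(other, np.matmul(self.data, other.data), back)

    def pow(self, exponent: float):
        out = Tensor(self.data ** exponent)
        out.requires_grad = self.requires_grad
        out._prev = (self,)

        def _bw(g):
            self._accumulate(g * exponent * self.data ** (exponent - 1.0))

        out._backward = _bw
        return out

    # -- elementwise nonlinearities ------------------------------------

    def _unary(self, out_data, grad_local):
        out = Tensor(out_data)
        out.requires_grad = self.requires_grad
        out._prev = (self,)

        def _bw(g):
            self._accumulate(g * grad_local(out_data))

        out._backward = _bw
        return out

    def exp(self):
        return self._unary(np.exp(self.data), lambda o: o)

    def log(self):
        return self._unary(np.log(self.data), lambda o: 1.0 / self.data)

    def tanh(self):
        return self._unary(np.tanh(self.data), lambda o: 1.0 - o * o)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))
        return self._unary(out_data, lambda o: o * (1.0 - o))

    def relu(self):
        return self._unary(
            np.maximum(self.data, 0.0), lambda o: (self.data > 0).astype(DTYPE)
        )

    # -- reductions & shape ---------------------------------------------

    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims))
        out.requires_grad = self.requires_grad
        out._prev = (self,)

        def _bw(g):
            gg = g
            if axis is not None and not keepdims:
                gg = np.expand_dims(gg, axis)
            self._accumulate(np.broadcast_to(gg, self.shape).copy())

        out._backward = _bw
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape))
        out.requires_grad = self.requires_grad
        out._prev = (self,)

        def _bw(g):
            self._accumulate(g.reshape(self.shape))

        out._backward = _bw
        return out

    def transpose(self, axes):
        out = Tensor(self.data.transpose(axes))
        out.requires_grad = self.requires_grad
        out._prev = (self,)
        inverse = np.argsort(axes)

        def _bw(g):
            self._accumulate(g.transpose(inverse))

        out._backward = _bw
        return out


# -- composite operations ----------------------------------------------


def softmax(t: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable softmax, fused into one node: the backward pass is
    ``g_in = s * (g - sum(g * s))`` along the softmax axis."""
    e = np.exp(t.data - t.data.max(axis=axis, keepdims=True))
    s = e / e.sum(axis=axis, keepdims=True)
    out = Tensor(s)
    out.requires_grad = t.requires_grad
    out._prev = (t,)

    def _bw(g):
        inner = (g * s).sum(axis=axis, keepdims=True)
        t._accumulate(s * (g - inner))

    out._backward = _bw
    return out


def log_softmax(t: Tensor, axis: int = -1) -> Tensor:
    shifted = t + Tensor(-t.data.max(axis=axis, keepdims=True))
    return shifted - shifted.exp().sum(axis=axis, keepdims=True).log()


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean negative log-likelihood of integer ``labels`` under ``logits``."""
    n, k = logits.shape
    onehot = np.zeros((n, k), dtype=DTYPE)
    onehot[np.arange(n), np.asarray(labels, dtype=int)] = 1.0
    return -(log_softmax(logits) * Tensor(onehot)).sum() * (1.0 / n)


def layer_norm(t: Tensor, gain: Tensor, bias: Tensor, eps: float = 1e-5) -> Tensor:
    """Layer normalization over the last axis."""
    mu = t.mean(axis=-1, keepdims=True)
    centered = t - mu
    var = (centered * centered).mean(axis=-1, keepdims=True)
    return centered * (var + eps).pow(-0.5) * gain + bias


def dropout(t: Tensor, p: float, rng: np.random.Generator, training: bool) -> Tensor:
    """Inverted dropout: active only in training mode."""
    if not training or p <= 0:
        return t
    mask = (rng.random(t.shape) >= p).astype(DTYPE) / (1.0 - p)
    return t * Tensor(mask)


class Adam:
    """Adam optimizer over a list of parameter tensors, with global-norm
    gradient clipping for stability at aggressive learning rates."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 clip_norm: float | None = 5.0):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.clip_norm = clip_norm
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def _clip(self) -> None:
        if self.clip_norm is None:
            return
        total = np.sqrt(
            sum(float(np.sum(p.grad.astype(np.float64) ** 2))
                for p in self.params if p.grad is not None)
        )
        if total > self.clip_norm:
            scale = self.clip_norm / total
            for p in self.params:
                if p.grad is not None:
                    p.grad = p.grad * DTYPE(scale)

    def step(self) -> None:
        self._clip()
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad.astype(np.float64)
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data = (p.data.astype(np.float64)
                      - self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(DTYPE)
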