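"""A small reverse-mode automatic-differentiation engine over numpy arrays.

Implements exactly the operations the moment-aggregation model needs:
dense linear algebra, elementwise arithmetic, integer powers and signed
roots, sigmoid/relu, row gather and segment means over edge lists, and a
numerically stable binary cross-entropy on logits.  Gradients propagate
through a dynamically built tape; `Adam` performs the parameter updates.
"""

from __future__ import annotations

import numpy as np


class Tensor:
    """A node in the computation tape.

    ``parents`` holds ``(tensor, vjp)`` pairs where ``vjp`` maps the output
    cotangent to that parent's cotangent contribution.
    """

    __slots__ = ("data", "grad", "parents", "requires_grad")

    def __init__(self, data, parents=(), requires_grad=False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.parents = tuple(parents)
        self.requires_grad = requires_grad or any(p.requires_grad for p, _ in parents)

    @property
    def shape(self):
        return self.data.shape

    def backward(self, seed=None):
        """Accumulate gradients of ``self`` w.r.t. every reachable tensor."""
        order, visited = [], set()

        def visit(t):
            if id(t) in visited:
                return
            visited.add(id(t))
            for p, _ in t.parents:
                visit(p)
            order.append(t)

        visit(self)
        for t in order:
            t.grad = None
        self.grad = np.ones_like(self.data) if seed is None else np.asarray(seed, dtype=np.float64)
        for t in reversed(order):
            if t.grad is None or not t.requires_grad:
                continue
            for parent, vjp in t.parents:
                if not parent.requires_grad:
                    continue
                contribution = vjp(t.grad)
                if parent.grad is None:
                    parent.grad = contribution.copy()
                else:
                    parent.grad += contribution

    # -- operator sugar ----------------------------------------------------
    def __add__(self, other):
        return add(self, _as_tensor(other))

    __radd__ = __add__

    def __sub__(self, other):
        return add(self, scale(_as_tensor(other), -1.0))

    def __mul__(self, other):
        if isinstance(other, (int, float)):
            return scale(self, float(other))
        return mul(self, other)

    __rmul__ = __mul__

    def __matmul__(self, other):
        return matmul(self, other)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


def add(a: Tensor, b: Tensor) -> Tensor:
    return Tensor(
        a.data + b.data,
        parents=[
            (a, lambda g: _unbroadcast(g, a.data.shape)),
            (b, lambda g: _unbroadcast(g, b.data.shape)),
        ],
    )


def mul(a: Tensor, b: Tensor) -> Tensor:
    return Tensor(
        a.data * b.data,
        parents=[
            (a, lambda g: _unbroadcast(g * b.data, a.data.shape)),
            (b, lambda g: _unbroadcast(g * a.data, b.data.shape)),
        ],
    )


def scale(a: Tensor, c: float) -> Tensor:
    return Tensor(a.data * c, parents=[(a, lambda g: g * c)])


def matmul(a: Tensor, b: Tensor) -> Tensor:
    return Tensor(
        a.data @ b.data,
        parents=[(a, lambda g: g @ b.data.T), (b, lambda g: a.data.T @ g)],
    )


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    widths = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + widths)
    parents = []
    for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
        def vjp(g, lo=lo, hi=hi):
            index = [slice(None)] * g.ndim
            index[axis] = slice(lo, hi)
            return g[tuple(index)]

        parents.append((t, vjp))
    return Tensor(np.concatenate([t.data for t in tensors], axis=axis), parents=parents)


def sigmoid(a: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-np.clip(a.data, -500, 500)))
    return Tensor(s, parents=[(a, lambda g: g * s * (1.0 - s))])


def relu(a: Tensor) -> Tensor:
    mask = a.data > 0
    return Tensor(a.data * mask, parents=[(a, lambda g: g * mask)])


def power_int(a: Tensor, k: int) -> Tensor:
    """Elementwise integer power ``a**k`` (plain real power)."""
    if k < 1:
        raise ValueError("power order must be >= 1")
    out = a.data**k
    if k == 1:
        return Tensor(out, parents=[(a, lambda g: g)])
    deriv = k * a.data ** (k - 1)
    return Tensor(out, parents=[(a, lambda g: g * deriv)])


def signed_root(a: Tensor, k: int, eps: float = 1e-8) -> Tensor:
    """Elementwise ``sign(s) * (|s| + eps)**(1/k)``.

    Keeps odd-order negative moments negative and stays differentiable at 0
    thanks to the stabiliser ``eps``.
    """
    if k < 1:
        raise ValueError("root order must be >= 1")
    base = np.abs(a.data) + eps
    out = np.sign(a.data) * base ** (1.0 / k)
    # d/ds sign(s)(|s|+eps)^(1/k) = (1/k)(|s|+eps)^(1/k - 1); at s=0 the
    # two one-sided derivatives agree, so the same expression applies.
    with np.errstate(divide="ignore"):
        deriv = (1.0 / k) * base ** (1.0 / k - 1.0)
    if k > 1:
        deriv = np.where(base > 0, deriv, 0.0)
    return Tensor(out, parents=[(a, lambda g: g * deriv)])


def gather(a: Tensor, index: np.ndarray) -> Tensor:
    index = np.asarray(index, dtype=np.int64)

    def vjp(g):
        out = np.zeros_like(a.data)
        np.add.at(out, index, g)
        return out

    return Tensor(a.data[index], parents=[(a, vjp)])


def segment_mean(a: Tensor, segments: np.ndarray, n_segments: int) -> Tensor:
    """Mean of the rows of ``a`` grouped by ``segments``; empty segments yield 0."""
    segments = np.asarray(segments, dtype=np.int64)
    counts = np.bincount(segments, minlength=n_segments).astype(np.float64)
    safe = np.maximum(counts, 1.0)
    sums = np.zeros((n_segments,) + a.data.shape[1:])
    np.add.at(sums, segments, a.data)
    out = sums / safe[:, None]

    def vjp(g):
        return (g / safe[:, None])[segments]

    return Tensor(out, parents=[(a, vjp)])


def mean_all(a: Tensor) -> Tensor:
    n = a.data.size
    return Tensor(
        np.asarray(a.data.mean()), parents=[(a, lambda g: np.full_like(a.data, g / n))]
    )


def bce_with_logits(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean binary cross-entropy computed stably from logits."""
    labels = np.asarray(labels, dtype=np.float64).reshape(logits.data.shape)
    z = logits.data
    # softplus(z) - y*z, with softplus(z) = max(z,0) + log1p(exp(-|z|))
    loss = np.maximum(z, 0.0) - labels * z + np.log1p(np.exp(-np.abs(z)))
    n = z.size
    sig = 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))

    def vjp(g):
        return g * (sig - labels) / n

    return Tensor(np.asarray(loss.mean()), parents=[(logits, vjp)])


class Adam:
    """Adam optimiser over a list of parameter tensors, with gradient clipping."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8, clip_norm: float | None = 5.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.clip_norm = clip_norm
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        grads = [p.grad if p.grad is not None else np.zeros_like(p.data) for p in self.params]
        if self.clip_norm is not None:
            total = np.sqrt(sum(float((g**2).sum()) for g in grads))
            if total > self.clip_norm:
                grads = [g * (self.clip_norm / total) for g in grads]
        self.t += 1
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1; m += (1 - self.b1) * g
            v *= self.b2; v += (1 - self.b2) * g * g
            m_hat = m / (1 - self.b1**self.t)
            v_hat = v / (1 - self.b2**self.t)
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
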