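"""Minimal reverse-mode automatic differentiation on numpy arrays.

Just enough machinery for the recurrent attention encoder–decoder in
``.backend``: broadcast-aware elementwise ops, (batched) matmul, sigmoid,
tanh, concatenation, embedding lookup and a fused softmax cross-entropy.
Gradients are accumulated by a topological sweep over the tape each node
records implicitly through its parent links.
"""

from __future__ import annotations

import numpy as np


class Tensor:
    __slots__ = ("data", "grad", "parents", "grad_fns", "requires_grad")

    def __init__(self, data, parents=(), grad_fns=(), requires_grad=False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.parents = parents
        self.grad_fns = grad_fns
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)

    @property
    def shape(self):
        return self.data.shape

    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor) -> None:
            stack = [(t, iter(t.parents))]
            seen.add(id(t))
            while stack:
                node, it = stack[-1]
                advanced = False
                for p in it:
                    if id(p) not in seen and p.requires_grad:
                        seen.add(id(p))
                        stack.append((p, iter(p.parents)))
                        advanced = True
                        break
                if not advanced:
                    topo.append(node)
                    stack.pop()

        visit(self)
        self.grad = grad
        for node in reversed(topo):
            g = node.grad
            if g is None:
                continue
            for parent, fn in zip(node.parents, node.grad_fns):
                if not parent.requires_grad:
                    continue
                pg = fn(g)
                if parent.grad is None:
                    parent.grad = pg
                else:
                    parent.grad = parent.grad + pg

    # sugar used by the model code
    def __add__(self, other):
        return add(self, other)

    def __radd__(self, other):
        return add(self, other)

    def __mul__(self, other):
        return mul(self, other)

    def __rmul__(self, other):
        return mul(self, other)

    def __matmul__(self, other):
        return matmul(self, other)


def param(data, rng: np.random.Generator | None = None, scale: float | None = None) -> Tensor:
    """A trainable leaf tensor; with ``rng`` set, Glorot-style random init."""
    if rng is not None:
        shape = data if isinstance(data, tuple) else tuple(data)
        if scale is None:
            scale = float(np.sqrt(2.0 / sum(shape)))
        data = rng.normal(0.0, scale, size=shape)
    return Tensor(data, requires_grad=True)


def constant(data) -> Tensor:
    return Tensor(data)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))


def add(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    return Tensor(a.data + b.data, (a, b),
                  (lambda g: _unbroadcast(g, a.shape), lambda g: _unbroadcast(g, b.shape)))


def mul(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    return Tensor(a.data * b.data, (a, b),
                  (lambda g: _unbroadcast(g * b.data, a.shape),
                   lambda g: _unbroadcast(g * a.data, b.shape)))


def matmul(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)

    def grad_a(g):
        return _unbroadcast(np.matmul(g, np.swapaxes(b.data, -1, -2)), a.shape)

    def grad_b(g):
        return _unbroadcast(np.matmul(np.swapaxes(a.data, -1, -2), g), b.shape)

    return Tensor(np.matmul(a.data, b.data), (a, b), (grad_a, grad_b))


def tanh(a: Tensor) -> Tensor:
    out = np.tanh(a.data)
    return Tensor(out, (a,), (lambda g: g * (1.0 - out * out),))


def sigmoid(a: Tensor) -> Tensor:
    out = 1.0 / (1.0 + np.exp(-np.clip(a.data, -60, 60)))
    return Tensor(out, (a,), (lambda g: g * out * (1.0 - out),))


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    datas = [t.data for t in tensors]
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def make_grad(i):
        def fn(g):
            sl = [slice(None)] * g.ndim
            sl[axis if axis >= 0 else g.ndim + axis] = slice(offsets[i], offsets[i + 1])
            return g[tuple(sl)]
        return fn

    return Tensor(np.concatenate(datas, axis=axis), tuple(tensors),
                  tuple(make_grad(i) for i in range(len(tensors))))


def reshape(a: Tensor, shape: tuple) -> Tensor:
    old = a.shape
    return Tensor(a.data.reshape(shape), (a,), (lambda g: g.reshape(old),))


def embedding(table: Tensor, ids: np.ndarray) -> Tensor:
    ids = np.asarray(ids)

    def grad_table(g):
        out = np.zeros_like(table.data)
        np.add.at(out, ids.reshape(-1), g.reshape(-1, table.data.shape[1]))
        return out

    return Tensor(table.data[ids], (table,), (grad_table,))


def softmax(a: Tensor, axis: int = -1, additive_mask: np.ndarray | None = None) -> Tensor:
    x = a.data if additive_mask is None else a.data + additive_mask
    x = x - x.max(axis=axis, keepdims=True)
    e = np.exp(x)
    out = e / e.sum(axis=axis, keepdims=True)

    def grad_a(g):
        dot = (g * out).sum(axis=axis, keepdims=True)
        return out * (g - dot)

    return Tensor(out, (a,), (grad_a,))


def cross_entropy_logits(logits: Tensor, targets: np.ndarray, weights: np.ndarray) -> Tensor:
    """Weighted mean of -log softmax(logits)[target] over positions.

    ``logits`` is (N, V); ``weights`` zeroes out padding positions; the
    result is the average per contributing position.
    """
    x = logits.data - logits.data.max(axis=-1, keepdims=True)
    lse = np.log(np.exp(x).sum(axis=-1))
    n = np.arange(len(targets))
    logp = x[n, targets] - lse
    total = weights.sum()
    loss = -(weights * logp).sum() / total

    def grad_logits(g):
        p = np.exp(x - lse[:, None])
        p[n, targets] -= 1.0
        return g * p * (weights / total)[:, None]

    return Tensor(loss, (logits,), (grad_logits,))


class Adam:
    """Adam with linear learning-rate warmup over the first ``warmup`` updates."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3, warmup: int = 0,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.warmup = max(0, int(warmup))
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        lr = self.lr * min(1.0, self.t / self.warmup) if self.warmup else self.lr
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
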