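"""Minimal reverse-mode automatic differentiation over numpy arrays.

Implements exactly the operations a Transformer encoder--decoder needs
(matmul, broadcasting add, relu, softmax, layer norm, embedding lookup,
dropout, masked token-level cross-entropy) as a tape of closures. The API
is functional: every op takes and returns :class:`Tensor`.

Gradient checking against central finite differences lives in the test
suite; all ops support float64 inputs for that purpose while the model
itself runs in float32.
"""

from __future__ import annotations

from contextlib import contextmanager

import numpy as np

_GRAD_ENABLED = True


@contextmanager
def no_grad():
    """Disable graph construction (evaluation / decoding)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def grad_enabled() -> bool:
    return _GRAD_ENABLED


class Tensor:
    """An array node in the autodiff tape.

    ``grad`` accumulates the gradient of the final scalar w.r.t. ``data``
    after :meth:`backward` is called on that scalar.
    """

    __slots__ = ("data", "grad", "_parents", "_backward")

    def __init__(self, data, parents=(), backward=None):
        self.data = np.asarray(data)
        self.grad = None
        if _GRAD_ENABLED:
            self._parents = tuple(parents)
            self._backward = backward
        else:
            self._parents = ()
            self._backward = None

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def zero_grad(self):
        self.grad = None

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
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
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
            # release graph references as we go
            node._backward = None
            node._parents = ()


def _accum(t: Tensor, g: np.ndarray) -> None:
    # Callers guarantee `g` is either freshly allocated or may alias the
    # (already consumed) child gradient; ops that would hand the same array
    # to two different parents copy one of them (see `add`).
    if t.grad is None:
        t.grad = g if isinstance(g, np.ndarray) else np.asarray(g)
    else:
        t.grad += g


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum gradient ``g`` down to ``shape`` (inverse of numpy broadcasting)."""
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g


def add(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data + b.data

    def backward(g):
        ga = _unbroadcast(g, a.data.shape)
        gb = _unbroadcast(g, b.data.shape)
        if gb is ga:  # same array object would alias two parents' grads
            gb = gb.copy()
        _accum(a, ga)
        _accum(b, gb)

    return Tensor(out_data, (a, b), backward)


def add_const(a: Tensor, c: np.ndarray) -> Tensor:
    """Add a constant (no gradient flows to ``c``)."""
    out_data = a.data + c

    def backward(g):
        _accum(a, _unbroadcast(g, a.data.shape))

    return Tensor(out_data, (a,), backward)


def scale(a: Tensor, s: float) -> Tensor:
    def backward(g):
        _accum(a, g * s)

    return Tensor(a.data * s, (a,), backward)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data @ b.data

    def backward(g):
        ga = g @ np.swapaxes(b.data, -1, -2)
        gb = np.swapaxes(a.data, -1, -2) @ g
        _accum(a, _unbroadcast(ga, a.data.shape))
        _accum(b, _unbroadcast(gb, b.data.shape))

    return Tensor(out_data, (a, b), backward)


def linear(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """``x @ w + b`` with ``w`` of shape (in, out)."""
    out_data = x.data @ w.data
    if b is not None:
        out_data = out_data + b.data

    def backward(g):
        x2 = x.data.reshape(-1, x.data.shape[-1])
        g2 = g.reshape(-1, g.shape[-1])
        _accum(w, x2.T @ g2)
        _accum(x, g @ w.data.T)
        if b is not None:
            _accum(b, g2.sum(axis=0))

    parents = (x, w) if b is None else (x, w, b)
    return Tensor(out_data, parents, backward)


def relu(a: Tensor) -> Tensor:
    mask = a.data > 0
    out_data = a.data * mask

    def backward(g):
        _accum(a, g * mask)

    return Tensor(out_data, (a,), backward)


def dropout(a: Tensor, p: float, rng: np.random.Generator, training: bool) -> Tensor:
    if not training or p <= 0.0:
        return a
    keep = rng.random(a.data.shape) >= p
    factor = 1.0 / (1.0 - p)
    out_data = a.data * keep * factor

    def backward(g):
        _accum(a, g * keep * factor)

    return Tensor(out_data, (a,), backward)


def softmax(a: Tensor, axis: int = -1) -> Tensor:
    m = a.data.max(axis=axis, keepdims=True)
    e = np.exp(a.data - m)
    y = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        dot = (g * y).sum(axis=axis, keepdims=True)
        _accum(a, (g - dot) * y)

    return Tensor(y, (a,), backward)


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Normalization over the last axis with learnable gain/shift."""
    mu = x.data.mean(axis=-1, keepdims=True)
    var = x.data.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    out_data = gamma.data * xhat + beta.data

    def backward(g):
        gx = g * gamma.data
        mean_gx = gx.mean(axis=-1, keepdims=True)
        mean_gx_xhat = (gx * xhat).mean(axis=-1, keepdims=True)
        _accum(x, inv * (gx - mean_gx - xhat * mean_gx_xhat))
        axes = tuple(range(g.ndim - 1))
        _accum(gamma, (g * xhat).sum(axis=axes))
        _accum(beta, g.sum(axis=axes))

    return Tensor(out_data, (x, gamma, beta), backward)


def embedding(table: Tensor, ids: np.ndarray) -> Tensor:
    ids = np.asarray(ids)
    out_data = table.data[ids]

    def backward(g):
        gt = np.zeros_like(table.data)
        np.add.at(gt, ids.reshape(-1), g.reshape(-1, g.shape[-1]))
        _accum(table, gt)

    return Tensor(out_data, (table,), backward)


def transpose(a: Tensor, axes: tuple) -> Tensor:
    inv = np.argsort(axes)

    def backward(g):
        _accum(a, np.transpose(g, inv))

    return Tensor(np.transpose(a.data, axes), (a,), backward)


def reshape(a: Tensor, shape: tuple) -> Tensor:
    orig = a.data.shape

    def backward(g):
        _accum(a, g.reshape(orig))

    return Tensor(a.data.reshape(shape), (a,), backward)


def cross_entropy_logits(logits: Tensor, targets: np.ndarray, valid: np.ndarray) -> Tensor:
    """Mean token cross-entropy over positions where ``valid`` is True.

    ``logits``: (N, V); ``targets``: (N,) int ids; ``valid``: (N,) bool.
    Raises if no position is valid (e.g. an all-padding target).
    """
    targets = np.asarray(targets).reshape(-1)
    valid = np.asarray(valid).reshape(-1).astype(bool)
    n_valid = int(valid.sum())
    if n_valid == 0:
        raise ValueError("cross-entropy over zero non-padding positions")
    z = logits.data
    m = z.max(axis=-1, keepdims=True)
    lse = m + np.log(np.exp(z - m).sum(axis=-1, keepdims=True))
    logp = z - lse
    nll = -logp[np.arange(z.shape[0]), targets]
    loss = nll[valid].mean()

    def backward(g):
        probs = np.exp(logp)
        d = probs
        d[np.arange(z.shape[0]), targets] -= 1.0
        d *= (valid / n_valid)[:, None] * g
        _accum(logits, d)

    return Tensor(np.asarray(loss), (logits,), backward)
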