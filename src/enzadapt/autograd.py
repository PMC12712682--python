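"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Supports exactly the operations the fusion model and the downstream
classifier need: broadcast arithmetic, (batched) matrix products, tanh /
GELU / ReLU nonlinearities, softmax with an additive mask, layer
normalization, embedding lookup, dropout, and masked cross-entropy from
logits.  All computation is float64, so training runs are bit-reproducible
given a seed and gradient sums are exactly linear in their parts.

Gradients accumulate into ``Tensor.grad``; call :func:`backward` on a
scalar result.  Graphs are built eagerly and freed after the backward pass.
"""

from __future__ import annotations

import math
from typing import Callable, Sequence

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    """An array node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents", "name")

    def __init__(self, data, requires_grad: bool = False, name: str = ""):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward: Callable[[np.ndarray], None] | None = None
        self._parents: tuple[Tensor, ...] = ()
        self.name = name

    @property
    def shape(self):
        return self.data.shape

    def zero_grad(self):
        self.grad = None

    def _accumulate(self, grad: np.ndarray):
        if self.grad is None:
            self.grad = np.array(grad, dtype=np.float64, copy=True)
        else:
            self.grad += grad

    # -- operator sugar ---------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    def __radd__(self, other):
        return add(self, other)

    def __mul__(self, other):
        return mul(self, other)

    def __rmul__(self, other):
        return mul(self, other)

    def __sub__(self, other):
        return add(self, mul(other, -1.0))

    def __matmul__(self, other):
        return matmul(self, other)

    def __repr__(self):
        return f"Tensor(shape={self.shape}, grad={self.requires_grad}, name={self.name!r})"


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _node(
    data: np.ndarray,
    parents: Sequence[Tensor],
    backward: Callable[[np.ndarray], None],
) -> Tensor:
    out = Tensor(data)
    if any(p.requires_grad or p._parents for p in parents):
        out.requires_grad = any(p.requires_grad for p in parents)
        out._parents = tuple(parents)
        out._backward = backward
    return out


def backward(loss: Tensor):
    """Run reverse accumulation from a scalar ``loss``."""
    if loss.data.size != 1:
        raise ValueError("backward() requires a scalar")
    topo: list[Tensor] = []
    seen: set[int] = set()
    stack = [(loss, False)]
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
    grads: dict[int, np.ndarray] = {id(loss): np.ones_like(loss.data)}
    for node in reversed(topo):
        g = grads.pop(id(node), None)
        if g is None:
            continue
        if node.requires_grad:
            node._accumulate(g)
        if node._backward is not None:
            node._backward_into(g, grads)
    # free graph
    for node in topo:
        node._parents = ()
        node._backward = None


def _backward_into(self: Tensor, g: np.ndarray, grads: dict) -> None:
    partials = self._backward(g)
    for parent, pg in zip(self._parents, partials):
        if pg is None or (not parent.requires_grad and not parent._parents):
            continue
        if id(parent) in grads:
            grads[id(parent)] += pg
        else:
            grads[id(parent)] = pg


Tensor._backward_into = _backward_into  # type: ignore[attr-defined]


# ---------------------------------------------------------------------------
# primitive operations

def add(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data + b.data

    def bw(g):
        return _unbroadcast(g, a.shape), _unbroadcast(g, b.shape)

    return _node(out_data, (a, b), bw)


def mul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data * b.data

    def bw(g):
        return (
            _unbroadcast(g * b.data, a.shape),
            _unbroadcast(g * a.data, b.shape),
        )

    return _node(out_data, (a, b), bw)


def matmul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data @ b.data

    def bw(g):
        ga = g @ np.swapaxes(b.data, -1, -2)
        gb = np.swapaxes(a.data, -1, -2) @ g
        return _unbroadcast(ga, a.shape), _unbroadcast(gb, b.shape)

    return _node(out_data, (a, b), bw)


def reshape(a: Tensor, shape) -> Tensor:
    a = _as_tensor(a)
    out_data = a.data.reshape(shape)

    def bw(g):
        return (g.reshape(a.shape),)

    return _node(out_data, (a,), bw)


def transpose(a: Tensor, axes) -> Tensor:
    a = _as_tensor(a)
    inverse = np.argsort(axes)

    def bw(g):
        return (np.transpose(g, inverse),)

    return _node(np.transpose(a.data, axes), (a,), bw)


def tanh(a) -> Tensor:
    a = _as_tensor(a)
    t = np.tanh(a.data)

    def bw(g):
        return (g * (1.0 - t * t),)

    return _node(t, (a,), bw)


def relu(a) -> Tensor:
    a = _as_tensor(a)
    mask = a.data > 0

    def bw(g):
        return (g * mask,)

    return _node(a.data * mask, (a,), bw)


_GELU_C = math.sqrt(2.0 / math.pi)


def gelu(a) -> Tensor:
    """tanh-approximation GELU."""
    a = _as_tensor(a)
    x = a.data
    inner = _GELU_C * (x + 0.044715 * x**3)
    t = np.tanh(inner)
    out_data = 0.5 * x * (1.0 + t)

    def bw(g):
        d_inner = _GELU_C * (1.0 + 3 * 0.044715 * x**2)
        grad = 0.5 * (1.0 + t) + 0.5 * x * (1.0 - t * t) * d_inner
        return (g * grad,)

    return _node(out_data, (a,), bw)


def sigmoid(a) -> Tensor:
    a = _as_tensor(a)
    s = 1.0 / (1.0 + np.exp(-a.data))

    def bw(g):
        return (g * s * (1.0 - s),)

    return _node(s, (a,), bw)


def softmax(a: Tensor, additive_mask: np.ndarray | None = None) -> Tensor:
    """Softmax over the last axis, optionally after adding a constant mask."""
    a = _as_tensor(a)
    z = a.data if additive_mask is None else a.data + additive_mask
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=-1, keepdims=True)

    def bw(g):
        dot = (g * p).sum(axis=-1, keepdims=True)
        return (p * (g - dot),)

    return _node(p, (a,), bw)


def layer_norm(a: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-12) -> Tensor:
    """Normalize over the last axis, then scale and shift."""
    a, gamma, beta = _as_tensor(a), _as_tensor(gamma), _as_tensor(beta)
    x = a.data
    mean = x.mean(axis=-1, keepdims=True)
    var = x.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x - mean) * inv
    out_data = xhat * gamma.data + beta.data

    def bw(g):
        n = x.shape[-1]
        g_xhat = g * gamma.data
        g_x = (
            inv
            / n
            * (
                n * g_xhat
                - g_xhat.sum(axis=-1, keepdims=True)
                - xhat * (g_xhat * xhat).sum(axis=-1, keepdims=True)
            )
        )
        g_gamma = _unbroadcast(g * xhat, gamma.shape)
        g_beta = _unbroadcast(g, beta.shape)
        return g_x, g_gamma, g_beta

    return _node(out_data, (a, gamma, beta), bw)


def embedding(ids: np.ndarray, weight: Tensor) -> Tensor:
    """Row lookup ``weight[ids]``; gradient scatters back into the table."""
    weight = _as_tensor(weight)
    ids = np.asarray(ids, dtype=np.int64)

    def bw(g):
        gw = np.zeros_like(weight.data)
        np.add.at(gw, ids.reshape(-1), g.reshape(-1, g.shape[-1]))
        return (gw,)

    return _node(weight.data[ids], (weight,), bw)


def dropout(a: Tensor, p: float, rng: np.random.Generator, training: bool) -> Tensor:
    if not training or p == 0.0:
        return a
    a = _as_tensor(a)
    keep = (rng.random(a.shape) >= p) / (1.0 - p)

    def bw(g):
        return (g * keep,)

    return _node(a.data * keep, (a,), bw)


def mean_all(a: Tensor) -> Tensor:
    a = _as_tensor(a)
    n = a.data.size

    def bw(g):
        return (np.full(a.shape, float(g) / n),)

    return _node(np.asarray(a.data.mean()), (a,), bw)


IGNORE_INDEX = -100


def cross_entropy_logits(
    logits: Tensor, labels: np.ndarray, ignore_index: int = IGNORE_INDEX
) -> Tensor:
    """Mean cross-entropy over positions whose label is not ``ignore_index``.

    ``logits`` has shape (..., V); ``labels`` the matching leading shape.
    Raises if every label is ignored (no gradient signal).
    """
    logits = _as_tensor(logits)
    labels = np.asarray(labels, dtype=np.int64)
    flat_logits = logits.data.reshape(-1, logits.data.shape[-1])
    flat_labels = labels.reshape(-1)
    active = flat_labels != ignore_index
    n_active = int(active.sum())
    if n_active == 0:
        raise ValueError("all labels are ignored: no prediction targets in batch")
    z = flat_logits - flat_logits.max(axis=-1, keepdims=True)
    logsumexp = np.log(np.exp(z).sum(axis=-1))
    picked = z[np.arange(len(flat_labels)), np.clip(flat_labels, 0, None)]
    losses = np.where(active, logsumexp - picked, 0.0)
    loss_val = losses.sum() / n_active

    def bw(g):
        p = np.exp(z - logsumexp[:, None])
        p[np.arange(len(flat_labels)), np.clip(flat_labels, 0, None)] -= 1.0
        p *= (active[:, None] * float(g)) / n_active
        return (p.reshape(logits.shape),)

    return _node(np.asarray(loss_val), (logits,), bw)


def binary_cross_entropy_logits(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean BCE from logits; labels in {0, 1}."""
    logits = _as_tensor(logits)
    y = np.asarray(labels, dtype=np.float64).reshape(logits.shape)
    x = logits.data
    # log(1 + exp(-|x|)) formulation, stable for large |x|
    losses = np.maximum(x, 0) - x * y + np.log1p(np.exp(-np.abs(x)))
    n = x.size

    def bw(g):
        s = 1.0 / (1.0 + np.exp(-x))
        return ((s - y) * (float(g) / n),)

    return _node(np.asarray(losses.mean()), (logits,), bw)


# ---------------------------------------------------------------------------
# parameters and modules

class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data, name: str = ""):
        super().__init__(data, requires_grad=True, name=name)


class Module:
    """Tiny module container: tracks parameters and submodules by attribute."""

    def __setattr__(self, key, value):
        object.__setattr__(self, key, value)

    def named_parameters(self, prefix: str = "") -> list[tuple[str, Parameter]]:
        out: list[tuple[str, Parameter]] = []
        for key, value in vars(self).items():
            name = f"{prefix}{key}"
            if isinstance(value, Parameter):
                out.append((name, value))
            elif isinstance(value, Module):
                out.extend(value.named_parameters(f"{name}."))
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        out.extend(item.named_parameters(f"{name}.{i}."))
                    elif isinstance(item, Parameter):
                        out.append((f"{name}.{i}", item))
        return out

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]):
        params = dict(self.named_parameters())
        missing = set(params) - set(state)
        if missing:
            raise KeyError(f"missing parameters in state dict: {sorted(missing)[:5]}")
        for name, p in params.items():
            if p.data.shape != state[name].shape:
                raise ValueError(f"shape mismatch for {name}")
            p.data = np.array(state[name], dtype=np.float64)


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        scale = 1.0 / math.sqrt(d_in)
        self.weight = Parameter(rng.uniform(-scale, scale, size=(d_in, d_out)))
        self.bias = Parameter(np.zeros(d_out))

    def __call__(self, x: Tensor) -> Tensor:
        return add(matmul(x, self.weight), self.bias)


class LayerNorm(Module):
    def __init__(self, dim: int):
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))

    def __call__(self, x: Tensor) -> Tensor:
        return layer_norm(x, self.gamma, self.beta)
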