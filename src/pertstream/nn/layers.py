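"""Neural layers built on the :mod:`pertstream.nn.tensor` engine."""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, softmax

__all__ = [
    "Module",
    "Linear",
    "LayerNorm",
    "MultiheadSelfAttention",
    "TransformerEncoderLayer",
    "normalized_adjacency",
]


class Module:
    """Base class: collects parameters from attributes and sub-modules."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        seen: set[int] = set()
        for value in vars(self).values():
            if isinstance(value, Tensor) and value.requires_grad:
                if id(value) not in seen:
                    seen.add(id(value))
                    params.append(value)
            elif isinstance(value, Module):
                for p in value.parameters():
                    if id(p) not in seen:
                        seen.add(id(p))
                        params.append(p)
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        for p in item.parameters():
                            if id(p) not in seen:
                                seen.add(id(p))
                                params.append(p)
        return params

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError("state size mismatch")
        for p, a in zip(params, arrays):
            p.data = np.asarray(a, dtype=np.float64).reshape(p.shape)


class Linear(Module):
    """Affine map x @ W + b with uniform(-1/sqrt(fan_in), ..) init."""

    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        bound = 1.0 / np.sqrt(in_dim)
        self.weight = Tensor(rng.uniform(-bound, bound, size=(in_dim, out_dim)), requires_grad=True)
        self.bias = Tensor(rng.uniform(-bound, bound, size=(out_dim,)), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered**2).mean(axis=-1, keepdims=True)
        return centered / (var + self.eps).sqrt() * self.gamma + self.beta


class MultiheadSelfAttention(Module):
    """Scaled dot-product self-attention with an additive mask.

    The mask is an (m, m) array added to QK^T/sqrt(d_k) before the softmax;
    entries of a large negative value suppress the corresponding pairs to
    (numerically exactly) zero weight.
    """

    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator):
        if dim % n_heads != 0:
            raise ValueError("n_heads must divide dim")
        self.dim = dim
        self.n_heads = n_heads
        self.head_dim = dim // n_heads
        self.wq = Linear(dim, dim, rng)
        self.wk = Linear(dim, dim, rng)
        self.wv = Linear(dim, dim, rng)
        self.wo = Linear(dim, dim, rng)

    def _split(self, x: Tensor, c: int, m: int) -> Tensor:
        return x.reshape(c, m, self.n_heads, self.head_dim).transpose(0, 2, 1, 3)

    def attention_weights(self, x: Tensor, mask: np.ndarray) -> np.ndarray:
        """Post-softmax weights, shape (c, heads, m, m); for inspection/tests."""
        return self._forward(x, mask)[1]

    def _forward(self, x: Tensor, mask: np.ndarray | None):
        c, m, _ = x.shape
        q = self._split(self.wq(x), c, m)
        k = self._split(self.wk(x), c, m)
        v = self._split(self.wv(x), c, m)
        scores = (q @ k.transpose(0, 1, 3, 2)) / np.sqrt(self.head_dim)
        if mask is not None:
            scores = scores + Tensor(mask)
        weights = softmax(scores, axis=-1)
        out = weights @ v
        out = out.transpose(0, 2, 1, 3).reshape(c, m, self.dim)
        return self.wo(out), weights.data

    def __call__(self, x: Tensor, mask: np.ndarray | None = None) -> Tensor:
        return self._forward(x, mask)[0]


class TransformerEncoderLayer(Module):
    """Pre-norm encoder block: x + MHA(LN(x)), then x + FFN(LN(x)).

    Pre-norm keeps the residual stream un-normalized, which both stabilizes
    optimization at small step budgets and lets additive signals (such as a
    perturbation embedding added at every position) pass straight through
    to downstream readouts.
    """

    def __init__(self, dim: int, n_heads: int, ff_dim: int, rng: np.random.Generator):
        self.attn = MultiheadSelfAttention(dim, n_heads, rng)
        self.norm1 = LayerNorm(dim)
        self.norm2 = LayerNorm(dim)
        self.ff1 = Linear(dim, ff_dim, rng)
        self.ff2 = Linear(ff_dim, dim, rng)

    def __call__(self, x: Tensor, mask: np.ndarray | None = None) -> Tensor:
        x = x + self.attn(self.norm1(x), mask)
        return x + self.ff2(self.ff1(self.norm2(x)).relu())


def normalized_adjacency(n_nodes: int, edges, node_index: dict) -> np.ndarray:
    """Symmetric-normalized adjacency with self-loops, D^-1/2 (A+I) D^-1/2.

    `edges` is an iterable of (u, v, weight); weights enter as |weight| since
    the normalization requires non-negative entries.  Undirected: both
    (u, v) and (v, u) are filled.
    """
    a = np.eye(n_nodes)
    for u, v, w in edges:
        i, j = node_index[u], node_index[v]
        if i == j:
            continue
        a[i, j] = abs(w)
        a[j, i] = abs(w)
    d = a.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(d)
    return a * inv_sqrt[:, None] * inv_sqrt[None, :]
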