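"""Minimal feed-forward building blocks with explicit reverse-mode gradients.

The entity-relation model is a small multitask network: embedding tables,
per-entity MLPs (tanh preceded by layer normalization), pairwise bilinear
relation heads, and a bilinear feature mixer for side information.  All of it
runs on NumPy; every module exposes a functional ``forward(...) -> (out, cache)``
and a ``backward(cache, grad_out) -> grad_in`` that accumulates parameter
gradients in place, which keeps training bit-reproducible on one thread.
"""

from __future__ import annotations

import numpy as np
from scipy import sparse as sp

__all__ = [
    "Param",
    "Embedding",
    "Linear",
    "LayerNorm",
    "DenseBlock",
    "MLP",
    "PairBilinear",
    "FeatureMixer",
    "RelationHead",
]


class Param:
    """A trainable array together with its accumulated gradient."""

    __slots__ = ("name", "value", "grad")

    def __init__(self, name: str, value: np.ndarray):
        self.name = name
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0

    def __repr__(self) -> str:  # pragma: no cover
        return f"Param({self.name}, shape={self.value.shape})"


def _fan_in_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    # uniform(-1/sqrt(fan_in), 1/sqrt(fan_in)), the standard dense-layer default
    bound = 1.0 / np.sqrt(max(fan_in, 1))
    return rng.uniform(-bound, bound, size=shape)


class Module:
    """Base: a named container of Params (recursively collected)."""

    def params(self) -> list[Param]:
        out: list[Param] = []
        for v in self.__dict__.values():
            if isinstance(v, Param):
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.params())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.params())
                    elif isinstance(item, Param):
                        out.append(item)
        return out


class Embedding(Module):
    """Lookup table of per-instance trainable vectors."""

    def __init__(self, name: str, n: int, dim: int, rng: np.random.Generator):
        # unit-variance rows: strong enough to break the symmetric saddle when
        # an auxiliary self-relation must split entities into activity clusters
        self.weight = Param(f"{name}.emb", rng.normal(0.0, 1.0, size=(n, dim)))

    @property
    def shape(self) -> tuple[int, int]:
        return self.weight.value.shape

    def forward(self, idx: np.ndarray):
        idx = np.asarray(idx, dtype=np.intp)
        return self.weight.value[idx], idx

    def backward(self, cache: np.ndarray, grad: np.ndarray) -> None:
        np.add.at(self.weight.grad, cache, grad)


class Linear(Module):
    def __init__(self, name: str, d_in: int, d_out: int, rng: np.random.Generator, bias: bool = True):
        self.W = Param(f"{name}.W", _fan_in_init(rng, (d_in, d_out), d_in))
        self.b = Param(f"{name}.b", _fan_in_init(rng, (d_out,), d_in)) if bias else None

    def forward(self, x: np.ndarray):
        y = x @ self.W.value
        if self.b is not None:
            y = y + self.b.value
        return y, x

    def backward(self, cache: np.ndarray, grad: np.ndarray) -> np.ndarray:
        x = cache
        self.W.grad += x.T @ grad
        if self.b is not None:
            self.b.grad += grad.sum(axis=0)
        return grad @ self.W.value.T


class LayerNorm(Module):
    """Per-sample normalization over the feature axis with learned gain/shift."""

    def __init__(self, name: str, dim: int, eps: float = 1e-5):
        self.gain = Param(f"{name}.gain", np.ones(dim))
        self.shift = Param(f"{name}.shift", np.zeros(dim))
        self.eps = eps

    def forward(self, x: np.ndarray):
        mu = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv
        y = xhat * self.gain.value + self.shift.value
        return y, (xhat, inv)

    def backward(self, cache, grad: np.ndarray) -> np.ndarray:
        xhat, inv = cache
        d = xhat.shape[-1]
        self.gain.grad += (grad * xhat).sum(axis=0)
        self.shift.grad += grad.sum(axis=0)
        g = grad * self.gain.value
        # standard layer-norm backward
        return inv * (g - g.mean(axis=-1, keepdims=True) - xhat * (g * xhat).mean(axis=-1, keepdims=True))


def _tanh_forward(x):
    y = np.tanh(x)
    return y, y


def _tanh_backward(cache, grad):
    return grad * (1.0 - cache * cache)


class DenseBlock(Module):
    """Linear -> (optional LayerNorm) -> activation.

    The default configuration follows the published architecture: tanh
    activations preceded by layer normalization.  ``activation='identity'``
    together with ``norm=False`` yields a plain affine map, which is what the
    linear-limit (classical matrix factorization) configuration uses.
    """

    def __init__(self, name, d_in, d_out, rng, activation="tanh", norm=True, bias=True):
        if activation not in ("tanh", "identity"):
            raise ValueError(f"unknown activation {activation!r}")
        self.lin = Linear(name + ".lin", d_in, d_out, rng, bias=bias)
        self.norm = LayerNorm(name + ".ln", d_out) if norm else None
        self.activation = activation

    def forward(self, x):
        y, c_lin = self.lin.forward(x)
        c_norm = None
        if self.norm is not None:
            y, c_norm = self.norm.forward(y)
        c_act = None
        if self.activation == "tanh":
            y, c_act = _tanh_forward(y)
        return y, (c_lin, c_norm, c_act)

    def backward(self, cache, grad):
        c_lin, c_norm, c_act = cache
        if self.activation == "tanh":
            grad = _tanh_backward(c_act, grad)
        if self.norm is not None:
            grad = self.norm.backward(c_norm, grad)
        return self.lin.backward(c_lin, grad)


class MLP(Module):
    """Stack of DenseBlocks; depth 0 is the identity map."""

    def __init__(self, name, d_in, width, depth, rng, activation="tanh", norm=True):
        self.blocks = []
        d = d_in
        for i in range(depth):
            self.blocks.append(DenseBlock(f"{name}.{i}", d, width, rng, activation=activation, norm=norm))
            d = width
        self.d_out = d

    def forward(self, x):
        caches = []
        for blk in self.blocks:
            x, c = blk.forward(x)
            caches.append(c)
        return x, caches

    def backward(self, caches, grad):
        for blk, c in zip(reversed(self.blocks), reversed(caches)):
            grad = blk.backward(c, grad)
        return grad


class PairBilinear(Module):
    """Affine bilinear pair mixing: h_k = u^T W_k v (+ A_k.u + B_k.v + b_k).

    The linear terms make the stage the full [u;1]^T W [v;1] form, so single-
    side (entity-level) effects are representable alongside the interaction -
    a pure product form cannot express "this drug is generally active"
    independently of its partner.  ``linear_terms=False`` (with ``bias=False``)
    recovers the pure product used in the classical-MF limit.
    """

    def __init__(self, name, d_u, d_v, d_out, rng, bias=True, linear_terms=True):
        self.W = Param(f"{name}.W", _fan_in_init(rng, (d_out, d_u, d_v), d_u * d_v))
        self.A = Param(f"{name}.A", _fan_in_init(rng, (d_u, d_out), d_u)) if linear_terms else None
        self.B = Param(f"{name}.B", _fan_in_init(rng, (d_v, d_out), d_v)) if linear_terms else None
        self.b = Param(f"{name}.b", np.zeros(d_out)) if bias else None

    def forward(self, u: np.ndarray, v: np.ndarray):
        k, du_, dv_ = self.W.value.shape
        # T[b, k, i] = W[k, i, :] . v[b, :]; h = sum_i T[b, k, i] u[b, i]
        T = (v @ self.W.value.reshape(k * du_, dv_).T).reshape(-1, k, du_)
        h = np.einsum("bki,bi->bk", T, u)
        if self.A is not None:
            h = h + u @ self.A.value + v @ self.B.value
        if self.b is not None:
            h = h + self.b.value
        return h, (u, v, T)

    def backward(self, cache, grad):
        u, v, T = cache
        k, du_, dv_ = self.W.value.shape
        # M[b, (k i)] = grad[b, k] u[b, i]
        M = (grad[:, :, None] * u[:, None, :]).reshape(-1, k * du_)
        self.W.grad += (M.T @ v).reshape(k, du_, dv_)
        if self.b is not None:
            self.b.grad += grad.sum(axis=0)
        du = np.einsum("bk,bki->bi", grad, T)
        dv = M @ self.W.value.reshape(k * du_, dv_)
        if self.A is not None:
            self.A.grad += u.T @ grad
            self.B.grad += v.T @ grad
            du = du + grad @ self.A.value.T
            dv = dv + grad @ self.B.value.T
        return du, dv


class FeatureMixer(Module):
    """Bilinear combination of an embedding row with a per-instance feature
    vector, producing a vector of the entity's latent width.

    Sparse feature matrices (CSR) are consumed without densification: the
    contraction against the feature axis is a sparse-dense product.
    No bias term, so an all-zero feature row contributes exactly nothing.
    """

    def __init__(self, name, d_emb, d_feat, d_out, rng):
        self.W = Param(f"{name}.W", _fan_in_init(rng, (d_out, d_emb, d_feat), d_emb * d_feat))
        self.d_out = d_out

    def forward(self, e: np.ndarray, x):
        k, de, df = self.W.value.shape
        # P[b, k, d] = sum_f x[b, f] W[k, d, f]
        Wflat = self.W.value.reshape(k * de, df)
        P = (x @ Wflat.T)
        P = np.asarray(P).reshape(-1, k, de)
        out = np.einsum("bkd,bd->bk", P, e, optimize=True)
        return out, (e, x, P)

    def backward(self, cache, grad):
        e, x, P = cache
        k, de, df = self.W.value.shape
        de_grad = np.einsum("bk,bkd->bd", grad, P, optimize=True)
        # dW[k,d,f] = sum_b grad[b,k] e[b,d] x[b,f]
        M = (grad[:, :, None] * e[:, None, :]).reshape(-1, k * de)
        if sp.issparse(x):
            dW = np.asarray((x.T @ M)).T
        else:
            dW = M.T @ x
        self.W.grad += dW.reshape(k, de, df)
        return de_grad  # features are data, not parameters


class RelationHead(Module):
    """Relation module M_ij: bilinear stage, then a small FF head.

    Default: bilinear output width 10, head of 2 tanh/layer-norm layers of 10
    neurons, final affine projection to one raw score per pair.  With
    ``pure_bilinear=True`` the module degenerates to score = u^T W v, the
    classical-MF limit used for the linear-equivalence check.
    """

    def __init__(self, name, d_u, d_v, rng, bilinear_dim=10, head_depth=2,
                 head_width=10, activation="tanh", norm=True, pure_bilinear=False):
        self.pure_bilinear = pure_bilinear
        if pure_bilinear:
            self.bilinear = PairBilinear(name + ".bil", d_u, d_v, 1, rng,
                                         bias=False, linear_terms=False)
            self.head = None
            self.out = None
        else:
            self.bilinear = PairBilinear(name + ".bil", d_u, d_v, bilinear_dim, rng, bias=True)
            self.head = MLP(name + ".head", bilinear_dim, head_width, head_depth, rng,
                            activation=activation, norm=norm)
            self.out = Linear(name + ".out", self.head.d_out, 1, rng)

    def forward(self, u, v):
        h, c_bil = self.bilinear.forward(u, v)
        if self.pure_bilinear:
            return h[:, 0], (c_bil, None, None)
        h, c_head = self.head.forward(h)
        s, c_out = self.out.forward(h)
        return s[:, 0], (c_bil, c_head, c_out)

    def backward(self, cache, grad):
        c_bil, c_head, c_out = cache
        g = np.asarray(grad)[:, None]
        if not self.pure_bilinear:
            g = self.out.backward(c_out, g)
            g = self.head.backward(c_head, g)
        return self.bilinear.backward(c_bil, g)
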