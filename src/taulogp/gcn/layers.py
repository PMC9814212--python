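"""Graph-network building blocks on plain numpy arrays.

Stateless functional ops (graph_conv, graph_pool) plus layer classes that
carry parameters and hand-written backward passes. A minibatch of molecule
graphs is packed into one disjoint graph (see :func:`build_batch`); all ops
are permutation-equivariant over atoms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.sparse as sp


# ---------------------------------------------------------------------------
# batch packing
# ---------------------------------------------------------------------------


@dataclass
class GraphBatch:
    """Disjoint union of molecule graphs.

    ``adjacency`` is the symmetric 0/1 atom adjacency; ``nbr_padded`` holds,
    per atom, [self, neighbors..., self-padding] for max pooling;
    ``membership`` is the (n_graphs x n_atoms) gather matrix.
    """

    node_features: np.ndarray
    adjacency: sp.csr_matrix
    nbr_padded: np.ndarray
    membership: sp.csr_matrix
    graph_sizes: np.ndarray

    @property
    def n_graphs(self) -> int:
        return int(self.membership.shape[0])


def neighbor_adjacency(neighbor_lists: Sequence[np.ndarray], n_atoms: int | None = None) -> sp.csr_matrix:
    n = n_atoms if n_atoms is not None else len(neighbor_lists)
    rows, cols = [], []
    for i, nbrs in enumerate(neighbor_lists):
        for j in nbrs:
            rows.append(i)
            cols.append(int(j))
    data = np.ones(len(rows), dtype=np.float64)
    return sp.csr_matrix((data, (rows, cols)), shape=(n, n))


def pad_neighbors(neighbor_lists: Sequence[np.ndarray]) -> np.ndarray:
    """(n_atoms, 1 + max_degree) index array: slot 0 is the atom itself,
    remaining slots are neighbors, padded with the atom's own index."""
    n = len(neighbor_lists)
    k = 1 + max((len(nb) for nb in neighbor_lists), default=0)
    out = np.empty((n, k), dtype=np.int64)
    for i, nbrs in enumerate(neighbor_lists):
        out[i, :] = i
        out[i, 1 : 1 + len(nbrs)] = nbrs
    return out


def build_batch(features_list) -> GraphBatch:
    """Pack per-molecule :class:`~taulogp.featurize.GraphFeatures` into one
    disjoint graph with atom indices offset per molecule."""
    xs, nbr_all = [], []
    sizes = []
    offset = 0
    for gf in features_list:
        xs.append(gf.node_features.astype(np.float64))
        for nbrs in gf.neighbor_lists:
            nbr_all.append(np.asarray(nbrs, dtype=np.int64) + offset)
        sizes.append(gf.n_atoms)
        offset += gf.n_atoms
    n_atoms = offset
    x = np.concatenate(xs, axis=0) if xs else np.zeros((0, 0))
    adj = neighbor_adjacency(nbr_all, n_atoms)
    nbrp = pad_neighbors(nbr_all)
    rows = np.repeat(np.arange(len(sizes)), sizes)
    member = sp.csr_matrix(
        (np.ones(n_atoms), (rows, np.arange(n_atoms))), shape=(len(sizes), n_atoms)
    )
    return GraphBatch(
        node_features=x,
        adjacency=adj,
        nbr_padded=nbrp,
        membership=member,
        graph_sizes=np.asarray(sizes, dtype=np.int64),
    )


# ---------------------------------------------------------------------------
# functional ops
# ---------------------------------------------------------------------------


def graph_conv(x, adjacency, w_self, w_nbr, b):
    """h'_v = W_self h_v + sum_{u in N(v)} W_nbr h_u + b (pre-activation)."""
    if x.shape[1] != w_self.shape[0]:
        raise ValueError(f"graph_conv: width mismatch {x.shape[1]} vs {w_self.shape[0]}")
    return x @ w_self + (adjacency @ x) @ w_nbr + b


def graph_pool(x, nbr_padded):
    """Elementwise max over {v} union N(v); returns (pooled, argmax-slot)."""
    cand = x[nbr_padded]  # (n, k, f)
    arg = cand.argmax(axis=1)
    return cand.max(axis=1), arg


# ---------------------------------------------------------------------------
# layers with parameters / backward passes
# ---------------------------------------------------------------------------


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


class GraphConvLayer:
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        self.params = {
            "w_self": _glorot(rng, in_dim, out_dim),
            "w_nbr": _glorot(rng, in_dim, out_dim),
            "b": np.zeros(out_dim),
        }
        self.grads: dict[str, np.ndarray] = {}
        self._cache = None

    def forward(self, x, adjacency):
        ax = adjacency @ x
        self._cache = (x, ax, adjacency)
        return graph_conv(x, adjacency, self.params["w_self"], self.params["w_nbr"], self.params["b"])

    def backward(self, dz):
        x, ax, adjacency = self._cache
        self.grads = {
            "w_self": x.T @ dz,
            "w_nbr": ax.T @ dz,
            "b": dz.sum(axis=0),
        }
        # adjacency is symmetric, so A^T = A
        return dz @ self.params["w_self"].T + adjacency @ (dz @ self.params["w_nbr"].T)


class DenseLayer:
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        self.params = {"w": _glorot(rng, in_dim, out_dim), "b": np.zeros(out_dim)}
        self.grads: dict[str, np.ndarray] = {}
        self._x = None

    def forward(self, x):
        self._x = x
        return x @ self.params["w"] + self.params["b"]

    def backward(self, dz):
        self.grads = {"w": self._x.T @ dz, "b": dz.sum(axis=0)}
        return dz @ self.params["w"].T


class BatchNormLayer:
    """Per-feature batch normalization with running statistics at inference."""

    def __init__(self, dim: int, momentum: float = 0.9, eps: float = 1e-5):
        self.params = {"gamma": np.ones(dim), "beta": np.zeros(dim)}
        self.grads: dict[str, np.ndarray] = {}
        self.running_mean = np.zeros(dim)
        self.running_var = np.ones(dim)
        self.n_updates = 0
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    def _running_stats(self):
        # bias-corrected exponential averages (Adam-style), so short training
        # runs still get usable inference statistics
        if self.n_updates == 0:
            return self.running_mean, self.running_var
        corr = 1.0 - self.momentum**self.n_updates
        return self.running_mean / corr, self.running_var / corr

    def forward(self, x, training: bool):
        if training and x.shape[0] > 1:
            mean = x.mean(axis=0)
            var = x.var(axis=0)
            if self.n_updates == 0:
                self.running_mean = np.zeros_like(mean)
                self.running_var = np.zeros_like(var)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
            self.n_updates += 1
        else:
            mean, var = self._running_stats()
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv
        self._cache = (xhat, inv, training and x.shape[0] > 1)
        return self.params["gamma"] * xhat + self.params["beta"]

    def backward(self, dy):
        xhat, inv, batch_stats = self._cache
        self.grads = {"gamma": (dy * xhat).sum(axis=0), "beta": dy.sum(axis=0)}
        dxhat = dy * self.params["gamma"]
        if not batch_stats:
            return dxhat * inv
        n = xhat.shape[0]
        return (inv / n) * (n * dxhat - dxhat.sum(axis=0) - xhat * (dxhat * xhat).sum(axis=0))


class ReluOp:
    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dy):
        return np.where(self._mask, dy, 0.0)


class GraphPoolOp:
    def forward(self, x, nbr_padded):
        out, arg = graph_pool(x, nbr_padded)
        self._cache = (nbr_padded, arg, x.shape)
        return out

    def backward(self, dy):
        nbr_padded, arg, shape = self._cache
        dx = np.zeros(shape)
        n, f = shape
        src = np.take_along_axis(nbr_padded, arg, axis=1)  # (n, f): source atom per output cell
        cols = np.broadcast_to(np.arange(f), (n, f))
        np.add.at(dx, (src, cols), dy)
        return dx


class GatherSumOp:
    """Atom-to-molecule sum via the membership matrix."""

    def forward(self, x, membership):
        self._membership = membership
        return membership @ x

    def backward(self, dy):
        return self._membership.T @ dy


class DropoutOp:
    def __init__(self, p: float):
        self.p = p

    def forward(self, x, training: bool, rng: np.random.Generator | None):
        if not training or self.p <= 0:
            self._mask = None
            return x
        self._mask = (rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class Adam:
    """Adaptive-moment SGD over a flat {name: array} parameter mapping."""

    def __init__(self, lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        for name, g in grads.items():
            if name not in self.m:
                self.m[name] = np.zeros_like(g)
                self.v[name] = np.zeros_like(g)
            self.m[name] = self.beta1 * self.m[name] + (1 - self.beta1) * g
            self.v[name] = self.beta2 * self.v[name] + (1 - self.beta2) * g * g
            mhat = self.m[name] / (1 - self.beta1**self.t)
            vhat = self.v[name] / (1 - self.beta2**self.t)
            params[name] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
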