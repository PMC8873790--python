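"""Graclus-style multilevel graph coarsening and binary-tree max pooling.

Greedy normalized-cut matching: nodes are visited in a seeded random order
and each unmarked node merges with the unmarked neighbor maximizing
w_ij (1/d_i + 1/d_j); leftovers become singletons.  After `n_levels`
rounds, fake (zero-degree) nodes pad every cluster chain into a balanced
binary tree, and a permutation of the level-0 nodes places each parent's
two children next to each other, so pooling a graph signal reduces to
non-overlapping 1-D max pooling of size 2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, maxpool_blocks, pad_permute, tensor


@dataclass
class CoarseningHierarchy:
    """Coarsened graphs plus the bookkeeping that enables 1-D pooling."""

    graphs: list  # padded+permuted adjacency per level (level 0 = finest)
    cluster_maps: list  # per-level parent assignment over *real* nodes
    perms: list  # per-level permutation: position -> real node id or -1 (fake)
    n_real: list  # number of real nodes at each level
    masks: list  # per-level boolean mask over padded positions, True = real

    @property
    def permutation(self) -> np.ndarray:
        return self.perms[0]

    @property
    def n_fake(self) -> int:
        return int((self.perms[0] < 0).sum())

    @property
    def n_levels(self) -> int:
        return len(self.cluster_maps)

    def padded_size(self, level: int = 0) -> int:
        return len(self.perms[level])


def _match_level(W: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One round of greedy normalized-cut matching; returns parent ids."""
    N = W.shape[0]
    degree = W.sum(axis=1)  # includes collapsed self-weight on the diagonal
    parents = -np.ones(N, dtype=int)
    marked = np.zeros(N, dtype=bool)
    next_cluster = 0
    for i in rng.permutation(N):
        if marked[i]:
            continue
        marked[i] = True
        # candidate neighbors: positive off-diagonal weight, unmarked
        weights = W[i].copy()
        weights[i] = 0.0
        cand = np.flatnonzero((weights > 0) & ~marked)
        best = -1
        if cand.size:
            di = degree[i] if degree[i] > 0 else 1.0
            dj = np.where(degree[cand] > 0, degree[cand], 1.0)
            score = weights[cand] * (1.0 / di + 1.0 / dj)
            top = score.max()
            best = int(cand[score >= top - 1e-15].min())  # tie -> lowest index
        parents[i] = next_cluster
        if best >= 0:
            marked[best] = True
            parents[best] = next_cluster
        next_cluster += 1
    return parents


def _coarsen_weights(W: np.ndarray, parents: np.ndarray) -> np.ndarray:
    """Sum merged edges; intra-cluster weight accumulates on the diagonal."""
    n_coarse = parents.max() + 1
    M = np.zeros((len(parents), n_coarse))
    M[np.arange(len(parents)), parents] = 1.0
    return M.T @ W @ M


def _compute_perms(cluster_maps: list, n_coarsest: int) -> list:
    """Sibling-adjacent orderings with fake-node padding, coarsest level down.

    Returns one ordering per level (finest first); entries are real node
    ids or fake ids >= the level's real count.
    """
    orders = [list(range(n_coarsest))]
    for parents in reversed(cluster_maps):
        n_real = len(parents)
        fake_id = n_real
        layer = []
        for parent in orders[-1]:
            children = list(np.flatnonzero(parents == parent)) if parent < parents.max() + 1 else []
            while len(children) < 2:
                children.append(fake_id)
                fake_id += 1
            layer.extend(children)
        orders.append(layer)
    return orders[::-1]


def graclus_coarsen(
    A: np.ndarray, n_levels: int, seed: int = 0
) -> CoarseningHierarchy:
    """Coarsen `A` for `n_levels` rounds of pairwise merging."""
    A = np.asarray(A, dtype=float)
    if np.abs(A - A.T).max() > 1e-12 or (A < 0).any():
        raise ValueError("adjacency must be symmetric and nonnegative")
    if 2**n_levels > A.shape[0]:
        raise ValueError(
            f"{n_levels} levels need at least {2 ** n_levels} nodes, got {A.shape[0]}"
        )
    rng = np.random.default_rng(seed)
    W = A.copy()
    raw_graphs = [W]
    cluster_maps = []
    for _ in range(n_levels):
        parents = _match_level(W, rng)
        cluster_maps.append(parents)
        W = _coarsen_weights(W, parents)
        raw_graphs.append(W)

    n_real = [g.shape[0] for g in raw_graphs]
    perms = [np.asarray(p) for p in _compute_perms(cluster_maps, n_real[-1])]
    graphs, masks = [], []
    for W, perm, nr in zip(raw_graphs, perms, n_real):
        mask = perm < nr
        padded = np.zeros((len(perm), len(perm)))
        idx = perm[mask]
        padded[np.ix_(mask, mask)] = W[np.ix_(idx, idx)]
        np.fill_diagonal(padded, 0.0)  # collapsed self-weight is not an edge
        graphs.append(padded)
        masks.append(mask)
    # normalize fake entries to -1
    perms = [np.where(p < nr, p, -1) for p, nr in zip(perms, n_real)]
    return CoarseningHierarchy(graphs, cluster_maps, perms, n_real, masks)


def permute_signal(x, hierarchy: CoarseningHierarchy) -> Tensor:
    """Place real node values at their permuted positions, zeros at fakes.

    `x` is (batch, n_real, channels); zeros at fake positions are safe for
    max pooling because all pooled activations are softplus outputs > 0.
    """
    x = tensor(x)
    if x.shape[1] != hierarchy.n_real[0]:
        raise ValueError(
            f"signal has {x.shape[1]} nodes, hierarchy expects {hierarchy.n_real[0]}"
        )
    return pad_permute(x, hierarchy.perms[0])


def inverse_permute(x: np.ndarray, hierarchy: CoarseningHierarchy) -> np.ndarray:
    """Recover original node order from a padded, permuted (B, n, f) array."""
    perm = hierarchy.perms[0]
    real = perm >= 0
    out = np.empty((x.shape[0], hierarchy.n_real[0], x.shape[2]), dtype=x.dtype)
    out[:, perm[real], :] = x[:, real, :]
    return out


def graph_maxpool(x, pool_size: int) -> Tensor:
    """1-D max over consecutive `pool_size` blocks of the node axis."""
    return maxpool_blocks(tensor(x), pool_size)


def cluster_max_oracle(
    x: np.ndarray, parents: np.ndarray
) -> np.ndarray:
    """Brute-force per-cluster max over real nodes (test reference)."""
    n_coarse = parents.max() + 1
    out = np.full((x.shape[0], n_coarse, x.shape[2]), -np.inf)
    for node, p in enumerate(parents):
        out[:, p, :] = np.maximum(out[:, p, :], x[:, node, :])
    return out
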