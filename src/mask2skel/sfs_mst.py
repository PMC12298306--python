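"""Projection of a soft adjacency matrix onto a minimum-spanning-tree graph.

The optimizer keeps the topology soft (a matrix of edge probabilities), but
the rendered structural prior and the final output must be actual trees. The
selective-suppression projection here computes the maximum-probability
spanning tree (MST under weights -log A_ij), zeroes every other entry, and
lets gradients pass straight through the retained entries. Because the mask
is an MST by construction, every projected graph is connected and acyclic —
the 100% tree-rate guarantee is structural, not statistical.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.special import expit

__all__ = ["TreeProjection", "hard_mst", "sfs_project", "is_tree"]


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.parent[rb] = ra
        return True


def hard_mst(weights: np.ndarray) -> np.ndarray:
    """Kruskal MST of the complete graph given a symmetric weight matrix.

    Returns a boolean K x K edge mask with K-1 edges. Ties are broken
    deterministically: lower weight first, then lexicographic (i, j).
    """
    w = np.asarray(weights, dtype=float)
    k = w.shape[0]
    if w.shape != (k, k):
        raise ValueError("weights must be square")
    mask = np.zeros((k, k), dtype=bool)
    if k <= 1:
        return mask
    iu, ju = np.triu_indices(k, 1)
    wu = w[iu, ju]
    if not np.all(np.isfinite(wu)):
        raise ValueError("hard_mst requires finite weights")
    order = np.lexsort((ju, iu, wu))  # weight, then i, then j
    uf = _UnionFind(k)
    taken = 0
    for idx in order:
        i, j = int(iu[idx]), int(ju[idx])
        if uf.union(i, j):
            mask[i, j] = mask[j, i] = True
            taken += 1
            if taken == k - 1:
                break
    return mask


@dataclass
class TreeProjection:
    """MST-masked adjacency: probabilities on the spanning edges, zero off."""

    adjacency_mst: np.ndarray  # K x K in [0, 1]
    edge_mask: np.ndarray  # boolean K x K

    def edges(self) -> list[tuple[int, int]]:
        ii, jj = np.where(np.triu(self.edge_mask, 1))
        return list(zip(ii.tolist(), jj.tolist()))


def sfs_project(adjacency_logits: np.ndarray, positions: np.ndarray | None = None,
                weight_mode: str = "neglog") -> TreeProjection:
    """Project soft adjacency logits onto their maximum-probability spanning
    tree.

    ``weight_mode='neglog'`` uses w_ij = -log(sigmoid(logit_ij)), so the MST
    is the spanning tree with the largest product of edge probabilities.
    ``weight_mode='euclidean'`` uses inter-node distances (matching the
    initialization) and requires ``positions``.

    Gradients flow through retained entries only: A_mst = sigmoid(logits) on
    the mask, exactly zero elsewhere (suppressed entries receive no gradient
    from this path).
    """
    logits = np.asarray(adjacency_logits, dtype=float)
    a = expit(logits)
    np.fill_diagonal(a, 0.0)
    if weight_mode == "neglog":
        with np.errstate(divide="ignore"):
            w = -np.log(np.clip(a, 1e-300, 1.0))
        if positions is not None:
            # probabilities pinned at the parameterization bounds are exact
            # ties; an infinitesimal distance term orders those ties by the
            # geometric prior without ever overriding a probability gap
            p = np.asarray(positions)
            diff = p[:, None, :] - p[None, :, :]
            dist = np.sqrt((diff ** 2).sum(axis=2))
            diag = dist.max() or 1.0
            w = w + 1e-4 * dist / diag
    elif weight_mode == "euclidean":
        if positions is None:
            raise ValueError("euclidean weight mode requires positions")
        diff = np.asarray(positions)[:, None, :] - np.asarray(positions)[None, :, :]
        w = np.sqrt((diff ** 2).sum(axis=2))
    else:
        raise ValueError(f"unknown weight_mode {weight_mode!r}")
    mask = hard_mst(w)
    return TreeProjection(adjacency_mst=np.where(mask, a, 0.0), edge_mask=mask)


def is_tree(graph_or_mask) -> bool:
    """True iff the edge set is connected and has exactly K-1 edges.

    Accepts a SkeletonGraph (edges at probability > 0.5), a boolean edge-mask
    matrix, or an (edge list, node count) pair.
    """
    if hasattr(graph_or_mask, "adjacency_logits"):
        k = graph_or_mask.n_nodes
        edges = graph_or_mask.edges()
    elif isinstance(graph_or_mask, tuple):
        edges, k = graph_or_mask
    else:
        m = np.asarray(graph_or_mask)
        k = m.shape[0]
        ii, jj = np.where(np.triu(m, 1))
        edges = list(zip(ii.tolist(), jj.tolist()))
    g = nx.Graph()
    g.add_nodes_from(range(k))
    g.add_edges_from(edges)
    if k == 0:
        return False
    return g.number_of_edges() == k - 1 and nx.is_connected(g)
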