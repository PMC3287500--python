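"""Neighbor-joining guide trees for progressive alignment.

The dendrogram fixes the order in which sequences (and pre-aligned groups)
are merged.  Joining follows the five-step neighbor-joining procedure:
net-divergence ``r_i = sum_j D_ij / (m - 2)``, join the pair minimising
``M_ij = D_ij - r_i - r_j``, assign branch lengths
``d_iu = D_ij / 2 + (r_i - r_j) / 2`` and ``d_ju = D_ij - d_iu``, then
collapse the pair into a new node.  The default distance update is the
standard Saitou–Nei ``D_vu = (D_iv + D_jv - D_ij) / 2``; ``paper_literal``
switches to the unhalved form ``D_vu = D_iv + D_jv - D_ij``.  Ties on
``M_ij`` resolve to the smallest label pair, and the procedure always
performs exactly ``m - 1`` merges, rooting the tree at the final join.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .errors import InputError

__all__ = [
    "DistanceMatrix",
    "TreeNode",
    "GuideTree",
    "nj_build",
    "distances_from_scores",
]


@dataclass
class DistanceMatrix:
    """A symmetric non-negative m x m distance matrix with node labels."""

    D: np.ndarray
    labels: list

    def __post_init__(self):
        self.D = np.asarray(self.D, dtype=float)
        m = self.D.shape[0]
        if self.D.shape != (m, m) or m != len(self.labels):
            raise InputError("distance matrix shape/label mismatch")
        if m < 2:
            raise InputError("need at least 2 nodes")
        if not np.allclose(self.D, self.D.T):
            raise InputError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.D), 0):
            raise InputError("distance matrix diagonal must be zero")
        if (self.D < -1e-12).any():
            raise InputError("distances must be non-negative")


@dataclass
class TreeNode:
    """One node of the guide tree; leaves carry a label, internals two kids."""

    label: str
    children: tuple = ()
    branch_lengths: tuple = ()  # lengths to each child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self):
        if self.is_leaf:
            yield self
        else:
            for ch in self.children:
                yield from ch.leaves()

    def newick(self, lengths: bool = True) -> str:
        def rec(node, blen):
            if node.is_leaf:
                core = node.label
            else:
                inner = ",".join(
                    rec(ch, bl)
                    for ch, bl in zip(node.children, node.branch_lengths)
                )
                core = f"({inner})"
            if lengths and blen is not None:
                return f"{core}:{blen:.6g}"
            return core

        return rec(self, None) + ";"


@dataclass
class GuideTree:
    """Binary dendrogram over the input sequences with its merge order."""

    root: TreeNode
    merge_order: list  # (left TreeNode, right TreeNode, new TreeNode)

    def newick(self, lengths: bool = True) -> str:
        return self.root.newick(lengths)

    def leaf_labels(self) -> list:
        return [leaf.label for leaf in self.root.leaves()]


def nj_build(dm: DistanceMatrix, paper_literal: bool = False) -> GuideTree:
    """Neighbor joining with exactly ``m - 1`` merges.

    With two active nodes the pair joins directly with half the distance on
    each branch (net divergence is undefined at m = 2).  The output tree
    has ``2m - 1`` nodes.
    """
    nodes = {i: TreeNode(str(lab)) for i, lab in enumerate(dm.labels)}
    order_key = {i: i for i in nodes}  # creation order for tie-breaking
    D = {
        (i, j): float(dm.D[i, j])
        for i in range(len(dm.labels))
        for j in range(len(dm.labels))
    }
    active = sorted(nodes)
    next_id = len(dm.labels)
    merges = []
    while len(active) > 1:
        if len(active) == 2:
            i, j = sorted(active, key=order_key.get)
            dij = D[(i, j)]
            diu = dju = dij / 2
        else:
            mm = len(active)
            r = {
                a: sum(D[(a, b)] for b in active if b != a) / (mm - 2)
                for a in active
            }
            best = None
            for a, b in combinations(sorted(active, key=order_key.get), 2):
                M = D[(a, b)] - r[a] - r[b]
                if best is None or M < best[0] - 1e-12:
                    best = (M, a, b)
            _, i, j = best
            dij = D[(i, j)]
            diu = dij / 2 + (r[i] - r[j]) / 2
            dju = dij - diu
        new = TreeNode(
            f"n{next_id}", (nodes[i], nodes[j]), (diu, dju)
        )
        nodes[next_id] = new
        order_key[next_id] = next_id
        merges.append((nodes[i], nodes[j], new))
        for v in active:
            if v in (i, j):
                continue
            if paper_literal:
                dvu = D[(i, v)] + D[(j, v)] - D[(i, j)]
            else:
                dvu = (D[(i, v)] + D[(j, v)] - D[(i, j)]) / 2
            D[(next_id, v)] = D[(v, next_id)] = max(dvu, 0.0)
        D[(next_id, next_id)] = 0.0
        active = [v for v in active if v not in (i, j)] + [next_id]
        next_id += 1
    return GuideTree(nodes[active[0]], merges)


def distances_from_scores(S: np.ndarray, labels=None) -> DistanceMatrix:
    """Turn a pairwise similarity-score matrix into distances.

    ``D_ij = max(S) - S_ij`` off the diagonal (so the best-scoring pair is
    the closest) and ``D_ii = 0``.  Monotone decreasing in similarity.
    """
    S = np.asarray(S, dtype=float)
    m = S.shape[0]
    if labels is None:
        labels = [str(i) for i in range(m)]
    D = S.max() - S
    np.fill_diagonal(D, 0.0)
    D = (D + D.T) / 2  # guard against asymmetric float input
    return DistanceMatrix(D, list(labels))
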