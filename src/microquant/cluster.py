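"""Complete-linkage clustering of samples and dendrogram comparison.

Samples (rows of a samples x taxa log10 matrix) are clustered by
complete-linkage agglomeration on Euclidean distances. Two dendrograms
over the same samples — e.g. one from absolute and one from inferred
concentrations — are compared with the entanglement coefficient: number
the shared labels by the order they appear along each tree's leaves, take
the Euclidean distance between the two position vectors, and normalise by
the worst case (one order the exact reverse of the other). 0 means the
leaf orders agree perfectly, 1 a complete mismatch.

Leaf order is not determined by the merge tree alone, so a fixed seriation
rule makes it reproducible: at every merge the subtree containing the
lexicographically smallest label is drawn on the left.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cophenet, fcluster, linkage
from scipy.spatial.distance import pdist
from sklearn.metrics import silhouette_score

__all__ = ["Dendrogram", "cluster_samples", "entanglement", "choose_k",
           "TanglegramResult", "compare_dendrograms"]


@dataclass
class Dendrogram:
    """Agglomerative merge history with deterministic leaf order."""

    linkage_matrix: np.ndarray     # scipy (n-1) x 4 format
    labels: list[str]              # label per original observation index
    leaf_order: list[str]          # labels in drawing order (seriated)

    @property
    def merge_heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]

    def cophenetic_heights(self) -> np.ndarray:
        return cophenet(self.linkage_matrix)

    def cut(self, k: int) -> np.ndarray:
        return fcluster(self.linkage_matrix, k, criterion="maxclust")

    def to_newick(self) -> str:
        n = len(self.labels)
        Z = self.linkage_matrix

        def node(i, parent_h):
            if i < n:
                return f"{self.labels[i]}:{parent_h:.6g}"
            row = Z[i - n]
            h = row[2]
            left, right = _ordered_children(int(row[0]), int(row[1]), n, Z, self.labels)
            return f"({node(left, h)},{node(right, h)}):{max(parent_h - h, 0.0):.6g}"

        root = n + len(Z) - 1
        row = Z[-1]
        left, right = _ordered_children(int(row[0]), int(row[1]), n, Z, self.labels)
        h = row[2]
        return f"({node(left, h)},{node(right, h)});"


def _subtree_min_label(i, n, Z, labels, cache):
    if i in cache:
        return cache[i]
    if i < n:
        out = labels[i]
    else:
        a, b = int(Z[i - n, 0]), int(Z[i - n, 1])
        out = min(_subtree_min_label(a, n, Z, labels, cache),
                  _subtree_min_label(b, n, Z, labels, cache))
    cache[i] = out
    return out


def _ordered_children(a, b, n, Z, labels, cache=None):
    cache = cache if cache is not None else {}
    if (_subtree_min_label(a, n, Z, labels, cache)
            <= _subtree_min_label(b, n, Z, labels, cache)):
        return a, b
    return b, a


def _seriate(Z, labels) -> list[str]:
    """Leaf order with the smallest-label subtree drawn left at every merge."""
    n = len(labels)
    cache: dict[int, str] = {}
    order: list[str] = []

    def walk(i):
        if i < n:
            order.append(labels[i])
            return
        a, b = _ordered_children(int(Z[i - n, 0]), int(Z[i - n, 1]), n, Z, labels, cache)
        walk(a)
        walk(b)

    import sys
    old = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old, 2 * n + 100))
    try:
        walk(n + len(Z) - 1)
    finally:
        sys.setrecursionlimit(old)
    return order


def cluster_samples(matrix, labels=None, method="complete",
                    metric="euclidean") -> Dendrogram:
    """Complete-linkage hierarchical clustering of sample rows.

    ``matrix`` is samples x features (DataFrame rows become labels unless
    ``labels`` is given). Deterministic: scipy's agglomeration order plus
    the fixed seriation rule.
    """
    if isinstance(matrix, pd.DataFrame):
        if labels is None:
            labels = [str(i) for i in matrix.index]
        matrix = matrix.to_numpy(dtype=float)
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 samples")
    if not np.all(np.isfinite(matrix)):
        raise ValueError("matrix contains NaN or infinite values")
    if labels is None:
        labels = [str(i) for i in range(matrix.shape[0])]
    if len(set(labels)) != len(labels):
        raise ValueError("labels must be unique")
    Z = linkage(matrix, method=method, metric=metric)
    return Dendrogram(Z, list(labels), _seriate(Z, list(labels)))


def entanglement(d1: Dendrogram, d2: Dendrogram) -> float:
    """Normalized Euclidean distance between the two trees' leaf-position vectors.

    Positions are 1-based ranks of each shared label along the leaf order;
    the normaliser is the distance attained when one order is the exact
    reverse of the other. Identical leaf orders give 0, reversed orders 1.
    """
    if set(d1.leaf_order) != set(d2.leaf_order):
        raise ValueError("dendrograms must share an identical label set")
    labels = sorted(d1.leaf_order)
    pos1 = {lab: i + 1 for i, lab in enumerate(d1.leaf_order)}
    pos2 = {lab: i + 1 for i, lab in enumerate(d2.leaf_order)}
    u = np.array([pos1[lab] for lab in labels], dtype=float)
    v = np.array([pos2[lab] for lab in labels], dtype=float)
    n = len(labels)
    worst = np.linalg.norm(np.arange(1, n + 1) - np.arange(n, 0, -1))
    if worst == 0:
        return 0.0
    return float(np.linalg.norm(u - v) / worst)


@dataclass
class TanglegramResult:
    d1: Dendrogram
    d2: Dendrogram
    entanglement: float


def compare_dendrograms(d1: Dendrogram, d2: Dendrogram,
                        optimize_rotation=False) -> TanglegramResult:
    """Entanglement between two dendrograms over the same samples.

    ``optimize_rotation`` enables a one-pass greedy search that flips the
    children of each merge of the first tree whenever the flip lowers the
    entanglement (a sensitivity analysis; the plain coefficient uses the
    fixed seriation order).
    """
    if not optimize_rotation:
        return TanglegramResult(d1, d2, entanglement(d1, d2))
    best = d1
    best_e = entanglement(d1, d2)
    n = len(d1.labels)
    for m in range(len(d1.linkage_matrix)):
        flipped = _flip_merge(best, m, n)
        e = entanglement(flipped, d2)
        if e < best_e:
            best, best_e = flipped, e
    return TanglegramResult(best, d2, best_e)


def _flip_merge(dendro: Dendrogram, merge_index: int, n: int) -> Dendrogram:
    """Leaf order with the two subtrees of one merge swapped."""
    Z = dendro.linkage_matrix

    def leaves(i):
        if i < n:
            return [dendro.labels[i]]
        a, b = int(Z[i - n, 0]), int(Z[i - n, 1])
        return leaves(a) + leaves(b)

    a, b = int(Z[merge_index, 0]), int(Z[merge_index, 1])
    la, lb = leaves(a), leaves(b)
    order = dendro.leaf_order
    block = la + lb if _first_index(order, la) < _first_index(order, lb) else lb + la
    swapped = (block[len(la):] + block[: len(la)]
               if block[: len(la)] == la else block[len(lb):] + block[: len(lb)])
    i0 = min(order.index(x) for x in block)
    new_order = order[:i0] + swapped + order[i0 + len(block):]
    return Dendrogram(Z, dendro.labels, new_order)


def _first_index(order, labs):
    return min(order.index(x) for x in labs)


def choose_k(dendro: Dendrogram, matrix, k_range=range(2, 9)) -> int:
    """Cluster count maximising mean silhouette width over tree cuts.

    A single silhouette-based selector (not a multi-index majority vote).
    """
    if isinstance(matrix, pd.DataFrame):
        matrix = matrix.to_numpy(dtype=float)
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape[0] <= min(k_range):
        raise ValueError("fewer samples than the smallest candidate k")
    if np.all(pdist(matrix) == 0):
        raise ValueError("degenerate input: all samples identical")
    best_k, best_s = None, -np.inf
    for k in k_range:
        if k >= matrix.shape[0]:
            break
        assign = dendro.cut(k)
        if len(np.unique(assign)) < 2:
            continue
        s = silhouette_score(matrix, assign, metric="euclidean")
        if s > best_s:
            best_k, best_s = k, s
    if best_k is None:
        raise ValueError("no valid cut produced >= 2 clusters")
    return int(best_k)
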