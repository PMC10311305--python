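"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written as plain loops over exported
data structures, sharing no code path with the package implementation.
"""

from __future__ import annotations

import numpy as np


def bruteforce_knn(points: np.ndarray, k: int) -> list[list[int]]:
    """k nearest neighbors per point by exhaustive pairwise sort.

    Self excluded; ties broken by point index.
    """
    c = len(points)
    out = []
    for i in range(c):
        dists = []
        for j in range(c):
            if j == i:
                continue
            d = float(np.sqrt(((points[i] - points[j]) ** 2).sum()))
            dists.append((d, j))
        dists.sort()
        out.append([j for _, j in dists[:k]])
    return out


def bruteforce_knn_consistency(points: np.ndarray, types: np.ndarray, k: int) -> float:
    """Double-loop evaluation of the neighbor-consistency fraction."""
    c = len(points)
    total = 0
    for i, nbrs in enumerate(bruteforce_knn(points, k)):
        for j in nbrs:
            if types[i] == types[j]:
                total += 1
    return total / (c * k)


def oracle_gini(counts) -> float:
    w = sum(counts)
    return 1.0 - sum((x / w) ** 2 for x in counts)


def oracle_node_importance(node) -> float:
    """Eq-style impurity decrease recomputed from a SplitNode record."""
    w = sum(node.class_counts)
    wl = sum(node.left.class_counts)
    wr = sum(node.right.class_counts)
    return (
        w * oracle_gini(node.class_counts)
        - wl * oracle_gini(node.left.class_counts)
        - wr * oracle_gini(node.right.class_counts)
    )


def oracle_tree_importance(tree, g: int) -> np.ndarray:
    """Recompute the normalized per-gene importance of one exported tree
    by recursive traversal of its node table."""
    per_gene = [0.0] * g
    total = [0.0]

    def visit(node):
        if node.gene is None:
            return
        n = oracle_node_importance(node)
        per_gene[node.gene] += n
        total[0] += n
        visit(node.left)
        visit(node.right)

    visit(tree.root)
    if total[0] <= 0:
        return np.zeros(g)
    return np.array(per_gene) / total[0]


def oracle_forest_importance(trees, g: int) -> np.ndarray:
    """Mean of per-tree oracle importances."""
    acc = np.zeros(g)
    for t in trees:
        acc += oracle_tree_importance(t, g)
    return acc / len(trees)


def oracle_pearson(a: np.ndarray, b: np.ndarray) -> float:
    """Direct covariance / (sigma sigma) formula."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    cov = ((a - a.mean()) * (b - b.mean())).mean()
    sa = a.std()
    sb = b.std()
    if sa == 0 or sb == 0:
        return 0.0
    return cov / (sa * sb)


def oracle_redundancy_scan(
    genes: list[str],
    corr: dict[tuple[str, str], float],
    v: float,
    v_prime: float,
) -> tuple[list[str], list[str]]:
    """Step-by-step hand simulation of the sequential pruning scan.

    ``corr`` maps unordered gene-id pairs to their correlation. Returns
    (survivors, removed). The threshold is recomputed at each anchor
    from the number of surviving genes after it.
    """
    surviving = list(genes)
    removed = []
    pos = 0
    while pos < len(surviving):
        anchor = surviving[pos]
        L = len(surviving) - pos - 1
        h = v + v_prime / (L + 1)
        tail = []
        for gid in surviving[pos + 1 :]:
            key = (anchor, gid) if (anchor, gid) in corr else (gid, anchor)
            if corr[key] > h:
                removed.append(gid)
            else:
                tail.append(gid)
        surviving = surviving[: pos + 1] + tail
        pos += 1
    return surviving, removed
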