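"""Gene importance from a forest of label-guided decision trees.

Each tree is a CART classifier trained on *all* cells of the balanced
dataset (no bootstrap resampling — every tree sees the same labels);
gene randomization happens per split, where a random subset of genes
(default ceil(sqrt(g))) is drawn as split candidates, the canonical
random-forest rule. Trees are grown by best-Gini binary splits to
purity.

Importance is the classical mean-decrease-in-impurity statistic, computed
here explicitly from exported node tables:

* Gini impurity of a node:        I = 1 - sum_C p_C^2
* importance of an internal node: N = w I - w_l I_l - w_r I_r
  (w are absolute cell counts at the node and its children)
* per-tree gene importance:       f_i = sum_{a split on i} N_a / sum_b N_b
  over all internal nodes b, so each tree's vector sums to 1.

The forest importance of a gene is the average of its per-tree
importances over all trees (genes outside a tree's subspace contribute 0
for that tree), together with the mean mu and population standard
deviation sigma of the importance distribution used by the downstream
three-sigma cut.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.tree import DecisionTreeClassifier

from .balance import BalancedDataset

__all__ = [
    "SplitNode",
    "DecisionTree",
    "ImportanceVector",
    "gini_impurity",
    "node_importance",
    "tree_importance",
    "fit_forest_importance",
]


@dataclass
class SplitNode:
    """One node of a fitted binary decision tree.

    Internal nodes carry the split gene (a *global* gene index) and
    threshold; leaves have ``gene is None``. ``class_counts`` are the
    absolute per-cluster cell counts reaching the node.
    """

    class_counts: np.ndarray
    gene: int | None = None
    threshold: float | None = None
    left: "SplitNode | None" = None
    right: "SplitNode | None" = None

    @property
    def w(self) -> int:
        return int(self.class_counts.sum())

    @property
    def is_leaf(self) -> bool:
        return self.gene is None


@dataclass
class DecisionTree:
    """A fitted tree plus the gene subspace it was allowed to split on."""

    root: SplitNode
    gene_subspace: np.ndarray

    def internal_nodes(self) -> list[SplitNode]:
        out, stack = [], [self.root]
        while stack:
            node = stack.pop()
            if not node.is_leaf:
                out.append(node)
                stack.append(node.left)
                stack.append(node.right)
        return out


@dataclass
class ImportanceVector:
    """Forest-averaged per-gene importance with summary statistics."""

    f: np.ndarray
    n_trees: int
    mu: float = field(init=False)
    sigma: float = field(init=False)

    def __post_init__(self) -> None:
        self.f = np.asarray(self.f, dtype=float)
        if (self.f < 0).any():
            raise ValueError("importances must be non-negative")
        self.mu = float(self.f.mean())
        self.sigma = float(self.f.std())  # population std

    @property
    def n_genes(self) -> int:
        return self.f.size


def gini_impurity(class_counts: np.ndarray) -> float:
    """Gini impurity 1 - sum_C (count_C / w)^2 of a node."""
    counts = np.asarray(class_counts, dtype=float)
    if (counts < 0).any():
        raise ValueError("class counts must be non-negative")
    w = counts.sum()
    if w == 0:
        raise ValueError("node has no cells")
    p = counts / w
    return float(1.0 - np.dot(p, p))


def node_importance(node: SplitNode) -> float:
    """Impurity reduction N = w I - w_l I_l - w_r I_r of an internal node."""
    if node.is_leaf:
        raise ValueError("node importance is defined for internal nodes only")
    return (
        node.w * gini_impurity(node.class_counts)
        - node.left.w * gini_impurity(node.left.class_counts)
        - node.right.w * gini_impurity(node.right.class_counts)
    )


def tree_importance(t: DecisionTree, g: int) -> np.ndarray:
    """Per-gene normalized importance of one tree, length ``g``.

    ``f_i`` is the summed importance of the nodes split on gene ``i``
    divided by the total over all internal nodes; the vector sums to 1
    whenever any split reduces impurity. If no split reduces impurity
    the zero vector is returned with a warning.
    """
    internal = t.internal_nodes()
    if not internal:
        raise ValueError("tree has no internal node")
    f = np.zeros(g)
    total = 0.0
    for node in internal:
        n = node_importance(node)
        f[node.gene] += n
        total += n
    if total <= 0:
        warnings.warn("no impurity reduction anywhere in tree", stacklevel=2)
        return np.zeros(g)
    return f / total


def _export_tree(
    clf: DecisionTreeClassifier,
    x_sub: np.ndarray,
    y_enc: np.ndarray,
    subspace: np.ndarray,
) -> DecisionTree:
    """Rebuild an explicit node table from a fitted sklearn tree.

    Per-node class counts are recomputed from the decision paths of the
    training cells, so they are exact integers independent of how the
    library stores node values. Split feature indices are mapped from
    subspace-local to global gene indices.
    """
    tree = clf.tree_
    n_classes = clf.n_classes_
    csc = clf.decision_path(x_sub).tocsc()  # cells x nodes indicator
    counts = np.zeros((tree.node_count, n_classes), dtype=int)
    for node in range(tree.node_count):
        members = csc.indices[csc.indptr[node] : csc.indptr[node + 1]]
        counts[node] = np.bincount(y_enc[members], minlength=n_classes)

    def build(node_id: int) -> SplitNode:
        if tree.children_left[node_id] == -1:
            return SplitNode(class_counts=counts[node_id])
        return SplitNode(
            class_counts=counts[node_id],
            gene=int(subspace[tree.feature[node_id]]),
            threshold=float(tree.threshold[node_id]),
            left=build(tree.children_left[node_id]),
            right=build(tree.children_right[node_id]),
        )

    return DecisionTree(root=build(0), gene_subspace=np.asarray(subspace))


def _fit_one_tree(
    x: np.ndarray,
    y_enc: np.ndarray,
    max_features: int | None,
    tree_seed: int,
) -> DecisionTree:
    """Fit one CART tree on all cells with per-split gene sampling."""
    clf = DecisionTreeClassifier(
        criterion="gini",
        splitter="best",
        max_features=max_features,
        min_samples_leaf=1,
        random_state=tree_seed,
    )
    clf.fit(x, y_enc)
    return _export_tree(clf, x, y_enc, np.arange(x.shape[1]))


def _max_features(rule: str | int, g: int) -> int | None:
    if rule == "sqrt":
        return min(g, math.ceil(math.sqrt(g)))
    if rule == "all":
        return None
    size = int(rule)
    if not 1 <= size <= g:
        raise ValueError(f"subspace size {size} outside 1..{g}")
    return size


def fit_forest_importance(
    b: BalancedDataset,
    n_trees: int = 100,
    subspace: str | int = "sqrt",
    seed: int = 0,
    return_trees: bool = False,
) -> ImportanceVector | tuple[ImportanceVector, list[DecisionTree]]:
    """Forest-averaged Gini importance of every gene.

    Each of ``n_trees`` trees is fit on all cells; gene randomization is
    per split: at every node a random subset of ``subspace`` genes
    (``"sqrt"`` -> ceil(sqrt(g)), ``"all"`` -> every gene, or an
    explicit integer) is drawn as split candidates, so trees differ
    through the candidate draws while every gene remains visible to
    every tree. The forest importance is the mean of per-tree
    importance vectors. Deterministic given ``seed``.
    """
    labels = b.labels
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError("importance needs at least 2 clusters")
    # encode labels to 0..n-1 for bincounts in the node tables
    y_enc = np.searchsorted(uniq, labels)
    x = np.ascontiguousarray(b.values.T)  # cells x genes
    g = x.shape[1]
    mf = _max_features(subspace, g)
    rng = np.random.default_rng(seed)

    total = np.zeros(g)
    trees: list[DecisionTree] = []
    for _ in range(n_trees):
        tree = _fit_one_tree(x, y_enc, mf, tree_seed=int(rng.integers(2**31)))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            total += tree_importance(tree, g)
        if return_trees:
            trees.append(tree)
    imp = ImportanceVector(f=total / n_trees, n_trees=n_trees)
    if return_trees:
        return imp, trees
    return imp
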