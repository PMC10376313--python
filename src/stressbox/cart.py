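"""A personalized CART binary classifier built on a sorted Gini split.

The split search sorts each feature once and sweeps every candidate
boundary with prefix counts, so the class counts on both sides of any
cutoff come from O(1) arithmetic instead of re-partitioning the data.
For a boundary after sorted position c, with p0/p1 the class fractions on
a side, the impurity of a side is the product p0 * p1 and the score of
the boundary is the plain (unweighted) sum of the two sides' products —
the literal form of the sorted-split algorithm this tree implements.  A
``weighted`` variant using the classical size-weighted Gini
(n_side / n) * 2 * p0 * p1 is selectable for comparison.

The tree is grown recursively: at each node the best (feature, cutoff)
pair minimizes the split score, samples route left when x_i < theta, and
leaves predict the majority class of their training samples.  All
tie-breaks are deterministic (lowest boundary index, lowest feature
index, class 0), so two fits on the same data always agree.  Depth and
leaf-size limits stand in for pruning.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .errors import ParameterError, SchemaError
from .io_core import FeatureTable


@dataclass
class GiniSplitResult:
    """Outcome of the sorted split search on one feature."""

    gini: float
    cutoff_value: float
    cutoff_index: int
    feature_index: int = -1
    pure: bool = False  # single-class input: nothing to split
    valid: bool = True  # False when no boundary separates distinct values


def _side_impurity(n0: float, n1: float) -> float:
    n = n0 + n1
    if n == 0:
        return 0.0
    return (n0 / n) * (n1 / n)


def gini_split(
    values,
    labels,
    impurity: str = "paper",
    fixed_cutoff: Optional[float] = None,
) -> GiniSplitResult:
    """Best binary split of one feature by the sorted prefix-count sweep.

    ``impurity='paper'`` scores a boundary as the unweighted sum of the
    two sides' p0*p1 products; ``'weighted'`` uses the classical
    size-weighted Gini.  ``fixed_cutoff`` skips the sweep and scores the
    single boundary at that threshold (samples with value < cutoff go
    below).  Ties break toward the lowest boundary index.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if impurity not in ("paper", "weighted"):
        raise ParameterError(f"unknown impurity form {impurity!r}")
    if values.ndim != 1 or values.shape != labels.shape:
        raise ParameterError("values and labels must be equal-length 1-D")
    n = len(values)
    if n < 2:
        raise ParameterError("need at least 2 samples to split")
    if not np.isin(labels, [0, 1]).all():
        raise SchemaError("labels must be binary (0/1)")

    if labels.min() == labels.max():
        return GiniSplitResult(0.0, float("nan"), -1, pure=True, valid=False)

    order = np.argsort(values, kind="stable")
    sv = values[order]
    sl = labels[order]
    total1 = int(sl.sum())
    total0 = n - total1

    if fixed_cutoff is not None:
        n_below = int(np.sum(sv < fixed_cutoff))
        if n_below == 0 or n_below == n:
            return GiniSplitResult(
                _side_impurity(total0, total1), float(fixed_cutoff), n_below,
                valid=False,
            )
        boundaries = np.asarray([n_below - 1])
    else:
        distinct = sv[:-1] < sv[1:]
        boundaries = np.nonzero(distinct)[0]  # boundary after sorted index c
        if boundaries.size == 0:
            return GiniSplitResult(
                _side_impurity(total0, total1), float("nan"), -1, valid=False
            )

    cum1 = np.cumsum(sl)
    n1_below = cum1[boundaries].astype(float)
    n_below = boundaries + 1.0
    n0_below = n_below - n1_below
    n1_above = total1 - n1_below
    n_above = n - n_below
    n0_above = n_above - n1_above

    g_below = (n0_below / n_below) * (n1_below / n_below)
    g_above = (n0_above / n_above) * (n1_above / n_above)
    if impurity == "paper":
        totals = g_below + g_above
    else:
        totals = (n_below / n) * 2.0 * g_below + (n_above / n) * 2.0 * g_above

    best = int(np.argmin(totals))  # argmin takes the first (lowest) index on ties
    c = int(boundaries[best])
    cutoff = float(fixed_cutoff) if fixed_cutoff is not None else float(sv[c + 1])
    return GiniSplitResult(
        gini=float(totals[best]),
        cutoff_value=cutoff,
        cutoff_index=c + 1,
    )


@dataclass
class CartNode:
    """Internal node (feature/threshold/children) or leaf (label/counts)."""

    counts: tuple[int, int]  # class 0 / class 1 training counts at this node
    label: int
    feature_index: int = -1
    threshold: float = float("nan")
    left: Optional["CartNode"] = None
    right: Optional["CartNode"] = None

    @property
    def is_leaf(self) -> bool:
        return self.left is None

    def to_dict(self) -> dict:
        d = {"counts": list(self.counts), "label": self.label}
        if not self.is_leaf:
            d.update(
                feature_index=self.feature_index,
                threshold=self.threshold,
                left=self.left.to_dict(),
                right=self.right.to_dict(),
            )
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CartNode":
        node = cls(counts=tuple(d["counts"]), label=d["label"])
        if "left" in d:
            node.feature_index = d["feature_index"]
            node.threshold = d["threshold"]
            node.left = cls.from_dict(d["left"])
            node.right = cls.from_dict(d["right"])
        return node


@dataclass
class CartTree:
    root: CartNode
    n_features: int
    max_depth: int
    min_samples_leaf: int
    feature_names: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "kind": "cart",
            "n_features": self.n_features,
            "max_depth": self.max_depth,
            "min_samples_leaf": self.min_samples_leaf,
            "feature_names": self.feature_names,
            "root": self.root.to_dict(),
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "CartTree":
        return cls(
            root=CartNode.from_dict(payload["root"]),
            n_features=payload["n_features"],
            max_depth=payload["max_depth"],
            min_samples_leaf=payload["min_samples_leaf"],
            feature_names=list(payload.get("feature_names", [])),
        )

    def depth(self) -> int:
        def _d(node: CartNode) -> int:
            if node.is_leaf:
                return 0
            return 1 + max(_d(node.left), _d(node.right))

        return _d(self.root)


def _majority(y: np.ndarray) -> tuple[int, tuple[int, int]]:
    n1 = int(y.sum())
    n0 = len(y) - n1
    return (1 if n1 > n0 else 0), (n0, n1)  # tie -> class 0


def _grow(
    x: np.ndarray,
    y: np.ndarray,
    depth: int,
    max_depth: int,
    min_leaf: int,
    impurity: str,
) -> CartNode:
    label, counts = _majority(y)
    node = CartNode(counts=counts, label=label)
    if depth >= max_depth or counts[0] == 0 or counts[1] == 0:
        return node

    best: Optional[tuple[float, float, int]] = None  # (score, cutoff, feature)
    for j in range(x.shape[1]):
        res = gini_split(x[:, j], y, impurity=impurity)
        if not res.valid and not res.pure:
            continue
        if res.pure:
            continue
        mask = x[:, j] < res.cutoff_value
        if mask.sum() < min_leaf or (~mask).sum() < min_leaf:
            continue
        cand = (res.gini, res.cutoff_value, j)
        if best is None or (cand[0], cand[2], cand[1]) < (best[0], best[2], best[1]):
            best = cand
    if best is None:
        return node

    _, theta, j = best
    mask = x[:, j] < theta
    node.feature_index = j
    node.threshold = theta
    node.left = _grow(x[mask], y[mask], depth + 1, max_depth, min_leaf, impurity)
    node.right = _grow(x[~mask], y[~mask], depth + 1, max_depth, min_leaf, impurity)
    return node


def build_tree(
    table: FeatureTable,
    max_depth: int = 5,
    min_samples_leaf: int = 1,
    impurity: str = "paper",
) -> CartTree:
    """Grow a CART tree on a binary-labeled feature table."""
    if table.labels is None:
        raise SchemaError("building a tree requires labels")
    y = np.asarray(table.labels)
    if not np.isin(y, [0, 1]).all():
        raise SchemaError("CART handles binary labels only")
    if table.n_samples < 1:
        raise ParameterError("need at least one sample")
    root = _grow(table.values, y, 0, max_depth, min_samples_leaf, impurity)
    return CartTree(
        root=root,
        n_features=table.n_features,
        max_depth=max_depth,
        min_samples_leaf=min_samples_leaf,
        feature_names=list(table.feature_names),
    )


def predict(tree: CartTree, x) -> int:
    """Route one feature vector root-to-leaf (left iff x_i < theta)."""
    x = np.asarray(x, dtype=float)
    if x.shape != (tree.n_features,):
        raise SchemaError(
            f"expected {tree.n_features} features, got {x.shape}"
        )
    node = tree.root
    while not node.is_leaf:
        node = node.left if x[node.feature_index] < node.threshold else node.right
    return node.label


def predict_many(tree: CartTree, x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return np.asarray([predict(tree, row) for row in x], dtype=int)


class CartClassifier(BaseEstimator, ClassifierMixin):
    """Scikit-learn-compatible front end for the CART tree.

    Lets the personalized tree plug into cross-validation, pipelines and
    grid search alongside the comparison classifiers.
    """

    def __init__(self, max_depth: int = 5, min_samples_leaf: int = 1, impurity: str = "paper"):
        self.max_depth = max_depth
        self.min_samples_leaf = min_samples_leaf
        self.impurity = impurity

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        names = [f"f{j}" for j in range(X.shape[1])]
        table = FeatureTable(names, X, y, "binary")
        self.tree_ = build_tree(
            table, self.max_depth, self.min_samples_leaf, self.impurity
        )
        self.classes_ = np.asarray([0, 1])
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        return predict_many(self.tree_, np.asarray(X, dtype=float))
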