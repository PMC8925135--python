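"""Class-weighted CART over boolean recurrence indicators.

Greedy recursive binary partitioning minimising the Gini impurity
``1 - sum_k p_k^2``, where the class proportions ``p_k`` are computed on
observation weights: every recurrent-class observation carries weight ``w``
(the false-negative cost knob) and every non-recurrent observation weight 1.
Sweeping ``w`` yields the three operating points of practical interest —
``w = 4`` leans the tree toward flagging every true recurrence (high
sensitivity), ``w = 0.5`` toward only flagging sure cases (high PPV), and
``w = 1`` balances the two (high overall accuracy).

Because the features are all binary there are no split thresholds and no
scores to re-threshold afterwards; the class weight enters both the split
criterion and the leaf majority vote, which is what differentiates the
three trees.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

RECURRENT = "recurrent"
NON_RECURRENT = "non_recurrent"

#: Preset false-negative cost weights for the three operating points.
OPERATING_POINTS = {"high_sensitivity": 4.0, "high_accuracy": 1.0, "high_ppv": 0.5}


def gini_impurity(weighted_counts: Sequence[float]) -> float:
    """Gini impurity ``1 - sum_k p_k^2`` of a node from per-class weighted counts.

    For two classes the value lies in ``[0, 0.5]``: 0 for a pure node, 0.5
    for a 50/50 split. Raises on an empty node.
    """
    counts = np.asarray(weighted_counts, dtype=float)
    if (counts < 0).any():
        raise ValueError("class counts must be non-negative")
    total = counts.sum()
    if total <= 0:
        raise ValueError("gini_impurity undefined for an empty node")
    p = counts / total
    return float(1.0 - (p ** 2).sum())


def _node_counts(labels: np.ndarray, weights: np.ndarray) -> tuple[float, float]:
    return float(weights[labels].sum()), float(weights[~labels].sum())


def split_gain(column: np.ndarray, labels: np.ndarray,
               weights: Optional[np.ndarray] = None) -> float:
    """Impurity decrease of splitting a node on one boolean indicator.

    Parent Gini minus the weight-averaged Gini of the yes/no children;
    non-negative, and exactly 0 for a constant column.
    """
    column = np.asarray(column, dtype=bool)
    labels = np.asarray(labels, dtype=bool)
    if column.shape != labels.shape:
        raise ValueError(f"shape mismatch: column {column.shape} vs labels {labels.shape}")
    if weights is None:
        weights = np.ones(labels.shape, dtype=float)
    weights = np.asarray(weights, dtype=float)

    total = weights.sum()
    parent = gini_impurity(_node_counts(labels, weights))
    gain = parent
    for mask in (column, ~column):
        w_side = weights[mask].sum()
        if w_side == 0:
            continue
        child = gini_impurity(_node_counts(labels[mask], weights[mask]))
        gain -= (w_side / total) * child
    return max(float(gain), 0.0)


# ---------------------------------------------------------------------------
# tree structure

@dataclass
class Leaf:
    label: str  # RECURRENT or NON_RECURRENT

    def is_leaf(self) -> bool:
        return True


@dataclass
class Node:
    indicator: str
    yes: Union["Node", Leaf]
    no: Union["Node", Leaf]

    def is_leaf(self) -> bool:
        return False


@dataclass
class DecisionTree:
    """An induced tree plus the indicator column order it was fitted on."""
    root: Union[Node, Leaf]
    feature_names: list[str]

    def depth(self) -> int:
        def _d(n) -> int:
            return 0 if n.is_leaf() else 1 + max(_d(n.yes), _d(n.no))
        return _d(self.root)

    def indicators_used(self) -> set[str]:
        used: set[str] = set()

        def _walk(n):
            if not n.is_leaf():
                used.add(n.indicator)
                _walk(n.yes)
                _walk(n.no)
        _walk(self.root)
        return used

    # -- serialization ------------------------------------------------------

    def to_text(self) -> str:
        lines: list[str] = []

        def _emit(n, indent: int, prefix: str):
            pad = "  " * indent
            if n.is_leaf():
                lines.append(f"{pad}{prefix}[{n.label}]")
            else:
                lines.append(f"{pad}{prefix}{n.indicator}?")
                _emit(n.yes, indent + 1, "yes: ")
                _emit(n.no, indent + 1, "no: ")
        _emit(self.root, 0, "")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str, feature_names: Optional[Sequence[str]] = None
                  ) -> "DecisionTree":
        rows = [(len(ln) - len(ln.lstrip()), ln.strip())
                for ln in text.splitlines() if ln.strip()]
        pos = 0

        def _parse(indent: int):
            nonlocal pos
            depth, line = rows[pos]
            body = line.split(": ", 1)[1] if ": " in line else line
            pos += 1
            if body.startswith("["):
                label = body.strip("[]")
                if label not in (RECURRENT, NON_RECURRENT):
                    raise ValueError(f"unknown leaf label {label!r}")
                return Leaf(label)
            if not body.endswith("?"):
                raise ValueError(f"malformed tree line: {line!r}")
            name = body[:-1]
            yes = _parse(depth + 2)
            no = _parse(depth + 2)
            return Node(name, yes, no)

        root = _parse(0)
        if pos != len(rows):
            raise ValueError("trailing content in tree text")
        names = list(feature_names) if feature_names is not None else sorted(
            cls(root, []).indicators_used())
        return cls(root, names)


# ---------------------------------------------------------------------------
# estimator

class GiniTreeClassifier(BaseEstimator, ClassifierMixin):
    """CART-style decision tree for boolean indicators with a class-weight knob.

    Parameters
    ----------
    max_depth : int, default 5
        Maximum number of indicator tests on any root-to-leaf path.
    min_leaf : int, default 10
        A split is rejected when either child would hold fewer than this many
        observations (raw counts, not weighted).
    fn_cost_weight : float, default 1.0
        Observation weight given to recurrent-class rows in both the Gini
        criterion and the leaf majority vote. Values above 1 trade PPV for
        sensitivity; below 1, the reverse.

    Attributes
    ----------
    tree_ : DecisionTree
        The induced rule structure.
    feature_names_in_ : list of str
        Indicator column order used for splitting and tie-breaking.

    Notes
    -----
    Splits maximise the weighted Gini gain; ties break toward the earliest
    column in ``feature_names_in_``, each indicator is tested at most once
    per path, and an exactly tied leaf vote goes to the recurrent class.
    """

    def __init__(self, max_depth: int = 5, min_leaf: int = 10,
                 fn_cost_weight: float = 1.0):
        self.max_depth = max_depth
        self.min_leaf = min_leaf
        self.fn_cost_weight = fn_cost_weight

    # -- fitting ------------------------------------------------------------

    def fit(self, X, y) -> "GiniTreeClassifier":
        if self.max_depth < 1 or self.min_leaf < 1:
            raise ValueError("max_depth and min_leaf must be >= 1")
        if not self.fn_cost_weight > 0:
            raise ValueError("fn_cost_weight must be positive")
        X, names = self._as_matrix(X)
        y = self._as_labels(y)
        if X.shape[0] == 0:
            raise ValueError("cannot fit a tree on an empty matrix")
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y disagree on the number of rows")
        self.feature_names_in_ = names
        weights = np.where(y, float(self.fn_cost_weight), 1.0)
        self.tree_ = DecisionTree(
            root=self._grow(X, y, weights, depth=0, available=list(range(len(names)))),
            feature_names=names)
        return self

    def _grow(self, X, y, w, depth, available):
        w_pos, w_neg = _node_counts(y, w)
        if w_pos == 0 or w_neg == 0 or depth >= self.max_depth or not available:
            return Leaf(self._vote(w_pos, w_neg))

        best_gain, best_col = 0.0, None
        for col in available:  # ascending column order => documented tie-break
            column = X[:, col]
            n_yes = int(column.sum())
            if n_yes < self.min_leaf or (len(column) - n_yes) < self.min_leaf:
                continue
            gain = split_gain(column, y, w)
            if gain > best_gain + 1e-12:
                best_gain, best_col = gain, col
        if best_col is None:
            return Leaf(self._vote(w_pos, w_neg))

        mask = X[:, best_col]
        remaining = [c for c in available if c != best_col]
        return Node(
            indicator=self.feature_names_in_[best_col],
            yes=self._grow(X[mask], y[mask], w[mask], depth + 1, remaining),
            no=self._grow(X[~mask], y[~mask], w[~mask], depth + 1, remaining),
        )

    @staticmethod
    def _vote(w_pos: float, w_neg: float) -> str:
        # exact tie goes to the recurrent class (favours sensitivity)
        return RECURRENT if w_pos >= w_neg else NON_RECURRENT

    # -- prediction ---------------------------------------------------------

    def predict(self, X) -> np.ndarray:
        labels, _ = self.predict_with_trigger(X)
        return labels

    def predict_with_trigger(self, X) -> tuple[np.ndarray, list[Optional[str]]]:
        """Labels plus, for each recurrent call, the triggering indicator —
        the last indicator on the decision path answered "present"."""
        if not hasattr(self, "tree_"):
            raise ValueError("classifier is not fitted")
        X, names = self._as_matrix(X, expect=self.feature_names_in_)
        col = {name: i for i, name in enumerate(names)}
        missing = self.tree_.indicators_used() - set(names)
        if missing:
            raise ValueError(f"indicator vector missing tested indicators: {sorted(missing)}")
        labels = np.zeros(X.shape[0], dtype=bool)
        triggers: list[Optional[str]] = []
        for i in range(X.shape[0]):
            node = self.tree_.root
            last_present: Optional[str] = None
            while not node.is_leaf():
                if X[i, col[node.indicator]]:
                    last_present = node.indicator
                    node = node.yes
                else:
                    node = node.no
            if node.label == RECURRENT:
                labels[i] = True
                triggers.append(last_present)
            else:
                triggers.append(None)
        return labels, triggers

    # -- plumbing -----------------------------------------------------------

    @staticmethod
    def _as_matrix(X, expect: Optional[list[str]] = None):
        if isinstance(X, pd.DataFrame):
            names = list(X.columns)
            mat = X.to_numpy(dtype=bool)
        else:
            mat = np.asarray(X, dtype=bool)
            if mat.ndim == 1:
                mat = mat.reshape(1, -1)
            names = (list(expect) if expect is not None
                     else [f"x{i}" for i in range(mat.shape[1])])
        if expect is not None and len(names) != len(expect):
            raise ValueError("feature count differs from the fitted matrix")
        return mat, names

    @staticmethod
    def _as_labels(y) -> np.ndarray:
        arr = np.asarray(y)
        if arr.dtype.kind in "US":
            return arr == RECURRENT
        return arr.astype(bool)


# ---------------------------------------------------------------------------
# functional wrappers

@dataclass
class TreeConfig:
    max_depth: int = 5
    min_leaf: int = 10
    fn_cost_weight: float = 1.0
    operating_points: dict = field(default_factory=lambda: dict(OPERATING_POINTS))


def fit_tree(indicator_matrix, labels, config: Optional[TreeConfig] = None) -> DecisionTree:
    config = config or TreeConfig()
    clf = GiniTreeClassifier(max_depth=config.max_depth, min_leaf=config.min_leaf,
                             fn_cost_weight=config.fn_cost_weight)
    return clf.fit(indicator_matrix, labels).tree_


def predict(tree: DecisionTree, indicator_vector: dict) -> tuple[str, Optional[str]]:
    """Follow one indicator vector (name -> bool) down a tree.

    Returns ``(label, triggering_indicator)``; the trigger is the last node
    answered "present" on the path, None for non-recurrent leaves.
    """
    missing = tree.indicators_used() - set(indicator_vector)
    if missing:
        raise ValueError(f"indicator vector missing tested indicators: {sorted(missing)}")
    node = tree.root
    last_present = None
    while not node.is_leaf():
        if bool(indicator_vector[node.indicator]):
            last_present = node.indicator
            node = node.yes
        else:
            node = node.no
    return node.label, (last_present if node.label == RECURRENT else None)


def fit_operating_points(indicator_matrix, labels, config: Optional[TreeConfig] = None,
                         ) -> dict[str, DecisionTree]:
    """Fit the three preset operating-point trees (high sensitivity,
    high accuracy, high PPV) on one indicator matrix."""
    config = config or TreeConfig()
    trees = {}
    for name, w in config.operating_points.items():
        point = TreeConfig(max_depth=config.max_depth, min_leaf=config.min_leaf,
                           fn_cost_weight=w)
        trees[name] = fit_tree(indicator_matrix, labels, point)
    return trees
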