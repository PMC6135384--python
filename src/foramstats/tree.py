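"""Univariate classification tree of cluster membership against
environmental predictors.

Greedy binary recursive partitioning: each node is split on the single
(variable, threshold) pair that maximally reduces the multinomial deviance

    D(node) = -2 * sum_k n_k * log(n_k / n)        (0 * log 0 = 0),

with candidate thresholds at midpoints between consecutive distinct sorted
predictor values and the rule "value <= threshold goes left".  Splitting
stops when a node is pure, smaller than ``min_node``, or when the best
achievable reduction falls below ``min_deviance_fraction`` of the root
deviance.  Ties between candidate splits are broken deterministically:
earlier predictor column first, then smaller threshold.

Because the tree is grown greedily without pruning it describes the training
configuration only; with island-constant predictors several variables can
induce identical partitions, so which variable labels a split can be a
tie-break artifact.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .io import ValidationError

__all__ = ["TreeNode", "grow_tree", "predict", "tree_to_text", "tree_to_json",
           "multinomial_deviance", "best_split", "leaves"]


@dataclass
class TreeNode:
    node_id: int
    deviance: float
    class_counts: dict
    predicted_class: object
    split_variable: str | None = None
    split_threshold: float | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.split_variable is None

    @property
    def n(self) -> int:
        return sum(self.class_counts.values())


def multinomial_deviance(labels) -> float:
    """-2 log-likelihood of the saturated-vs-node multinomial fit."""
    labels = list(labels)
    n = len(labels)
    if n == 0:
        return 0.0
    counts: dict = {}
    for y in labels:
        counts[y] = counts.get(y, 0) + 1
    return -2.0 * sum(k * math.log(k / n) for k in counts.values() if k > 0)


def _counts(labels) -> dict:
    out: dict = {}
    for y in labels:
        out[y] = out.get(y, 0) + 1
    return out


def _gini_cost(labels) -> float:
    n = len(labels)
    if n == 0:
        return 0.0
    counts = _counts(labels)
    return n * (1.0 - sum((k / n) ** 2 for k in counts.values()))


def _rss_cost(labels) -> float:
    """Residual sum of squares around the node mean (regression-tree cost;
    requires a numeric response, e.g. dendrogram-ordered cluster numbers)."""
    v = np.asarray(labels, dtype=float)
    if v.size == 0:
        return 0.0
    return float(((v - v.mean()) ** 2).sum())


_COSTS = {"deviance": multinomial_deviance, "gini": _gini_cost, "rss": _rss_cost}


def best_split(
    predictors: pd.DataFrame, labels: np.ndarray, criterion: str = "deviance"
) -> tuple[str, float, float] | None:
    """Exhaustive search over (variable, midpoint threshold) candidates.

    Returns (variable, threshold, cost reduction) for the best split or None
    if no split separates the data.  Tie-break: earlier column, then smaller
    threshold (implemented by strict improvement while scanning in canonical
    order).
    """
    cost_fn = _COSTS[criterion]
    cost = cost_fn(labels)
    best = None
    best_gain = 0.0
    for var in predictors.columns:
        x = predictors[var].to_numpy(dtype=float)
        values = np.unique(x)
        for lo, hi in zip(values[:-1], values[1:]):
            thr = (lo + hi) / 2.0
            mask = x <= thr
            left, right = labels[mask], labels[~mask]
            gain = cost - cost_fn(left) - cost_fn(right)
            if gain > best_gain + 1e-12:
                best_gain = gain
                best = (var, float(thr), float(gain))
    return best


def grow_tree(
    predictors: pd.DataFrame,
    response,
    min_node: int = 2,
    min_deviance_fraction: float = 0.01,
    criterion: str = "deviance",
) -> TreeNode:
    """Grow the classification tree.

    ``response`` is a sequence of class labels aligned to the predictor rows
    (a :class:`~foramstats.cluster.ClusterAssignment` works via its
    ``labels``).  A constant response yields a single-leaf tree.
    """
    if hasattr(response, "labels"):  # ClusterAssignment
        response = [response.labels[s] for s in predictors.index]
    labels = np.asarray(list(response))
    if predictors.shape[1] < 1:
        raise ValidationError("no predictors")
    if predictors.shape[0] < 2:
        raise ValidationError("need at least 2 samples")
    if len(labels) != predictors.shape[0]:
        raise ValidationError("response length does not match predictors")
    if criterion not in _COSTS:
        raise ValidationError(f"criterion must be one of {sorted(_COSTS)}")

    cost_fn = _COSTS[criterion]
    min_gain = min_deviance_fraction * cost_fn(labels)
    counter = {"next": 0}

    def build(idx: np.ndarray) -> TreeNode:
        sub = labels[idx]
        counts = _counts(sub)
        dev = cost_fn(sub)
        pred = min(counts, key=lambda c: (-counts[c], c))
        node = TreeNode(counter["next"], dev, counts, pred)
        counter["next"] += 1
        if len(counts) == 1 or len(idx) < min_node:
            return node
        split = best_split(predictors.iloc[idx], sub, criterion)
        if split is None:
            return node
        var, thr, gain = split
        if gain < min_gain:
            return node
        node.split_variable = var
        node.split_threshold = thr
        mask = predictors[var].to_numpy(dtype=float)[idx] <= thr
        node.left = build(idx[mask])
        node.right = build(idx[~mask])
        return node

    return build(np.arange(len(labels)))


def predict(root: TreeNode, sample: Mapping[str, float]):
    """Route one predictor vector through the tree (<= threshold goes left)."""
    node = root
    while not node.is_leaf:
        var = node.split_variable
        if var not in sample:
            raise ValidationError(f"missing predictor {var!r}")
        node = node.left if float(sample[var]) <= node.split_threshold else node.right
    return node.predicted_class


def leaves(root: TreeNode) -> list[TreeNode]:
    if root.is_leaf:
        return [root]
    return leaves(root.left) + leaves(root.right)


def tree_to_text(root: TreeNode) -> str:
    lines: list[str] = []

    def walk(node: TreeNode, depth: int, prefix: str) -> None:
        ind = "  " * depth
        counts = ", ".join(f"{k}:{v}" for k, v in sorted(node.class_counts.items(), key=str))
        if node.is_leaf:
            lines.append(f"{ind}{prefix}leaf -> class {node.predicted_class} "
                         f"(n={node.n}, deviance={node.deviance:.4g}, counts: {counts})")
        else:
            lines.append(f"{ind}{prefix}split {node.split_variable} <= "
                         f"{node.split_threshold:.6g} (n={node.n}, "
                         f"deviance={node.deviance:.4g}, counts: {counts})")
            walk(node.left, depth + 1, "L: ")
            walk(node.right, depth + 1, "R: ")

    walk(root, 0, "")
    return "\n".join(lines)


def tree_to_json(root: TreeNode) -> str:
    nodes = []

    def walk(node: TreeNode) -> None:
        nodes.append({
            "node_id": node.node_id,
            "split_variable": node.split_variable,
            "split_threshold": node.split_threshold,
            "deviance": node.deviance,
            "class_counts": {str(k): v for k, v in node.class_counts.items()},
            "predicted_class": node.predicted_class,
            "children": None if node.is_leaf else [node.left.node_id, node.right.node_id],
        })
        if not node.is_leaf:
            walk(node.left)
            walk(node.right)

    walk(root)
    return json.dumps({"nodes": nodes}, indent=2, default=str)
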