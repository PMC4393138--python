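"""ANOVA-impurity regression tree for binary survival data.

Greedy recursive partitioning of the 0/1 survival response on numeric
predictors, minimizing within-node sum of squares (the ANOVA
criterion).  Splitting follows the conventions of classic
recursive-partitioning software: a node is considered for splitting
only when it holds at least ``minsplit`` rows, each child must keep at
least ``minbucket`` rows, a split is accepted only when it reduces the
tree's relative error by at least ``cp`` (improvement ≥ cp · root sum
of squares), and candidate thresholds are midpoints between adjacent
observed predictor values.

Rows missing a predictor are excluded when evaluating splits on that
predictor and afterwards routed down the majority child (no surrogate
splits).  Each leaf carries the mean survival probability P and case
count n of the rows it holds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from paleosel.core_data import PREDICTOR_COLUMNS


@dataclass
class TreeNode:
    """One node: either a leaf or an internal split (var < threshold → left)."""

    n: int
    p: float  # mean survival probability of rows at this node
    ss: float  # within-node sum of squares of the response
    split_var: str | None = None
    threshold: float | None = None
    majority: str | None = None  # "left"/"right": where missing values go
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None
    improvement: float = 0.0  # absolute SSE reduction achieved by the split

    @property
    def is_leaf(self) -> bool:
        return self.split_var is None


@dataclass
class RegressionTree:
    """A fitted tree plus the control settings that produced it."""

    root: TreeNode
    control: dict = field(default_factory=dict)
    predictors: tuple[str, ...] = ()
    response: str = "survival"

    def to_text(self) -> str:
        lines: list[str] = []

        def walk(node: TreeNode, indent: int, label: str) -> None:
            pad = "  " * indent
            head = f"{pad}{label}n={node.n} P={node.p:.2f}"
            if node.is_leaf:
                lines.append(head + " *")
            else:
                lines.append(f"{head}  split: {node.split_var} < {node.threshold:.4g}")
                walk(node.left, indent + 1, f"[{node.split_var} < {node.threshold:.4g}] ")
                walk(node.right, indent + 1, f"[{node.split_var} >= {node.threshold:.4g}] ")

        walk(self.root, 0, "")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        def walk(node: TreeNode) -> dict:
            d = {"n": node.n, "p": node.p}
            if not node.is_leaf:
                d.update(
                    split_var=node.split_var,
                    threshold=node.threshold,
                    majority=node.majority,
                    left=walk(node.left),
                    right=walk(node.right),
                )
            return d

        return {"control": self.control, "tree": walk(self.root)}

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def _node_ss(y: np.ndarray) -> float:
    return float(((y - y.mean()) ** 2).sum()) if len(y) else 0.0


def best_split(
    X: pd.DataFrame, y: np.ndarray, minbucket: int
) -> tuple[str, float, float] | None:
    """Exhaustive scan for the (variable, threshold) minimizing child SSE.

    Returns (var, threshold, improvement) where improvement is the SSE
    reduction over the rows non-missing in that variable; None if no
    admissible split exists.  Thresholds are midpoints between adjacent
    distinct observed values.
    """
    best: tuple[str, float, float] | None = None
    for var in X.columns:
        x = X[var].to_numpy(dtype=float)
        ok = ~np.isnan(x)
        if ok.sum() < 2 * minbucket:
            continue
        xv, yv = x[ok], y[ok]
        order = np.argsort(xv, kind="mergesort")
        xs, ys = xv[order], yv[order]
        n = len(xs)
        parent_ss = _node_ss(ys)
        # prefix sums give left/right SSE for every cut in O(n)
        csum = np.cumsum(ys)
        csum2 = np.cumsum(ys**2)
        total, total2 = csum[-1], csum2[-1]
        for cut in range(minbucket, n - minbucket + 1):
            if xs[cut - 1] == xs[cut]:
                continue  # cannot separate equal values
            nl = cut
            nr = n - cut
            sl, sl2 = csum[cut - 1], csum2[cut - 1]
            ss_left = sl2 - sl**2 / nl
            ss_right = (total2 - sl2) - (total - sl) ** 2 / nr
            improvement = parent_ss - ss_left - ss_right
            if best is None or improvement > best[2] + 1e-12:
                threshold = (xs[cut - 1] + xs[cut]) / 2.0
                best = (var, float(threshold), float(improvement))
    return best


def fit_tree(
    table: pd.DataFrame,
    response: str = "survival",
    predictors: list[str] | None = None,
    minsplit: int = 20,
    minbucket: int = 7,
    cp: float = 0.01,
) -> RegressionTree:
    """Fit a greedy ANOVA regression tree to a 0/1 response.

    A constant response yields a root-only tree.  Rows missing the
    response are dropped; rows missing a predictor stay in the node and
    are routed by the majority rule when that predictor is split on.
    """
    if predictors is None:
        predictors = [c for c in PREDICTOR_COLUMNS if c in table.columns]
    data = table[[response, *predictors]].dropna(subset=[response])
    y_all = data[response].to_numpy(dtype=float)
    if len(y_all) == 0:
        raise ValueError("no rows with a response value")
    root_ss = _node_ss(y_all)

    def grow(idx: np.ndarray) -> TreeNode:
        y = y_all[idx]
        node = TreeNode(n=len(y), p=float(y.mean()), ss=_node_ss(y))
        if len(y) < minsplit or node.ss == 0:
            return node
        found = best_split(data.iloc[idx][predictors], y, minbucket)
        if found is None:
            return node
        var, threshold, improvement = found
        if root_ss == 0 or improvement < cp * root_ss:
            return node
        x = data.iloc[idx][var].to_numpy(dtype=float)
        go_left = x < threshold
        go_right = x >= threshold  # NaN is False in both masks
        n_left, n_right = int(go_left.sum()), int(go_right.sum())
        majority = "left" if n_left >= n_right else "right"
        missing = np.isnan(x)
        if majority == "left":
            go_left = go_left | missing
        else:
            go_right = go_right | missing
        node.split_var = var
        node.threshold = threshold
        node.majority = majority
        node.improvement = improvement
        node.left = grow(idx[go_left])
        node.right = grow(idx[go_right])
        return node

    root = grow(np.arange(len(data)))
    return RegressionTree(
        root=root,
        control={"minsplit": minsplit, "minbucket": minbucket, "cp": cp},
        predictors=tuple(predictors),
        response=response,
    )


def predict_survival(tree: RegressionTree, row) -> float:
    """Leaf survival probability for one predictor row (dict or Series).

    Missing split values follow the majority-child route.
    """
    node = tree.root
    while not node.is_leaf:
        value = row.get(node.split_var) if hasattr(row, "get") else row[node.split_var]
        if value is None or (isinstance(value, float) and np.isnan(value)):
            node = node.left if node.majority == "left" else node.right
        elif value < node.threshold:
            node = node.left
        else:
            node = node.right
    return node.p


def tree_deviance_explained(
    tree: RegressionTree, table: pd.DataFrame, response: str = "survival"
) -> float:
    """Percent of response sum of squares explained by the leaf means."""
    data = table.dropna(subset=[response])
    y = data[response].to_numpy(dtype=float)
    total = _node_ss(y)
    if total == 0:
        return 0.0
    pred = np.array([predict_survival(tree, row) for _, row in data.iterrows()])
    resid = float(((y - pred) ** 2).sum())
    return 100.0 * (1.0 - resid / total)
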