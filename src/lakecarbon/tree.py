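"""Binary recursive partitioning of a continuous response (anova CART).

Each split chooses the predictor and threshold that maximize the drop in
within-node sum of squares,

    ΔSS = SS(parent) - SS(left) - SS(right),

over all midpoints between consecutive distinct sorted predictor values.
Records with predictor < threshold go left; records at or above it go
right.  Growth stops when a node is too small to split, a maximum depth is
reached, or the best achievable ΔSS falls below the complexity parameter
times the root sum of squares (the rpart convention).  Leaves carry node
means; no cross-validation pruning and no surrogate splits.

Ties in ΔSS are broken deterministically: first by predictor order in the
input schema, then by the smaller threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TreeNode",
    "TreeFitConfig",
    "best_split",
    "fit_tree",
    "predict_tree",
    "render_tree",
]


@dataclass
class TreeFitConfig:
    """Stopping rules for tree growth.

    min_split: smallest node that may be split; min_leaf: smallest child
    allowed; cp: minimum ΔSS as a fraction of the root SS for a split to
    be kept; max_depth: unlimited when None.
    """

    min_split: int = 20
    min_leaf: int = 7
    cp: float = 0.01
    max_depth: int | None = None

    def __post_init__(self) -> None:
        if self.min_split < 2 or self.min_leaf < 1:
            raise ValueError("min_split must be >= 2 and min_leaf >= 1")
        if not (0.0 <= self.cp <= 1.0):
            raise ValueError("cp must be in [0, 1]")
        if self.max_depth is not None and self.max_depth < 0:
            raise ValueError("max_depth must be None or >= 0")


@dataclass
class TreeNode:
    """One node of a fitted tree.

    Internal nodes test ``variable < threshold`` (left branch); leaves
    have variable None and no children.  ``ss`` is the node's response sum
    of squares around its own mean.
    """

    mean: float
    n: int
    ss: float
    variable: str | None = None
    threshold: float | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.variable is None

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        return self.left.leaves() + self.right.leaves()

    def depth(self) -> int:
        if self.is_leaf:
            return 0
        return 1 + max(self.left.depth(), self.right.depth())


def _node_ss(y: np.ndarray) -> float:
    return float(((y - y.mean()) ** 2).sum()) if len(y) else 0.0


def best_split(x, y, min_leaf: int = 1):
    """Best threshold on a single predictor.

    Scans midpoints between consecutive distinct sorted values of `x`,
    maximizing the reduction in response sum of squares subject to both
    children holding at least `min_leaf` records.  Returns (threshold,
    reduction), or None when no admissible split exists (e.g. constant
    predictor).  Ties prefer the smaller threshold.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 2 or len(np.unique(x)) < 2:
        return None
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    csum = np.cumsum(ys)
    csum2 = np.cumsum(ys**2)
    total, total2 = csum[-1], csum2[-1]
    parent_ss = total2 - total**2 / n

    best = None  # (reduction, threshold)
    # Candidate cut after position i (left = 0..i) only where value changes.
    for i in range(n - 1):
        if xs[i + 1] <= xs[i]:
            continue
        n_left = i + 1
        n_right = n - n_left
        if n_left < min_leaf or n_right < min_leaf:
            continue
        ss_left = csum2[i] - csum[i] ** 2 / n_left
        ss_right = (total2 - csum2[i]) - (total - csum[i]) ** 2 / n_right
        reduction = parent_ss - ss_left - ss_right
        threshold = (xs[i] + xs[i + 1]) / 2.0
        if best is None or reduction > best[0] + 1e-12 * max(1.0, abs(best[0])):
            best = (reduction, threshold)
    if best is None:
        return None
    return best[1], best[0]


def fit_tree(
    table: pd.DataFrame,
    response: str,
    predictors: list[str] | None = None,
    config: TreeFitConfig | None = None,
) -> TreeNode:
    """Grow a regression tree on `table`.

    `predictors` defaults to every numeric column except the response;
    their order in the list is the tie-break order between predictors
    achieving equal ΔSS.  Rows with a missing response are dropped; rows
    missing a predictor value are dropped as well (no surrogate splits).
    """
    if config is None:
        config = TreeFitConfig()
    if predictors is None:
        predictors = [
            c
            for c in table.columns
            if c != response and pd.api.types.is_numeric_dtype(table[c])
        ]
    cols = list(predictors) + [response]
    data = table[cols].dropna()
    if data.empty:
        raise ValueError("no complete rows to fit on")
    y = data[response].to_numpy(dtype=float)
    xmat = {p: data[p].to_numpy(dtype=float) for p in predictors}
    root_ss = _node_ss(y)
    min_gain = config.cp * root_ss

    def grow(idx: np.ndarray, depth: int) -> TreeNode:
        yv = y[idx]
        node = TreeNode(mean=float(yv.mean()), n=len(idx), ss=_node_ss(yv))
        if len(idx) < config.min_split or node.ss <= 0:
            return node
        if config.max_depth is not None and depth >= config.max_depth:
            return node
        chosen = None  # (reduction, threshold, variable)
        for p in predictors:
            res = best_split(xmat[p][idx], yv, min_leaf=config.min_leaf)
            if res is None:
                continue
            thr, red = res
            if chosen is None or red > chosen[0] + 1e-12 * max(1.0, abs(chosen[0])):
                chosen = (red, thr, p)
        if chosen is None or chosen[0] < min_gain or chosen[0] <= 0:
            return node
        red, thr, var = chosen
        mask = xmat[var][idx] < thr
        node.variable = var
        node.threshold = float(thr)
        node.left = grow(idx[mask], depth + 1)
        node.right = grow(idx[~mask], depth + 1)
        return node

    return grow(np.arange(len(y)), 0)


def predict_tree(tree: TreeNode, record) -> float:
    """Route one record (mapping or pandas row) to a leaf and return its
    mean.  Records exactly at a threshold go right (the ">=" branch).
    Raises KeyError if a tested variable is missing — there are no
    surrogate splits."""
    node = tree
    while not node.is_leaf:
        try:
            value = record[node.variable]
        except (KeyError, IndexError) as exc:
            raise KeyError(
                f"record is missing variable {node.variable!r} tested by the tree"
            ) from exc
        if value is None or (isinstance(value, float) and np.isnan(value)):
            raise KeyError(
                f"record has missing value for {node.variable!r}; "
                "missing-data routing is not supported"
            )
        node = node.left if value < node.threshold else node.right
    return node.mean


def render_tree(tree: TreeNode, precision: int = 4) -> str:
    """Plain-text indented rule rendering.

    Internal nodes print the rule applied to the left branch
    (``var < thr``) with its complement on the right; leaves print the node
    mean and size, mirroring figure-style annotations."""
    lines: list[str] = []

    def walk(node: TreeNode, prefix: str, label: str) -> None:
        if node.is_leaf:
            lines.append(
                f"{prefix}{label}leaf: mean={node.mean:.{precision}g} n={node.n}"
            )
            return
        lines.append(
            f"{prefix}{label}{node.variable} < {node.threshold:.{precision}g} "
            f"[mean={node.mean:.{precision}g} n={node.n}]"
        )
        walk(node.left, prefix + "  ", "yes: ")
        walk(node.right, prefix + "  ", "no:  ")

    walk(tree, "", "")
    return "\n".join(lines)
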