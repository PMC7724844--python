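"""Regression-tree engine for partitioning ADG on lesion prevalences.

Least-squares recursive partitioning: each split chooses the predictor and
cut-off minimising the summed within-child sum of squared errors (SSE),
fitting the piecewise-constant model ``f(x) = sum_m c_m * I{x in R_m}``
with ``c_m`` the leaf means.  Growing stops when no admissible split
remains under the minimum-node rule (both children must keep at least
``min_leaf`` rows; a node needs ``2*min_leaf`` rows to be splittable).

The grown tree is then pruned by cost complexity: for a penalty ``alpha``
the subtree minimising ``SSE + alpha * |T|`` (|T| = number of leaves) is
found by weakest-link pruning, and the operating ``alpha`` is chosen as
the one with the least k-fold cross-validated error.  A one-way ANOVA
between the two children of every retained split reports whether the
binary partitions differ significantly in the response.

`CartRegressor` wraps the engine as a scikit-learn style estimator; the
module-level functions expose the individual operations.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "CartNode",
    "CartRegressor",
    "best_split",
    "grow_tree",
    "prune",
    "pruning_sequence",
    "cp_table",
    "select_alpha",
    "predict",
    "partition_anova",
    "tree_to_text",
]

_TOL = 1e-9          # absolute tolerance on SSE-reduction comparisons
_LINK_TOL = 1e-9     # tolerance when matching weakest-link values


@dataclass
class CartNode:
    """One node of a regression tree.

    Leaves have ``split_var is None``; internal nodes send rows with
    ``x[split_var] < threshold`` to ``left``.
    """

    node_id: int
    n: int
    node_mean: float
    sse: float
    split_var: Optional[str] = None
    threshold: Optional[float] = None
    left: Optional["CartNode"] = None
    right: Optional["CartNode"] = None

    @property
    def is_leaf(self) -> bool:
        return self.split_var is None

    def leaves(self):
        if self.is_leaf:
            return [self]
        return self.left.leaves() + self.right.leaves()

    def internal_nodes(self):
        if self.is_leaf:
            return []
        return [self] + self.left.internal_nodes() + self.right.internal_nodes()

    @property
    def n_leaves(self) -> int:
        return len(self.leaves())

    @property
    def subtree_sse(self) -> float:
        return sum(leaf.sse for leaf in self.leaves())


def _node_stats(y: np.ndarray):
    mean = float(np.mean(y))
    return mean, float(np.sum((y - mean) ** 2))


def best_split(X: np.ndarray, y: np.ndarray, min_leaf: int,
               feature_names=None):
    """Exhaustive best binary split of one node.

    Scans every predictor and every midpoint between consecutive distinct
    values, subject to both children keeping >= ``min_leaf`` rows, and
    returns ``(feature, threshold, sse_reduction)`` for the split with the
    largest SSE reduction — or ``None`` if no admissible split reduces the
    SSE (e.g. a constant response).  Ties break on lowest predictor index,
    then lowest threshold.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-dimensional")
    n, p = X.shape
    if n == 0:
        raise ValueError("empty node")
    if feature_names is None:
        feature_names = list(range(p))

    _, sse_parent = _node_stats(y)
    best = None  # (reduction, col, threshold)
    for j in range(p):
        order = np.argsort(X[:, j], kind="stable")
        xs, ys = X[order, j], y[order]
        csum = np.cumsum(ys)
        csq = np.cumsum(ys ** 2)
        total, total_sq = csum[-1], csq[-1]
        # candidate boundaries after position i (= size of the left child)
        for i in range(max(min_leaf, 1), min(n - min_leaf, n - 1) + 1):
            if xs[i - 1] == xs[i]:
                continue
            left_sum, left_sq = csum[i - 1], csq[i - 1]
            right_sum, right_sq = total - left_sum, total_sq - left_sq
            sse_l = left_sq - left_sum ** 2 / i
            sse_r = right_sq - right_sum ** 2 / (n - i)
            reduction = sse_parent - (sse_l + sse_r)
            thr = (xs[i - 1] + xs[i]) / 2.0
            if reduction <= _TOL:
                continue
            if (best is None or reduction > best[0] + _TOL
                    or (abs(reduction - best[0]) <= _TOL
                        and (j, thr) < (best[1], best[2]))):
                best = (reduction, j, thr)
    if best is None:
        return None
    reduction, j, thr = best
    return feature_names[j], float(thr), float(reduction)


def _grow(X, y, min_leaf, feature_names, counter):
    mean, sse = _node_stats(y)
    node = CartNode(node_id=next(counter), n=len(y), node_mean=mean, sse=sse)
    if len(y) < 2 * min_leaf:
        return node
    split = best_split(X, y, min_leaf, feature_names)
    if split is None:
        return node
    var, thr, _ = split
    j = feature_names.index(var)
    mask = X[:, j] < thr
    node.split_var, node.threshold = var, thr
    node.left = _grow(X[mask], y[mask], min_leaf, feature_names, counter)
    node.right = _grow(X[~mask], y[~mask], min_leaf, feature_names, counter)
    return node


def _as_matrix(cohort, response, predictors):
    missing = [c for c in [response, *predictors] if c not in cohort.columns]
    if missing:
        raise KeyError(f"columns not in cohort: {missing}")
    X = cohort[list(predictors)].to_numpy(dtype=float)
    y = cohort[response].to_numpy(dtype=float)
    return X, y


def grow_tree(cohort: pd.DataFrame, response: str = "adg",
              predictors=None, min_node: int = 10) -> CartNode:
    """Grow the full tree top-down on a cohort table.

    ``min_node`` is the minimum number of farms in any branch or leaf
    (so a node needs at least ``2*min_node`` farms to split).
    """
    if predictors is None:
        from .synthetic_cohort import LESION_COLUMNS
        predictors = LESION_COLUMNS
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    X, y = _as_matrix(cohort, response, predictors)

    def counter():
        i = 0
        while True:
            yield i
            i += 1

    return _grow(X, y, min_node, list(predictors), counter())


def _weakest_links(root: CartNode):
    """Link value g(t) = (SSE(t) - SSE(T_t)) / (|T_t| - 1) per internal node."""
    return {node.node_id: (node.sse - node.subtree_sse) / (node.n_leaves - 1)
            for node in root.internal_nodes()}


def _collapse(root: CartNode, node_ids) -> None:
    for node in root.internal_nodes():
        if node.node_id in node_ids:
            node.split_var = node.threshold = None
            node.left = node.right = None


def prune(tree: CartNode, alpha: float) -> CartNode:
    """Smallest subtree minimising ``SSE + alpha * |T|`` (weakest link).

    ``alpha=0`` returns the tree unchanged (every grown split strictly
    reduces SSE); a huge ``alpha`` collapses to the root leaf.
    """
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    out = copy.deepcopy(tree)
    while not out.is_leaf:
        links = _weakest_links(out)
        weakest = min(links.values())
        if weakest > alpha:
            break
        _collapse(out, {i for i, g in links.items()
                        if g <= weakest + _LINK_TOL})
    return out


def pruning_sequence(tree: CartNode):
    """Nested cost-complexity sequence ``[(alpha_k, subtree_k), ...]``.

    ``alpha_0 = 0`` with the full tree; alphas strictly increase and the
    final subtree is the root leaf.  ``subtree_k`` is optimal for
    penalties in ``[alpha_k, alpha_{k+1})``.
    """
    seq = [(0.0, copy.deepcopy(tree))]
    current = copy.deepcopy(tree)
    while not current.is_leaf:
        links = _weakest_links(current)
        weakest = min(links.values())
        _collapse(current, {i for i, g in links.items()
                            if g <= weakest + _LINK_TOL})
        seq.append((float(weakest), copy.deepcopy(current)))
    return seq


def _predict_one(node: CartNode, x: dict):
    while not node.is_leaf:
        node = node.left if x[node.split_var] < node.threshold else node.right
    return node.node_mean


def predict(tree: CartNode, cohort: pd.DataFrame) -> np.ndarray:
    """Leaf-mean prediction for every row of ``cohort``."""
    records = cohort.to_dict("records")
    return np.array([_predict_one(tree, r) for r in records], dtype=float)


def cp_table(tree: CartNode, cohort: pd.DataFrame, response: str = "adg",
             predictors=None, k_folds: int = 10, seed: int = 0,
             min_node: int = 10) -> pd.DataFrame:
    """Cost-complexity table with k-fold cross-validated errors.

    One row per subtree in the pruning sequence, largest penalty first
    (root-only tree, rel_error 1.0).  Columns: ``alpha`` (penalty at which
    the subtree becomes optimal), ``cp`` (alpha normalised by the root
    SSE, as in rpart), ``n_leaves``, ``rel_error`` (resubstitution SSE /
    root SSE), ``xerror`` and ``xstd`` (cross-validated error and its SE,
    same normalisation).  Fold assignment is a seeded random partition.
    """
    if predictors is None:
        from .synthetic_cohort import LESION_COLUMNS
        predictors = list(LESION_COLUMNS)
    n = len(cohort)
    if not (2 <= k_folds <= n):
        raise ValueError(f"k_folds must be in [2, {n}]")
    y = cohort[response].to_numpy(dtype=float)
    _, sse_root = _node_stats(y)
    if sse_root == 0:
        raise ValueError("constant response; nothing to fit")

    seq = pruning_sequence(tree)
    alphas = [a for a, _ in seq]
    # geometric-mean penalties used to evaluate each subtree out-of-fold
    betas = []
    for k in range(len(seq)):
        if k + 1 < len(seq):
            betas.append(float(np.sqrt(max(alphas[k], 0.0) * alphas[k + 1])))
        else:
            betas.append(alphas[k])

    rng = np.random.default_rng(seed)
    fold_of = np.repeat(np.arange(k_folds), np.ceil(n / k_folds))[:n]
    fold_of = fold_of[rng.permutation(n)]

    sq_err = np.zeros((len(seq), n))
    for f in range(k_folds):
        test = fold_of == f
        train = ~test
        fold_tree = grow_tree(cohort.loc[train], response, predictors,
                              min_node=min_node)
        for k, beta in enumerate(betas):
            sub = prune(fold_tree, beta)
            pred = predict(sub, cohort.loc[test])
            sq_err[k, test] = (y[test] - pred) ** 2

    rows = []
    for k, (alpha, sub) in enumerate(seq):
        cv = sq_err[k]
        xerror = float(cv.sum() / sse_root)
        xstd = float(np.sqrt(n * np.var(cv)) / sse_root)
        rows.append({"alpha": alpha, "cp": alpha / sse_root,
                     "n_leaves": sub.n_leaves,
                     "rel_error": sub.subtree_sse / sse_root,
                     "xerror": xerror, "xstd": xstd})
    table = pd.DataFrame(rows).sort_values("alpha", ascending=False,
                                           kind="stable")
    return table.reset_index(drop=True)


def select_alpha(table: pd.DataFrame) -> float:
    """Penalty of the row with the least cross-validated error."""
    return float(table.loc[table["xerror"].idxmin(), "alpha"])


def partition_anova(tree: CartNode, cohort: pd.DataFrame,
                    response: str = "adg", alpha_level: float = 0.05
                    ) -> pd.DataFrame:
    """One-way ANOVA of the response between the children of every split.

    With two groups this is the squared two-sample t-test.  Splits with
    zero within-group variance but distinct means report ``F=inf, p=0``.
    """
    if tree.is_leaf:
        raise ValueError("tree has no splits")
    y = cohort[response].to_numpy(dtype=float)

    rows = []

    def visit(node, mask):
        if node.is_leaf:
            return
        x = cohort[node.split_var].to_numpy(dtype=float)
        left = mask & (x < node.threshold)
        right = mask & ~(x < node.threshold)
        yl, yr = y[left], y[right]
        within = np.sum((yl - yl.mean()) ** 2) + np.sum((yr - yr.mean()) ** 2)
        if within == 0:
            f_stat, p = (np.inf, 0.0) if yl.mean() != yr.mean() else (0.0, 1.0)
        else:
            f_stat, p = stats.f_oneway(yl, yr)
        rows.append({"node_id": node.node_id, "split_var": node.split_var,
                     "threshold": node.threshold,
                     "n_left": int(left.sum()), "n_right": int(right.sum()),
                     "mean_left": float(yl.mean()),
                     "mean_right": float(yr.mean()),
                     "F": float(f_stat), "p_value": float(p),
                     "significant": bool(p < alpha_level)})
        visit(node.left, left)
        visit(node.right, right)

    visit(tree, np.ones(len(cohort), dtype=bool))
    return pd.DataFrame(rows)


def tree_to_text(node: CartNode, indent: int = 0) -> str:
    """Plain-text indented tree report."""
    pad = "  " * indent
    if node.is_leaf:
        line = f"{pad}leaf: n={node.n} mean={node.node_mean:.1f} sse={node.sse:.1f}"
        return line + "\n"
    head = (f"{pad}node {node.node_id}: {node.split_var} < {node.threshold:.3f}"
            f" (n={node.n}, mean={node.node_mean:.1f})\n")
    return head + tree_to_text(node.left, indent + 1) + tree_to_text(
        node.right, indent + 1)


class CartRegressor(RegressorMixin, BaseEstimator):
    """Regression tree with minimum-node stopping and cost-complexity
    pruning selected by cross-validation.

    Parameters
    ----------
    min_leaf : int, default 10
        Minimum rows in any branch or leaf (a node needs ``2*min_leaf``
        rows to be split).
    pruning : {"cv", "none"}, default "cv"
        "cv" prunes at the penalty with the least k-fold cross-validated
        error; "none" keeps the full tree.
    k_folds : int, default 10
    random_state : int or None
        Seed of the cross-validation fold assignment.

    Attributes (after ``fit``)
    --------------------------
    tree_ : CartNode — the (pruned) fitted tree.
    tree_full_ : CartNode — the unpruned tree.
    cp_table_ : DataFrame — the cost-complexity table ("cv" only).
    alpha_ : float — the selected pruning penalty.
    feature_names_in_ : list of predictor names.
    """

    def __init__(self, min_leaf: int = 10, pruning: str = "cv",
                 k_folds: int = 10, random_state=None):
        self.min_leaf = min_leaf
        self.pruning = pruning
        self.k_folds = k_folds
        self.random_state = random_state

    def fit(self, X, y):
        if isinstance(X, pd.DataFrame):
            names = list(X.columns)
            frame = X.copy()
        else:
            X = np.asarray(X, dtype=float)
            names = [f"x{j}" for j in range(X.shape[1])]
            frame = pd.DataFrame(X, columns=names)
        frame = frame.reset_index(drop=True)
        frame["__response__"] = np.asarray(y, dtype=float)
        if self.pruning not in ("cv", "none"):
            raise ValueError("pruning must be 'cv' or 'none'")

        self.feature_names_in_ = names
        self.tree_full_ = grow_tree(frame, "__response__", names,
                                    min_node=self.min_leaf)
        if self.pruning == "cv" and not self.tree_full_.is_leaf:
            seed = 0 if self.random_state is None else int(self.random_state)
            self.cp_table_ = cp_table(self.tree_full_, frame, "__response__",
                                      names, k_folds=min(self.k_folds, len(frame)),
                                      seed=seed, min_node=self.min_leaf)
            self.alpha_ = select_alpha(self.cp_table_)
            self.tree_ = prune(self.tree_full_, self.alpha_)
        else:
            self.cp_table_ = None
            self.alpha_ = 0.0
            self.tree_ = copy.deepcopy(self.tree_full_)
        self.n_leaves_ = self.tree_.n_leaves
        return self

    def predict(self, X):
        if not hasattr(self, "tree_"):
            raise AttributeError("estimator is not fitted")
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X, dtype=float),
                             columns=self.feature_names_in_)
        return predict(self.tree_, X)

    def anova_table(self, X, y, alpha_level: float = 0.05) -> pd.DataFrame:
        """Per-split ANOVA of the fitted partitions on (X, y)."""
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X, dtype=float),
                             columns=self.feature_names_in_)
        frame = X.reset_index(drop=True).copy()
        frame["__response__"] = np.asarray(y, dtype=float)
        return partition_anova(self.tree_, frame, "__response__", alpha_level)
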