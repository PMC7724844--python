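import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plucksim import cart
from plucksim.cart import CartRegressor
from plucksim.synthetic_cohort import LESION_COLUMNS


def brute_force_split(X, y, min_leaf):
    """Independent exhaustive-enumeration oracle for the best binary split."""
    n, p = X.shape
    best = None
    for j in range(p):
        xs = np.unique(X[:, j])
        for lo, hi in zip(xs, xs[1:]):
            thr = (lo + hi) / 2.0
            mask = X[:, j] < thr
            if mask.sum() < min_leaf or (~mask).sum() < min_leaf:
                continue
            sse = (np.sum((y[mask] - y[mask].mean()) ** 2)
                   + np.sum((y[~mask] - y[~mask].mean()) ** 2))
            red = np.sum((y - y.mean()) ** 2) - sse
            if red <= 1e-9:
                continue
            key = (-red, j, thr)
            if best is None or key < best[0]:
                best = (key, j, thr, red)
    if best is None:
        return None
    _, j, thr, red = best
    return j, thr, red


class TestBestSplit:
    def test_perfectly_separated(self):
        res = cart.best_split(np.array([[1.], [2.], [3.], [4.]]),
                              np.array([0., 0., 10., 10.]), min_leaf=2)
        var, thr, red = res
        assert (var, thr) == (0, 2.5)
        assert red == pytest.approx(100.0)

    def test_constant_response_returns_none(self):
        X = np.arange(8, dtype=float).reshape(-1, 1)
        assert cart.best_split(X, np.full(8, 3.0), min_leaf=2) is None

    def test_empty_node_rejected(self):
        with pytest.raises(ValueError):
            cart.best_split(np.empty((0, 1)), np.empty(0), min_leaf=1)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.uniform(0, 10, size=(30, 3))
        y = X[:, 0] * 2 + rng.normal(0, 3, 30)
        res = cart.best_split(X, y, min_leaf=5)
        oracle = brute_force_split(X, y, min_leaf=5)
        assert (res[0], res[1]) == (oracle[0], pytest.approx(oracle[1]))
        assert res[2] == pytest.approx(oracle[2])


def exhaustive_tree(X, y, min_leaf):
    """Oracle recursion built on the brute-force split search."""
    mean = y.mean()
    node = {"mean": mean, "n": len(y)}
    if len(y) >= 2 * min_leaf:
        split = brute_force_split(X, y, min_leaf)
        if split is not None:
            j, thr, _ = split
            mask = X[:, j] < thr
            node["split"] = (j, thr)
            node["left"] = exhaustive_tree(X[mask], y[mask], min_leaf)
            node["right"] = exhaustive_tree(X[~mask], y[~mask], min_leaf)
    return node


def same_structure(node, oracle):
    if node.is_leaf:
        return "split" not in oracle and node.node_mean == pytest.approx(oracle["mean"])
    if "split" not in oracle:
        return False
    j, thr = oracle["split"]
    return (node.threshold == pytest.approx(thr)
            and same_structure(node.left, oracle["left"])
            and same_structure(node.right, oracle["right"]))


class TestGrowTree:
    def test_small_cohort_stays_a_leaf(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"x": rng.uniform(size=19), "adg": rng.normal(700, 30, 19)})
        tree = cart.grow_tree(df, "adg", ["x"], min_node=10)
        assert tree.is_leaf and tree.n == 19

    def test_exactly_twenty_separable_rows_split_once(self):
        df = pd.DataFrame({"x": np.arange(20.0),
                           "adg": np.r_[np.full(10, 700.0), np.full(10, 760.0)]})
        tree = cart.grow_tree(df, "adg", ["x"], min_node=10)
        assert not tree.is_leaf
        assert tree.left.is_leaf and tree.right.is_leaf
        assert tree.left.n == tree.right.n == 10

    def test_missing_column_raises(self, cohort):
        with pytest.raises(KeyError):
            cart.grow_tree(cohort, "nope", LESION_COLUMNS)

    @pytest.mark.parametrize("seed", range(5))
    def test_equals_exhaustive_recursion(self, seed):
        rng = np.random.default_rng(100 + seed)
        n = int(rng.integers(20, 51))
        X = rng.uniform(0, 10, size=(n, 3))
        y = np.where(X[:, 1] > 5, 50.0, 0.0) + rng.normal(0, 5, n)
        df = pd.DataFrame(X, columns=["a", "b", "c"])
        df["y"] = y
        tree = cart.grow_tree(df, "y", ["a", "b", "c"], min_node=5)
        oracle = exhaustive_tree(X, y, min_leaf=5)
        assert same_structure(tree, oracle)

    def test_prediction_conservation(self, fitted_tree, cohort):
        """Leaf-n weighted mean of leaf means equals the overall mean."""
        tree = fitted_tree.tree_full_
        weighted = sum(l.n * l.node_mean for l in tree.leaves()) / tree.n
        assert weighted == pytest.approx(cohort["adg"].mean())


def toy_three_leaf():
    df = pd.DataFrame({"x": [1., 2., 3., 4., 5., 6.],
                       "y": [0., 0., 10., 10., 30., 30.]})
    return df, cart.grow_tree(df, "y", ["x"], min_node=1)


class TestPrune:
    def test_alpha_zero_is_identity(self, fitted_tree):
        full = fitted_tree.tree_full_
        assert cart.prune(full, 0.0).n_leaves == full.n_leaves

    def test_huge_alpha_collapses_to_root(self, fitted_tree, cohort):
        root = cart.prune(fitted_tree.tree_full_, 1e12)
        assert root.is_leaf
        assert root.node_mean == pytest.approx(cohort["adg"].mean())

    def test_alpha_between_link_values_gives_two_leaves(self):
        # hand computation: leaves {0,0},{10,10},{30,30}; the inner split's
        # link value is (100-0)/1 = 100 and the root's is (933.33-0)/2 =
        # 466.67, so any alpha in between keeps exactly two leaves
        _, tree = toy_three_leaf()
        assert tree.n_leaves == 3
        pruned = cart.prune(tree, 200.0)
        assert pruned.n_leaves == 2
        assert sorted(l.node_mean for l in pruned.leaves()) == [5.0, 30.0]

    def test_sequence_is_nested_and_monotone(self, fitted_tree):
        seq = cart.pruning_sequence(fitted_tree.tree_full_)
        alphas = [a for a, _ in seq]
        n_leaves = [t.n_leaves for _, t in seq]
        assert alphas == sorted(alphas)
        assert all(b < a for a, b in zip(n_leaves, n_leaves[1:]))
        # nested: every later tree's internal nodes were internal earlier
        internal = [frozenset(n.node_id for n in t.internal_nodes())
                    for _, t in seq]
        for earlier, later in zip(internal, internal[1:]):
            assert later <= earlier
        assert n_leaves[-1] == 1


class TestCpTable:
    def test_first_row_is_root_with_unit_error(self, fitted_tree):
        table = fitted_tree.cp_table_
        assert table.loc[0, "n_leaves"] == 1
        assert table.loc[0, "rel_error"] == pytest.approx(1.0)
        assert (np.diff(table["alpha"]) < 0).all()
        assert (np.diff(table["n_leaves"]) > 0).all()
        assert (np.diff(table["rel_error"]) <= 1e-12).all()

    def test_separable_data_keeps_full_tree(self):
        x = np.arange(40.0)
        # four perfectly separated levels: growth stops at the true
        # 4-leaf structure, so the full tree is the correct model
        y = (x // 10) * 50.0
        df = pd.DataFrame({"x": x, "y": y})
        tree = cart.grow_tree(df, "y", ["x"], min_node=5)
        table = cart.cp_table(tree, df, "y", ["x"], k_folds=5, seed=0,
                              min_node=5)
        best = table.loc[table["xerror"].idxmin()]
        assert best["n_leaves"] == tree.n_leaves

    def test_deterministic_given_seed(self, fitted_tree, cohort):
        t1 = cart.cp_table(fitted_tree.tree_full_, cohort, seed=5)
        t2 = cart.cp_table(fitted_tree.tree_full_, cohort, seed=5)
        pd.testing.assert_frame_equal(t1, t2)

    def test_bad_fold_count_rejected(self, fitted_tree, cohort):
        with pytest.raises(ValueError):
            cart.cp_table(fitted_tree.tree_full_, cohort, k_folds=1)


class TestPartitionAnova:
    def test_identical_children_not_significant(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({"x": np.r_[np.zeros(15), np.ones(15)],
                           "y": np.tile(rng.normal(0, 1, 15), 2)})
        tree = cart.CartNode(0, 30, df["y"].mean(),
                             float(np.sum((df["y"] - df["y"].mean())**2)),
                             split_var="x", threshold=0.5)
        tree.left = cart.CartNode(1, 15, 0.0, 0.0)
        tree.right = cart.CartNode(2, 15, 0.0, 0.0)
        res = cart.partition_anova(tree, df, "y")
        assert res.loc[0, "F"] == pytest.approx(0.0, abs=1e-12)
        assert res.loc[0, "p_value"] == pytest.approx(1.0)

    def test_zero_within_variance_reports_tiny_p(self):
        df = pd.DataFrame({"x": [1., 2., 3., 4.], "y": [0., 0., 10., 10.]})
        tree = cart.grow_tree(df, "y", ["x"], min_node=2)
        res = cart.partition_anova(tree, df, "y")
        assert res.loc[0, "p_value"] < 1e-10

    def test_leaf_only_tree_rejected(self):
        leaf = cart.CartNode(0, 5, 1.0, 0.0)
        with pytest.raises(ValueError):
            cart.partition_anova(leaf, pd.DataFrame({"y": [1.0] * 5}), "y")


class TestEstimatorInterface:
    def test_sklearn_contract(self, cohort):
        model = CartRegressor(min_leaf=10, random_state=0)
        params = model.get_params()
        assert params["min_leaf"] == 10
        model.set_params(k_folds=5)
        model.fit(cohort[LESION_COLUMNS], cohort["adg"])
        pred = model.predict(cohort[LESION_COLUMNS])
        assert pred.shape == (len(cohort),)
        leaf_means = np.array([l.node_mean for l in model.tree_.leaves()])
        for v in np.unique(pred):
            assert np.min(np.abs(leaf_means - v)) < 1e-9
        assert 0.0 < model.score(cohort[LESION_COLUMNS], cohort["adg"]) <= 1.0

    def test_no_pruning_keeps_full_tree(self, cohort):
        model = CartRegressor(pruning="none").fit(cohort[LESION_COLUMNS],
                                                  cohort["adg"])
        assert model.n_leaves_ == model.tree_full_.n_leaves

    def test_matches_sklearn_root_split(self, cohort):
        """Independent cross-check: identical depth-1 fit to sklearn."""
        from sklearn.tree import DecisionTreeRegressor

        sk = DecisionTreeRegressor(max_depth=1, min_samples_leaf=10)
        sk.fit(cohort[LESION_COLUMNS], cohort["adg"])
        res = cart.best_split(cohort[LESION_COLUMNS].to_numpy(),
                              cohort["adg"].to_numpy(), min_leaf=10,
                              feature_names=list(LESION_COLUMNS))
        assert res[0] == LESION_COLUMNS[sk.tree_.feature[0]]
        # sklearn stores thresholds at float32 precision
        assert res[1] == pytest.approx(sk.tree_.threshold[0], abs=1e-5)
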