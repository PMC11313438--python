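"""Weighted forest: impurity, splits, trees, ensembles, MDI importances."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import ffrfe
from ffrfe.forest import (
    ForestParams,
    _tree_mdi,
    _tree_predict_proba,
    best_split,
    build_tree,
    fit_forest,
    gini_impurity,
)


class TestGini:
    def test_pure_node_is_zero(self):
        assert gini_impurity([1, 1, 1, 1]) == 0.0

    def test_equal_thirds_is_max(self):
        assert gini_impurity([0, 1, 2]) == pytest.approx(2 / 3)

    def test_study_class_balance(self):
        """H for unweighted frequencies 44/110, 39/110, 27/110 equals
        1 - (44^2 + 39^2 + 27^2)/110^2 = 7914/12100."""
        y = [0] * 44 + [1] * 39 + [2] * 27
        assert gini_impurity(y) == pytest.approx(7914 / 12100, abs=1e-12)

    def test_weights_act_as_multiplicities(self):
        assert gini_impurity([0, 1], w=[2.0, 1.0]) == pytest.approx(
            gini_impurity([0, 0, 1])
        )

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            gini_impurity([])

    @given(
        st.lists(st.sampled_from([0, 1, 2]), min_size=1, max_size=30),
        st.integers(0, 2**31 - 1),
    )
    def test_bounds(self, y, seed):
        w = np.random.default_rng(seed).uniform(0.1, 5.0, len(y))
        h = gini_impurity(y, w)
        assert 0.0 <= h <= 2 / 3 + 1e-12
        if len(set(y)) == 1:
            assert h == 0.0


def brute_force_split(x, y, w, features, min_samples_leaf):
    """Independent exhaustive minimizer over every (feature, midpoint)."""
    best = None
    w_total = w.sum()
    for i in features:
        vals = np.unique(x[:, i])
        for lo, hi in zip(vals[:-1], vals[1:]):
            t = (lo + hi) / 2
            mask = x[:, i] < t
            if mask.sum() < min_samples_leaf or (~mask).sum() < min_samples_leaf:
                continue
            g = (
                w[mask].sum() * gini_impurity(y[mask], w[mask])
                + w[~mask].sum() * gini_impurity(y[~mask], w[~mask])
            ) / w_total
            if best is None or g < best[2]:
                best = (i, t, g)
    return best


class TestBestSplit:
    def test_perfect_separator_found(self):
        x = np.array([[0.0, 5.0], [1.0, 5.0], [10.0, 5.0], [11.0, 5.0]])
        y = np.array([0, 0, 2, 2])
        i, t, g = best_split(x, y, np.ones(4), [0, 1])
        assert (i, t) == (0, 5.5)
        assert g == 0.0

    def test_constant_features_give_no_split(self):
        x = np.full((6, 2), 3.0)
        assert best_split(x, np.array([0, 1, 2, 0, 1, 2]), np.ones(6), [0, 1]) is None

    def test_min_samples_leaf_respected(self):
        x = np.arange(10, dtype=float)[:, None]
        y = np.array([0] * 2 + [1] * 8)
        sp = best_split(x, y, np.ones(10), [0], min_samples_leaf=4)
        assert sp is not None
        assert (x[:, 0] < sp[1]).sum() >= 4 and (x[:, 0] >= sp[1]).sum() >= 4

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 51))
        p = int(rng.integers(1, 6))
        x = rng.normal(size=(n, p))
        y = rng.integers(0, 3, n)
        w = rng.uniform(0.2, 3.0, n)
        msl = int(rng.integers(1, 4))
        got = best_split(x, y, w, range(p), msl)
        want = brute_force_split(x, y, w, range(p), msl)
        if want is None:
            assert got is None
        else:
            assert got[0] == want[0]
            assert got[1] == pytest.approx(want[1])
            assert got[2] == pytest.approx(want[2], abs=1e-12)


def _walk(node, visit):
    visit(node)
    if not node.is_leaf:
        _walk(node.left, visit)
        _walk(node.right, visit)


class TestBuildTree:
    def test_leaf_only_tree_carries_global_distribution(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(10, 2))
        y = np.array([0] * 5 + [1] * 3 + [2] * 2)
        params = ForestParams(min_samples_leaf=6, n_features_per_split=2)
        tree = build_tree(x, y, np.ones(10), params, rng)
        assert tree.is_leaf
        assert np.allclose(tree.proba, [0.5, 0.3, 0.2])

    def test_separable_data_fit_perfectly(self):
        rng = np.random.default_rng(1)
        y = np.repeat([0, 1, 2], 20)
        x = rng.normal(size=(60, 3))
        x[:, 1] = y * 5 + rng.normal(scale=0.1, size=60)
        params = ForestParams(max_depth=3, min_samples_leaf=1, n_features_per_split=3)
        tree = build_tree(x, y, np.ones(60), params, rng)
        pred = _tree_predict_proba(tree, x).argmax(axis=1)
        assert (pred == y).all()

    def test_depth_and_weight_conservation(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(100, 4))
        y = rng.integers(0, 3, 100)
        w = rng.uniform(0.5, 2.0, 100)
        params = ForestParams(max_depth=3, min_samples_leaf=5, n_features_per_split=2)
        tree = build_tree(x, y, w, params, rng)

        def depth_of(node):
            if node.is_leaf:
                return 0
            return 1 + max(depth_of(node.left), depth_of(node.right))

        assert depth_of(tree) <= 3

        def check(node):
            if not node.is_leaf:
                assert node.left.weight + node.right.weight == pytest.approx(
                    node.weight
                )
                assert node.delta > 0  # accepted splits decrease impurity

        _walk(tree, check)

    def test_leaf_probabilities_normalized(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(60, 3))
        y = rng.integers(0, 3, 60)
        tree = build_tree(
            x, y, np.ones(60), ForestParams(min_samples_leaf=5), rng
        )

        def check(node):
            if node.is_leaf:
                assert node.proba.sum() == pytest.approx(1.0, abs=1e-12)

        _walk(tree, check)


def _toy(seed=0, n=90):
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 3, n)
    x = rng.normal(size=(n, 5))
    x[:, 0] += y * 2.0  # informative feature
    return x, y


class TestForest:
    def test_same_seed_identical_models(self):
        x, y = _toy()
        params = ForestParams(n_trees=10, min_samples_leaf=5, seed=7)
        a = fit_forest(x, y, params)
        b = fit_forest(x, y, params)
        assert a.to_json() == b.to_json()
        assert np.array_equal(a.predict_proba(x), b.predict_proba(x))

    def test_single_class_rejected(self):
        x = np.random.default_rng(0).normal(size=(20, 2))
        with pytest.raises(ValueError):
            fit_forest(x, np.zeros(20, dtype=int), ForestParams())

    def test_single_tree_forest_equals_its_tree(self):
        x, y = _toy()
        params = ForestParams(n_trees=1, min_samples_leaf=5, seed=3)
        model = fit_forest(x, y, params)
        assert np.allclose(
            model.predict_proba(x), _tree_predict_proba(model.trees[0], x)
        )

    def test_prediction_averages_trees_and_normalizes(self):
        x, y = _toy(4)
        model = fit_forest(x, y, ForestParams(n_trees=20, min_samples_leaf=5, seed=1))
        proba = model.predict_proba(x)
        assert np.allclose(proba.sum(axis=1), 1.0)
        assert (proba >= 0).all() and (proba <= 1).all()
        manual = np.mean([_tree_predict_proba(t, x) for t in model.trees], axis=0)
        assert np.allclose(proba, manual)
        # invariant to tree order
        model.trees = model.trees[::-1]
        assert np.allclose(model.predict_proba(x), proba)

    def test_dimension_mismatch_rejected(self):
        x, y = _toy()
        model = fit_forest(x, y, ForestParams(n_trees=2, min_samples_leaf=5))
        with pytest.raises(ValueError):
            model.predict_proba(x[:, :3])

    def test_matches_reference_single_tree(self):
        """Unweighted single tree with all features per split reproduces a
        reference CART (scikit-learn) fit exactly on tie-free data."""
        from sklearn.tree import DecisionTreeClassifier

        for seed in range(5):
            rng = np.random.default_rng(seed)
            x = rng.normal(size=(80, 3))
            y = rng.integers(0, 3, 80)
            params = ForestParams(
                max_depth=2, min_samples_leaf=5, n_features_per_split=3
            )
            tree = build_tree(x, y, np.ones(80), params, rng)
            mine = _tree_predict_proba(tree, x).argmax(axis=1)
            ref = DecisionTreeClassifier(
                criterion="gini", max_depth=2, min_samples_leaf=5, random_state=0
            ).fit(x, y)
            assert np.array_equal(mine, ref.predict(x))

    def test_serialization_round_trip(self):
        x, y = _toy(5)
        model = fit_forest(x, y, ForestParams(n_trees=5, min_samples_leaf=5, seed=9))
        clone = ffrfe.ForestModel.from_json(model.to_json())
        assert np.allclose(model.predict_proba(x), clone.predict_proba(x))
        assert np.allclose(
            model.feature_importances_, clone.feature_importances_
        )


class TestMDI:
    def test_unused_feature_has_zero_importance(self):
        x, y = _toy()
        x[:, 3] = 1.0  # constant, can never be used
        model = fit_forest(x, y, ForestParams(n_trees=10, min_samples_leaf=5, seed=2))
        assert model.feature_importances_[3] == 0.0

    def test_rearrangement_identity(self):
        """Per tree, the MDI vector sums to the sum over internal nodes of
        p(m) * delta(m)."""
        x, y = _toy(6)
        model = fit_forest(x, y, ForestParams(n_trees=5, min_samples_leaf=5, seed=4))
        for tree in model.trees:
            total = []

            def collect(node):
                if not node.is_leaf:
                    total.append((node.weight / tree.weight) * node.delta)

            _walk(tree, collect)
            assert _tree_mdi(tree, 5).sum() == pytest.approx(sum(total))

    def test_perfect_depth_one_stump_importance_equals_root_impurity(self):
        x = np.array([[0.0], [0.0], [1.0], [1.0]])
        y = np.array([0, 0, 2, 2])
        rng = np.random.default_rng(0)
        params = ForestParams(max_depth=1, min_samples_leaf=1, n_features_per_split=1)
        tree = build_tree(x, y, np.ones(4), params, rng)
        assert _tree_mdi(tree, 1)[0] == pytest.approx(gini_impurity(y))

    def test_invariant_to_global_weight_rescaling(self):
        x, y = _toy(7)
        rng1 = np.random.default_rng(11)
        rng2 = np.random.default_rng(11)
        params = ForestParams(min_samples_leaf=5, n_features_per_split=2)
        w = np.random.default_rng(1).uniform(0.5, 2.0, y.size)
        a = _tree_mdi(build_tree(x, y, w, params, rng1), 5)
        b = _tree_mdi(build_tree(x, y, 7.5 * w, params, rng2), 5)
        assert np.allclose(a, b)

    def test_informative_feature_wins(self):
        """One informative + four noise features: the informative one gets
        the top MDI in at least 95% of seeded runs."""
        wins = 0
        for seed in range(20):
            x, y = _toy(seed=100 + seed)
            model = fit_forest(
                x, y, ForestParams(n_trees=20, min_samples_leaf=5, seed=seed)
            )
            wins += int(np.argmax(model.feature_importances_) == 0)
        assert wins >= 19
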