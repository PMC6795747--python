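"""The multimodal random forest: splitting, CART, voting, accuracy, the
tree-count scan and the stability rule."""

import numpy as np
import pytest

from mrfusion.forest import (
    AccuracyCurve,
    MultimodalRandomForestClassifier,
    SplitSpec,
    TreeSpec,
    accuracy,
    default_feature_count,
    draw_tree_inputs,
    fit_cart,
    scan_tree_counts,
    select_stable_count,
    split_train_test,
)


def leaf_tree(label, n_features=1):
    """A degenerate one-leaf tree that always votes ``label``."""
    return TreeSpec(
        feature_subset=np.arange(n_features),
        sample_indices=np.array([0]),
        feature=np.array([-1], dtype=np.int32),
        threshold=np.array([0.0]),
        left=np.array([-1], dtype=np.int32),
        right=np.array([-1], dtype=np.int32),
        value=np.array([label], dtype=np.int8),
    )


class TestSplit:
    def test_exact_six_four_partition(self):
        labels = np.array([-1] * 5 + [1] * 5)
        train, test = split_train_test(labels, SplitSpec(seed=1, stratified=False))
        assert len(train) == 6 and len(test) == 4
        assert sorted(np.concatenate([train, test])) == list(range(10))

    def test_stratified_per_class_rounding(self):
        labels = np.array([-1] * 5 + [1] * 5)
        train, test = split_train_test(labels, SplitSpec(seed=2))
        assert (labels[train] == -1).sum() == 3 and (labels[train] == 1).sum() == 3
        assert len(test) == 4

    def test_same_seed_reproduces_partition(self):
        labels = np.array([-1] * 20 + [1] * 17)
        a = split_train_test(labels, SplitSpec(seed=9))
        b = split_train_test(labels, SplitSpec(seed=9))
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_tiny_class_raises(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            split_train_test(np.array([-1, 1, 1, 1]), SplitSpec(seed=0))


class TestAccuracy:
    def test_extremes_and_fraction(self):
        assert accuracy([1, 1], [1, 1]) == 1.0
        assert accuracy([1, 1], [-1, -1]) == 0.0
        pred = [1] * 25 + [-1] * 5
        truth = [1] * 30
        assert accuracy(pred, truth) == pytest.approx(25 / 30)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            accuracy([1, 1], [1])


class TestDefaultFeatureCount:
    @pytest.mark.parametrize("M,m", [(3240, 57), (1, 1), (100, 10), (2, 1)])
    def test_nearest_sqrt(self, M, m):
        assert default_feature_count(M) == m


class TestDrawTreeInputs:
    def test_full_feature_set_when_m_equals_M(self):
        rng = np.random.default_rng(0)
        sample, features = draw_tree_inputs(8, 5, 5, rng)
        assert features.tolist() == [0, 1, 2, 3, 4]
        assert len(sample) == 8

    def test_m_above_M_raises(self):
        with pytest.raises(ValueError):
            draw_tree_inputs(8, 5, 6, np.random.default_rng(0))

    def test_inclusion_frequency_matches_m_over_M(self):
        # binomial check over many independent subset draws
        M, m, reps = 3240, 57, 10_000
        rng = np.random.default_rng(3)
        counts = np.zeros(M)
        for _ in range(reps):
            _, features = draw_tree_inputs(4, M, m, rng)
            counts[features] += 1
        p = m / M
        se = np.sqrt(p * (1 - p) / reps)
        frac = counts / reps
        assert np.abs(frac.mean() - p) < 3 * se
        assert (np.abs(frac - p) < 5 * se).mean() > 0.99


class TestCart:
    def test_single_class_gives_single_leaf(self):
        X = np.array([[0.0], [1.0], [2.0]])
        tree = fit_cart(X, np.array([1, 1, 1]))
        assert tree.n_nodes == 1
        assert tree.predict(X).tolist() == [1, 1, 1]

    def test_linearly_separable_depth_one(self):
        X = np.array([[0.0], [1.0], [2.0], [10.0], [11.0], [12.0]])
        y = np.array([-1, -1, -1, 1, 1, 1])
        tree = fit_cart(X, y)
        assert tree.n_nodes == 3  # one split, two leaves
        assert tree.threshold[0] == pytest.approx(6.0)
        assert accuracy(tree.predict(X), y) == 1.0

    def test_grows_to_purity_on_distinct_values(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(40, 6))
        y = rng.choice([-1, 1], size=40)
        tree = fit_cart(X, y)
        assert accuracy(tree.predict(X), y) == 1.0

    def test_max_depth_zero_is_majority_leaf(self):
        X = np.array([[0.0], [1.0], [2.0]])
        tree = fit_cart(X, np.array([-1, 1, 1]), max_depth=0)
        assert tree.n_nodes == 1 and tree.predict(X).tolist() == [1, 1, 1]

    def test_leaf_tie_resolves_to_ad(self):
        X = np.array([[0.0], [0.0]])  # unsplittable, 1 vs 1
        tree = fit_cart(X, np.array([-1, 1]))
        assert tree.predict(X).tolist() == [-1, -1]

    def test_agrees_with_sklearn_on_training_purity(self):
        # independent cross-check: both growers reach pure leaves
        from sklearn.tree import DecisionTreeClassifier

        rng = np.random.default_rng(11)
        X = rng.normal(size=(30, 4))
        y = rng.choice([-1, 1], size=30)
        ours = fit_cart(X, y).predict(X)
        theirs = DecisionTreeClassifier(random_state=0).fit(X, y).predict(X)
        assert np.array_equal(ours, theirs)

    def test_empty_sample_set_raises(self):
        with pytest.raises(ValueError):
            fit_cart(np.empty((0, 2)), np.array([], dtype=int))


class TestMajorityVote:
    def _forest_with_trees(self, trees):
        model = MultimodalRandomForestClassifier(n_estimators=len(trees))
        model.trees_ = trees
        model.n_features_in_ = 1
        model.classes_ = np.array([-1, 1])
        model.m_ = 1
        return model

    def test_strict_majority(self):
        model = self._forest_with_trees([leaf_tree(-1), leaf_tree(-1), leaf_tree(1)])
        assert model.predict(np.zeros((2, 1))).tolist() == [-1, -1]

    def test_unanimous_positive(self):
        model = self._forest_with_trees([leaf_tree(1), leaf_tree(1)])
        assert model.predict(np.zeros((1, 1))).tolist() == [1]

    def test_exact_tie_resolves_to_ad_and_is_counted(self):
        model = self._forest_with_trees([leaf_tree(1), leaf_tree(-1)])
        assert model.predict(np.zeros((3, 1))).tolist() == [-1, -1, -1]
        assert model.n_tie_votes_ == 3

    def test_tree_order_never_changes_predictions(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(20, 10))
        y = rng.choice([-1, 1], size=20)
        model = MultimodalRandomForestClassifier(n_estimators=15, random_state=1).fit(X, y)
        base = model.predict(X)
        rng.shuffle(model.trees_)
        assert np.array_equal(model.predict(X), base)

    def test_single_tree_forest_equals_its_tree(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(16, 6))
        y = rng.choice([-1, 1], size=16)
        model = MultimodalRandomForestClassifier(n_estimators=1, random_state=5).fit(X, y)
        assert np.array_equal(model.predict(X), model.trees_[0].predict(X))


class TestForestEstimator:
    def test_rejects_bad_labels(self):
        with pytest.raises(ValueError, match="-1"):
            MultimodalRandomForestClassifier(n_estimators=2).fit(
                np.zeros((4, 2)), np.array([0, 1, 0, 1])
            )

    def test_fit_is_deterministic_given_random_state(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(24, 12))
        y = rng.choice([-1, 1], size=24)
        a = MultimodalRandomForestClassifier(n_estimators=20, random_state=7).fit(X, y)
        b = MultimodalRandomForestClassifier(n_estimators=20, random_state=7).fit(X, y)
        for ta, tb in zip(a.trees_, b.trees_):
            assert np.array_equal(ta.feature_subset, tb.feature_subset)
            assert np.array_equal(ta.sample_indices, tb.sample_indices)
            assert np.array_equal(ta.threshold, tb.threshold)

    def test_sklearn_params_interface(self):
        model = MultimodalRandomForestClassifier(n_estimators=5)
        assert model.get_params()["n_estimators"] == 5
        model.set_params(n_estimators=9)
        assert model.n_estimators == 9

    def test_separates_one_informative_column(self):
        rng = np.random.default_rng(21)
        n = 40
        y = np.array([-1] * 20 + [1] * 20)
        X = rng.normal(size=(n, 9))
        X[:, 4] = np.where(y == -1, 1.0, -1.0) + 0.05 * rng.normal(size=n)
        model = MultimodalRandomForestClassifier(
            n_estimators=50, max_features=3, random_state=0
        ).fit(X, y)
        assert model.score(X, y) == 1.0


class TestTreeCountScan:
    def _data(self):
        rng = np.random.default_rng(13)
        y = np.array([-1] * 20 + [1] * 20)
        X = rng.normal(size=(40, 30))
        X[:, 3] = y + 0.3 * rng.normal(size=40)
        return X[:24], y[:24], X[24:], y[24:]

    def test_default_grid_has_sixty_points(self):
        counts = np.arange(10, 601, 10)
        assert len(counts) == 60

    def test_curve_shape_and_determinism(self):
        Xtr, ytr, Xte, yte = self._data()
        c1 = scan_tree_counts(Xtr, ytr, Xte, yte, 10, 50, 10, seed=4)
        c2 = scan_tree_counts(Xtr, ytr, Xte, yte, 10, 50, 10, seed=4)
        assert c1.tree_counts.tolist() == [10, 20, 30, 40, 50]
        assert np.array_equal(c1.accuracies, c2.accuracies)

    def test_single_point_grid(self):
        Xtr, ytr, Xte, yte = self._data()
        c = scan_tree_counts(Xtr, ytr, Xte, yte, 10, 10, 10, seed=0)
        assert len(c.accuracies) == 1

    def test_degenerate_grid_raises(self):
        Xtr, ytr, Xte, yte = self._data()
        with pytest.raises(ValueError):
            scan_tree_counts(Xtr, ytr, Xte, yte, 5, 50, 10, seed=0)


class TestStableCount:
    def test_constant_curve_returns_first_point(self):
        curve = AccuracyCurve(np.arange(10, 101, 10), np.full(10, 0.8))
        assert select_stable_count(curve) == 10

    def test_step_curve_returns_step_point(self):
        acc = np.array([0.5] * 6 + [0.8] * 14)
        curve = AccuracyCurve(np.arange(10, 201, 10), acc)
        assert select_stable_count(curve) == 70

    def test_transient_spike_is_ignored(self):
        acc = np.full(20, 0.8)
        acc[10] = 0.86  # single-point fluctuation above the plateau
        curve = AccuracyCurve(np.arange(10, 201, 10), acc)
        assert select_stable_count(curve) == 10

    def test_noisy_plateau_detection(self):
        rng = np.random.default_rng(17)
        hits = 0
        for _ in range(100):
            counts = np.arange(10, 301, 10)
            base = np.minimum(0.85, 0.5 + counts / 400)
            acc = np.clip(base + rng.normal(0, 0.005, len(counts)), 0, 1)
            chosen = select_stable_count(AccuracyCurve(counts, acc))
            if base[np.flatnonzero(counts == chosen)[0]] >= 0.80:
                hits += 1
        assert hits >= 95

    def test_short_curve_raises(self):
        with pytest.raises(ValueError):
            select_stable_count(AccuracyCurve(np.array([10, 20]), np.array([0.5, 0.5])))
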