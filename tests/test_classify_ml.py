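"""Decision-tree machinery against brute-force oracles and planted boundaries."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.tree import DecisionTreeClassifier

from oceandeg.classify_ml import (
    CVResult,
    decision_regions,
    fit_tree,
    gini_impurity,
    predict,
    predict_many,
    stratified_cv,
    training_accuracy,
)
from oceandeg.degradation_metrics import Tier3
from oceandeg.synthetic_data import (
    SimulationConfig,
    default_planted_rule,
    feature_matrix,
    simulate_polymers,
)


class TestGiniImpurity:
    def test_pure_node_is_zero(self):
        assert gini_impurity([17, 0, 0]) == 0.0

    def test_uniform_three_classes(self):
        assert gini_impurity([1, 1, 1]) == pytest.approx(2.0 / 3.0)

    @given(st.lists(st.integers(min_value=0, max_value=500), min_size=3, max_size=3))
    @settings(deadline=None)
    def test_matches_direct_formula(self, counts):
        if sum(counts) == 0:
            with pytest.raises(ValueError):
                gini_impurity(counts)
            return
        total = sum(counts)
        expected = 1.0 - sum((c / total) ** 2 for c in counts)
        value = gini_impurity(counts)
        assert value == pytest.approx(expected, abs=1e-12)
        assert 0.0 <= value <= 2.0 / 3.0 + 1e-15


# ---------------------------------------------------------------------------
# independent brute-force reimplementation of the greedy split search
# (plain python, recomputes impurity from scratch at every candidate)

def _oracle_gini(labels):
    n = len(labels)
    return 1.0 - sum((labels.count(c) / n) ** 2 for c in (0, 1, 2))


def _oracle_best_split(rows, labels):
    n = len(labels)
    parent = _oracle_gini(labels)
    best, best_gain = None, 0.0
    n_features = len(rows[0])
    for f in range(n_features):
        values = sorted(set(r[f] for r in rows))
        for lo, hi in zip(values, values[1:]):
            thr = (lo + hi) / 2.0
            left = [y for r, y in zip(rows, labels) if r[f] < thr]
            right = [y for r, y in zip(rows, labels) if r[f] >= thr]
            if not left or not right:
                continue
            gain = parent - (len(left) * _oracle_gini(left) + len(right) * _oracle_gini(right)) / n
            if gain > best_gain + 1e-12:
                best, best_gain = (f, thr), gain
    return best


def _oracle_tree_accuracy(rows, labels, depth):
    """Training accuracy of the greedy Gini tree, recomputed independently."""
    if depth == 0 or _oracle_gini(labels) == 0.0:
        majority = max((0, 1, 2), key=lambda c: (labels.count(c), -c))
        return labels.count(majority)
    split = _oracle_best_split(rows, labels)
    if split is None:
        majority = max((0, 1, 2), key=lambda c: (labels.count(c), -c))
        return labels.count(majority)
    f, thr = split
    left = [(r, y) for r, y in zip(rows, labels) if r[f] < thr]
    right = [(r, y) for r, y in zip(rows, labels) if r[f] >= thr]
    return (
        _oracle_tree_accuracy([r for r, _ in left], [y for _, y in left], depth - 1)
        + _oracle_tree_accuracy([r for r, _ in right], [y for _, y in right], depth - 1)
    )


class TestFitTree:
    def test_single_class_gives_root_leaf(self):
        X = np.array([[1.0], [2.0], [3.0]])
        y = [Tier3.slow] * 3
        model = fit_tree(X, y, feature_names=("Tg",), max_depth=2)
        assert model.root.is_leaf
        assert model.root.prediction == Tier3.slow

    def test_separable_toy_splits_at_midpoint(self):
        X = np.array([[1.0], [2.0], [10.0], [11.0]])
        y = [Tier3.slow, Tier3.slow, Tier3.fast, Tier3.fast]
        model = fit_tree(X, y, feature_names=("Mn",), max_depth=2)
        assert model.root.threshold == pytest.approx(6.0)
        assert training_accuracy(model, X, y) == 100.0

    def test_identical_features_mixed_labels_single_leaf(self):
        X = np.ones((4, 2))
        y = [Tier3.slow, Tier3.fast, Tier3.slow, Tier3.medium]
        with pytest.warns(UserWarning, match="single-leaf"):
            model = fit_tree(X, y, feature_names=("Mn", "Tg"), max_depth=2)
        assert model.root.is_leaf
        assert model.root.prediction == Tier3.slow  # tie broken toward slower

    def test_parent_counts_equal_children_sum(self):
        records, labels = simulate_polymers(
            SimulationConfig(n=60, seed=8), default_planted_rule(0.1)
        )
        X = feature_matrix(records, ["Tg", "Mn"])
        model = fit_tree(X, labels, feature_names=("Tg", "Mn"), max_depth=3)

        def _check(node):
            if node.is_leaf:
                return
            assert np.array_equal(node.counts, node.left.counts + node.right.counts)
            _check(node.left)
            _check(node.right)

        _check(model.root)

    @pytest.mark.parametrize("depth", [1, 2])
    def test_matches_brute_force_oracle_on_random_small_datasets(self, depth):
        """Optimized split search equals a from-scratch enumeration on <=20 records."""
        rng = np.random.default_rng(1234)
        for _ in range(40):
            n = int(rng.integers(4, 21))
            p = int(rng.integers(1, 4))
            X = rng.integers(0, 8, size=(n, p)).astype(float)
            y = rng.integers(0, 3, size=n)
            model = fit_tree(X, y, feature_names=tuple(f"f{i}" for i in range(p)), max_depth=depth)
            ours = training_accuracy(model, X, y) * n / 100.0
            oracle = _oracle_tree_accuracy([tuple(r) for r in X], list(map(int, y)), depth)
            assert ours == pytest.approx(oracle)

    def test_depth_three_never_increases_training_errors(self):
        rng = np.random.default_rng(55)
        for _ in range(10):
            X = rng.normal(size=(40, 3))
            y = rng.integers(0, 3, size=40)
            names = ("Mn", "enthalpy", "Tg")
            acc2 = training_accuracy(fit_tree(X, y, names, max_depth=2), X, y)
            acc3 = training_accuracy(fit_tree(X, y, names, max_depth=3), X, y)
            assert acc3 >= acc2 - 1e-9

    def test_agrees_with_sklearn_on_separable_data(self):
        records, labels = simulate_polymers(
            SimulationConfig(n=150, seed=21), default_planted_rule(0.0)
        )
        X = feature_matrix(records, ["Tg", "Mn"])
        y = np.array([int(v) for v in labels])
        ours = training_accuracy(fit_tree(X, y, ("Tg", "Mn"), max_depth=2), X, y)
        ref = DecisionTreeClassifier(criterion="gini", max_depth=2, random_state=0).fit(X, y)
        assert ours == pytest.approx(100.0 * ref.score(X, y)) == 100.0


class TestPredict:
    def test_threshold_routes_right_on_equality(self):
        X = np.array([[1.0], [3.0]])
        y = [Tier3.slow, Tier3.fast]
        model = fit_tree(X, y, feature_names=("Tg",), max_depth=1)
        assert model.root.threshold == pytest.approx(2.0)
        assert predict(model, [2.0]) == Tier3.fast  # >= goes right

    def test_missing_feature_rejected(self):
        model = fit_tree(np.array([[1.0], [3.0]]), [0, 2], feature_names=("Tg",), max_depth=1)
        with pytest.raises(ValueError, match="missing"):
            predict(model, [np.nan])

    def test_planted_threshold_recovery_within_sample_spacing(self):
        rule = default_planted_rule(label_noise=0.03)
        records, labels = simulate_polymers(SimulationConfig(n=200, seed=2020), rule)
        X = feature_matrix(records, ["Tg", "Mn"])
        model = fit_tree(X, labels, feature_names=("Tg", "Mn"), max_depth=2)
        assert model.root.feature == "Tg"
        tg = np.sort(X[:, 0])
        below = tg[tg < 25.0].max()
        above = tg[tg >= 25.0].min()
        spacing = above - below
        assert abs(model.root.threshold - 25.0) <= spacing


class TestStratifiedCV:
    def _planted(self, n, noise, seed):
        records, labels = simulate_polymers(
            SimulationConfig(n=n, seed=seed), default_planted_rule(noise)
        )
        return feature_matrix(records, ["Tg", "Mn"]), np.array([int(v) for v in labels])

    def test_noiseless_planted_data_scores_near_100(self):
        # holdout points adjacent to the planted boundary can fall on the wrong
        # side of a threshold refit without them, so "separable" means at most
        # a boundary-straddling point or two per fold, not literally 100%
        X, y = self._planted(200, 0.0, 31)
        result = stratified_cv(X, y, k=10, seed=1, feature_names=("Tg", "Mn"))
        assert result.mean_accuracy >= 99.0
        assert sorted(result.fold_accuracies)[len(result.fold_accuracies) // 2] == 100.0

    def test_label_permuted_data_near_chance(self):
        rng = np.random.default_rng(17)
        X = rng.normal(size=(300, 2))
        y = np.repeat([0, 1, 2], 100)
        result = stratified_cv(X, y, k=10, seed=5, feature_names=("Tg", "Mn"))
        assert abs(result.mean_accuracy - 100.0 / 3.0) < 12.0  # ~3 sigma of fold sampling

    def test_deterministic_given_seed(self):
        X, y = self._planted(100, 0.1, 7)
        a = stratified_cv(X, y, k=5, seed=42, feature_names=("Tg", "Mn"))
        b = stratified_cv(X, y, k=5, seed=42, feature_names=("Tg", "Mn"))
        assert a.fold_accuracies == b.fold_accuracies
        assert a.mean_accuracy == pytest.approx(np.mean(a.fold_accuracies))

    def test_fold_class_proportions_within_one_sample(self):
        from sklearn.model_selection import StratifiedKFold

        X, y = self._planted(200, 0.0, 31)
        for _, test_idx in StratifiedKFold(5, shuffle=True, random_state=0).split(X, y):
            counts = np.bincount(y[test_idx], minlength=3)
            expected = np.bincount(y, minlength=3) / 5.0
            assert np.all(np.abs(counts - expected) <= 1.0)

    def test_invalid_k(self):
        X, y = self._planted(20, 0.0, 2)
        with pytest.raises(ValueError):
            stratified_cv(X, y, k=1)
        with pytest.raises(ValueError):
            stratified_cv(X, y, k=50)

    def test_safety_no_extreme_confusion_on_separated_classes(self):
        """Well-separated classes never confuse fast with slow in either direction."""
        X, y = self._planted(200, 0.0, 77)
        model = fit_tree(X, y, feature_names=("Tg", "Mn"), max_depth=2)
        pred = predict_many(model, X)
        assert not np.any((y == int(Tier3.fast)) & (pred == int(Tier3.slow)))
        assert not np.any((y == int(Tier3.slow)) & (pred == int(Tier3.fast)))


class TestDecisionRegions:
    def test_linearly_separable_training_points_correct(self):
        rng = np.random.default_rng(3)
        X = np.vstack([rng.normal(-2, 0.3, (20, 2)), rng.normal(2, 0.3, (20, 2))])
        y = np.array([0] * 20 + [2] * 20)
        clf = decision_regions(X, y)
        assert np.all(clf.predict(X) == y)

    def test_planted_boundary_sign_reproduced(self):
        records, labels = simulate_polymers(
            SimulationConfig(n=300, seed=13), default_planted_rule(0.0)
        )
        X = feature_matrix(records, ["Tg", "Mn"])
        clf = decision_regions(X, np.array([int(v) for v in labels]))
        # probe far on each side of the planted Tg=25 boundary at median Mn
        mn = float(np.median(X[:, 1]))
        assert clf.predict([[60.0, mn]])[0] == int(Tier3.slow)
        assert clf.predict([[-60.0, 3.0]])[0] == int(Tier3.fast)

    def test_degenerate_single_class_rejected(self):
        X = np.random.default_rng(0).normal(size=(10, 2))
        with pytest.raises(ValueError, match="single-class"):
            decision_regions(X, np.zeros(10, dtype=int))
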