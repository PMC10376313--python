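import numpy as np
import pytest

from stressbox.cart import (
    CartClassifier,
    CartTree,
    build_tree,
    gini_split,
    predict,
    predict_many,
)
from stressbox.errors import ParameterError, SchemaError
from stressbox.io_core import FeatureTable, load_model, save_model


def exhaustive_best_split(values, labels, impurity="paper"):
    """O(n^2) oracle: evaluate every threshold partition by direct counting."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n = len(values)
    best = None
    for theta in np.unique(values):
        below = labels[values < theta]
        above = labels[values >= theta]
        if len(below) == 0 or len(above) == 0:
            continue

        def side(y):
            n0 = int(np.sum(y == 0))
            n1 = int(np.sum(y == 1))
            return (n0 / len(y)) * (n1 / len(y))

        if impurity == "paper":
            total = side(below) + side(above)
        else:
            total = (len(below) / n) * 2 * side(below) + (len(above) / n) * 2 * side(above)
        if best is None or total < best[0] - 1e-15:
            best = (total, theta)
    return best


class TestGiniSplit:
    def test_separable_split_is_pure(self):
        res = gini_split([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert res.gini == 0.0
        assert res.cutoff_value == 0.8

    def test_single_class_flagged_pure(self):
        res = gini_split([1.0, 2.0, 3.0], [0, 0, 0])
        assert res.gini == 0.0 and res.pure

    def test_tied_boundaries_take_lowest_index(self):
        # boundaries after sorted positions 0/1/2 score 2/9, 1/2, 2/9
        res = gini_split([1.0, 2.0, 3.0, 4.0], [0, 1, 0, 1])
        assert res.gini == pytest.approx(2 / 9)
        assert res.cutoff_value == 2.0

    def test_partition_counts_match_direct_counting(self, rng):
        values = rng.uniform(size=40)
        labels = rng.integers(0, 2, size=40)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        res = gini_split(values, labels)
        below = labels[values < res.cutoff_value]
        assert 0 < len(below) < 40
        order = np.argsort(values, kind="stable")
        assert np.array_equal(np.sort(below), np.sort(labels[order][: res.cutoff_index]))

    @pytest.mark.parametrize("impurity", ["paper", "weighted"])
    @pytest.mark.parametrize("seed", range(25))
    def test_oracle_equivalence_random_instances(self, seed, impurity):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 31))
        values = np.round(rng.uniform(size=n), 2)  # duplicates likely
        labels = rng.integers(0, 2, size=n)
        oracle = exhaustive_best_split(values, labels, impurity)
        res = gini_split(values, labels, impurity=impurity)
        if labels.min() == labels.max():
            assert res.pure and res.gini == 0.0
        elif oracle is None:
            assert not res.valid
        else:
            assert res.gini == pytest.approx(oracle[0], abs=1e-12)

    def test_fixed_cutoff_option(self):
        res = gini_split([0.1, 0.4, 0.6, 0.9], [0, 0, 1, 1], fixed_cutoff=0.5)
        assert res.gini == 0.0
        assert res.cutoff_value == 0.5

    def test_bad_labels_rejected(self):
        with pytest.raises(SchemaError):
            gini_split([1.0, 2.0], [0, 2])


class TestBuildTree:
    def test_separable_one_feature_depth_one(self, rng):
        x = np.concatenate([rng.uniform(0, 0.4, 10), rng.uniform(0.6, 1.0, 10)])
        y = np.array([0] * 10 + [1] * 10)
        tree = build_tree(FeatureTable(["f"], x[:, None], y, "binary"))
        assert tree.depth() == 1
        assert np.array_equal(predict_many(tree, x[:, None]), y)

    def test_identical_features_majority_leaf(self):
        table = FeatureTable(
            ["f"], np.ones((4, 1)), np.array([0, 0, 0, 1]), "binary"
        )
        tree = build_tree(table)
        assert tree.root.is_leaf
        assert tree.root.label == 0

    def test_xor_needs_depth_two(self):
        x = np.array([[0, 0], [0, 1], [1, 0], [1, 1.0]] * 5)
        y = np.array([0, 1, 1, 0] * 5)
        table = FeatureTable(["a", "b"], x, y, "binary")
        deep = build_tree(table, max_depth=2)
        assert np.mean(predict_many(deep, x) == y) == 1.0
        shallow = build_tree(table, max_depth=1)
        assert np.mean(predict_many(shallow, x) == y) <= 0.75

    def test_memorizes_consistent_data(self, rng):
        x = rng.uniform(size=(40, 3))
        y = rng.integers(0, 2, size=40)
        table = FeatureTable(["a", "b", "c"], x, y, "binary")
        tree = build_tree(table, max_depth=100, min_samples_leaf=1)
        assert np.mean(predict_many(tree, x) == y) == 1.0

    def test_nonbinary_labels_rejected(self):
        table = FeatureTable(["f"], np.arange(6.0)[:, None], np.arange(6) % 3,
                             "five_class")
        with pytest.raises(SchemaError):
            build_tree(table)

    @pytest.mark.parametrize("seed", range(10))
    def test_monotone_transform_invariance(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.uniform(size=(30, 3))
        y = rng.integers(0, 2, size=30)
        table = FeatureTable(["a", "b", "c"], x, y, "binary")
        tree = build_tree(table, max_depth=4)
        warped = x.copy()
        warped[:, 1] = np.exp(3 * warped[:, 1])  # strictly increasing
        tree_w = build_tree(FeatureTable(["a", "b", "c"], warped, y, "binary"),
                            max_depth=4)
        assert np.array_equal(predict_many(tree, x), predict_many(tree_w, warped))


class TestPredict:
    def test_single_leaf(self):
        table = FeatureTable(["f"], np.zeros((3, 1)), np.array([1, 1, 1]), "binary")
        tree = build_tree(table)
        assert predict(tree, [42.0]) == 1

    def test_depth_one_threshold_routing(self, rng):
        x = np.array([[0.1], [0.2], [0.9], [1.0]])
        y = np.array([0, 0, 1, 1])
        tree = build_tree(FeatureTable(["f"], x, y, "binary"))
        assert predict(tree, [0.5]) == 0
        assert predict(tree, [0.9]) == 1

    def test_wrong_arity_rejected(self):
        table = FeatureTable(["a", "b"], np.eye(2), np.array([0, 1]), "binary")
        tree = build_tree(table)
        with pytest.raises(SchemaError):
            predict(tree, [1.0])

    def test_training_confusion_matrix_reproduced(self, rng):
        x = rng.uniform(size=(50, 2))
        y = (x[:, 0] + 0.3 * rng.standard_normal(50) > 0.5).astype(int)
        table = FeatureTable(["a", "b"], x, y, "binary")
        tree = build_tree(table, max_depth=3)
        pred = predict_many(tree, x)
        cm = np.zeros((2, 2), int)
        for t, p in zip(y, pred):
            cm[t, p] += 1
        assert cm.sum() == 50
        assert cm[0, 0] + cm[1, 1] == int(np.sum(pred == y))


def test_tree_json_roundtrip(tmp_path, rng):
    x = rng.uniform(size=(30, 3))
    y = rng.integers(0, 2, size=30)
    table = FeatureTable(["a", "b", "c"], x, y, "binary")
    tree = build_tree(table, max_depth=4)
    p = tmp_path / "tree.json"
    save_model(tree, p)
    back = load_model(p)
    assert isinstance(back, CartTree)
    assert np.array_equal(predict_many(back, x), predict_many(tree, x))


def test_sklearn_front_end_clones_and_fits(rng):
    x = np.concatenate([rng.normal(0, 0.2, (20, 2)), rng.normal(2, 0.2, (20, 2))])
    y = np.array([0] * 20 + [1] * 20)
    clf = CartClassifier(max_depth=3).fit(x, y)
    assert np.mean(clf.predict(x) == y) == 1.0
    assert clf.get_params()["impurity"] == "paper"
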