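import itertools

import numpy as np
import pytest
from sklearn.base import clone
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import MinMaxScaler

from stressbox.errors import ParameterError, UnlabeledSampleError
from stressbox.io_core import FeatureTable
from stressbox.label_eval import (
    LabelRuleSet,
    classification_metrics,
    cross_validate,
    is_significant,
    learning_curve,
    make_model,
    pipeline_grid_search,
    rule_label_binary,
    ttest_groups,
)
from stressbox.synthetic import synth_feature_table


def neutral_features(**overrides):
    base = {
        "MeanHR": 70.0, "LF_Lomb": 500.0, "HF_Lomb": 400.0, "ApEN": 0.5,
        "SD1": 0.05, "SD2": 0.08, "PNN50": 0.2, "RMSSD": 0.05,
        "GSR_mean": 3.0, "LFHF_Lomb": 2.5, "RESP_rate": 25.0,
    }
    base.update(overrides)
    return base


class TestRuleLabeling:
    def test_clear_stress_profile(self):
        baseline = neutral_features()
        feats = neutral_features(
            LFHF_Lomb=3.5, RESP_rate=26.0, HF_Lomb=300.0, LF_Lomb=600.0, ApEN=0.7
        )
        assert rule_label_binary(feats, baseline) == 1

    def test_clear_relax_profile(self):
        baseline = neutral_features()
        feats = neutral_features(LFHF_Lomb=0.9, RESP_rate=12.0)
        assert rule_label_binary(feats, baseline) == 0

    def test_all_rules_abstaining_raises(self):
        feats = neutral_features()  # LF/HF 2.5 and RESP exactly 25 both abstain
        with pytest.raises(UnlabeledSampleError):
            rule_label_binary(feats, neutral_features())

    def test_absolute_rules_work_without_baseline(self):
        assert rule_label_binary(neutral_features(LFHF_Lomb=4.0, RESP_rate=30.0)) == 1

    def test_tie_resolves_to_relaxed(self):
        feats = neutral_features(LFHF_Lomb=3.5, RESP_rate=12.0)
        assert rule_label_binary(feats) == 0

    def test_custom_ruleset_threshold(self):
        rules = LabelRuleSet(resp_threshold=20.0)
        assert rule_label_binary(neutral_features(RESP_rate=22.0), rules=rules) == 1


class TestTTest:
    def test_identical_groups(self):
        t, p = ttest_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == 1.0

    def test_separated_groups_significant(self):
        _, p = ttest_groups([0.0, 0.1, 0.05], [10.0, 10.1, 9.9])
        assert p < 1e-4 and is_significant(p)

    def test_degenerate_constant_groups(self):
        _, p_same = ttest_groups([2.0, 2.0], [2.0, 2.0])
        _, p_diff = ttest_groups([2.0, 2.0], [5.0, 5.0])
        assert p_same == 1.0 and p_diff == 0.0

    def test_group_too_small_rejected(self):
        with pytest.raises(ParameterError):
            ttest_groups([1.0], [1.0, 2.0])


class TestClassificationMetrics:
    def test_perfect_prediction(self):
        rep = classification_metrics([0, 1, 2, 3], [0, 1, 2, 3], "five_class")
        assert rep.accuracy == 1.0 and rep.mse == 0.0 and rep.r2 == 1.0

    def test_mse_of_ordinal_labels(self):
        rep = classification_metrics([0, 1, 2], [0, 1, 4], "five_class")
        assert rep.mse == pytest.approx(4 / 3)

    def test_constant_mean_prediction_gives_zero_r2(self):
        rep = classification_metrics([0, 1, 2], [1, 1, 1], "five_class")
        assert rep.r2 == pytest.approx(0.0, abs=1e-12)

    def test_exhaustive_small_confusion_tables(self):
        # every 2x2 confusion table with cell counts <= 5 against hand formulas
        for tn, fp, fn, tp in itertools.product(range(3), repeat=4):
            if tn + fp + fn + tp == 0:
                continue
            y_true = [0] * (tn + fp) + [1] * (fn + tp)
            y_pred = [0] * tn + [1] * fp + [0] * fn + [1] * tp
            rep = classification_metrics(y_true, y_pred, "binary")
            assert rep.accuracy == pytest.approx((tn + tp) / len(y_true))
            if tp + fp:
                assert rep.precision == pytest.approx(tp / (tp + fp))
            else:
                assert np.isnan(rep.precision)
            if tp + fn:
                assert rep.recall == pytest.approx(tp / (tp + fn))
            else:
                assert np.isnan(rep.recall)


class TestCrossValidate:
    def test_separable_data_near_perfect_accuracy(self):
        # with cutoffs at observed feature values, the held-out extreme of
        # the positive class can be misrouted, so CV accuracy on separable
        # data is bounded by (n - folds) / n rather than exactly 1
        table = synth_feature_table(25, np.array([[0, 0], [3, 3.0]]), 0.1, seed=0)
        for folds in (5, 10):
            rep = cross_validate("cart", table, folds=folds, seed=0)
            assert rep.accuracy >= 1.0 - folds / table.n_samples

    def test_uninformative_features_score_near_chance(self, rng):
        values = rng.standard_normal((200, 4))
        labels = np.tile([0, 1], 100)
        table = FeatureTable(["a", "b", "c", "d"], values, labels, "binary")
        rep = cross_validate("cart", table, folds=5, seed=0)
        assert 0.35 <= rep.accuracy <= 0.65

    def test_too_many_folds_rejected(self):
        table = synth_feature_table(3, np.array([[0.0], [2.0]]), 0.1, seed=0)
        with pytest.raises(ParameterError):
            cross_validate("cart", table, folds=7, seed=0)

    def test_stratified_folds_preserve_class_ratio(self):
        labels = np.array([0] * 30 + [1] * 20)
        skf = StratifiedKFold(n_splits=5, shuffle=True, random_state=0)
        for _, test_idx in skf.split(np.zeros((50, 1)), labels):
            n1 = labels[test_idx].sum()
            assert abs(n1 - 4) <= 1  # 20/5 = 4 positives per fold, within 1


class TestPipelineGridSearch:
    def test_single_point_grid_matches_plain_cv(self):
        table = synth_feature_table(25, np.array([[0, 0, 0], [2, 2, 2.0]]), 0.4, seed=1)
        pipe = Pipeline(
            [("scale", MinMaxScaler()), ("model", make_model("cart"))]
        )
        direct = cross_validate(clone(pipe), table, folds=5, seed=0)
        grid = pipeline_grid_search(
            table, "cart", {"model__max_depth": [5]}, folds=5, seed=0
        )
        assert grid.accuracy == pytest.approx(direct.accuracy, abs=1e-12)

    def test_chi2_selects_the_informative_feature(self, rng):
        n = 60
        informative = np.tile([0.0, 1.0], n // 2)
        noise = rng.uniform(size=(n, 5))
        values = np.column_stack([informative, noise])
        table = FeatureTable([f"f{j}" for j in range(6)], values,
                             informative.astype(int), "binary")
        rep = pipeline_grid_search(
            table, "cart", {"model__max_depth": [1]}, folds=5, seed=0, select_k=1
        )
        assert rep.accuracy == 1.0

    def test_empty_grid_rejected(self):
        table = synth_feature_table(10, np.array([[0.0], [2.0]]), 0.2, seed=0)
        with pytest.raises(ParameterError):
            pipeline_grid_search(table, "cart", {}, folds=5, seed=0)

    def test_scaler_statistics_fit_per_fold(self, rng):
        # leak-freedom: the scaler fitted inside each fold sees different data
        values = np.sort(rng.uniform(size=(40, 2)), axis=0)
        labels = np.tile([0, 1], 20)
        mins = []
        skf = StratifiedKFold(n_splits=5, shuffle=True, random_state=0)
        for train_idx, _ in skf.split(values, labels):
            scaler = MinMaxScaler().fit(values[train_idx])
            mins.append(tuple(np.round(scaler.data_min_, 12)))
        assert len(set(mins)) > 1


class TestLearningCurve:
    def test_full_fraction_memorizes_consistent_data(self):
        table = synth_feature_table(30, np.array([[0, 0], [2, 2.0]]), 0.3, seed=0)
        model = make_model("cart")
        model.set_params(max_depth=100)
        train, val = learning_curve(model, table, [1.0], seed=0)
        assert train[0] == 1.0

    def test_training_score_dominates_validation(self):
        table = synth_feature_table(40, np.array([[0, 0], [1, 1.0]]), 0.8, seed=2)
        model = make_model("cart")
        model.set_params(max_depth=100)
        fracs = [0.4, 0.6, 0.8, 1.0]
        train, val = learning_curve(model, table, fracs, seed=0)
        assert len(train) == len(val) == len(fracs)
        assert np.nanmean(train) >= np.nanmean(val)

    def test_bad_fraction_rejected(self):
        table = synth_feature_table(10, np.array([[0.0], [2.0]]), 0.2, seed=0)
        with pytest.raises(ParameterError):
            learning_curve("cart", table, [0.0, 0.5], seed=0)


class TestModelRegistry:
    def test_boosting_adapter_uses_study_hyperparameters(self):
        egb = make_model("egb")
        params = egb.get_params()
        assert params["learning_rate"] == 1.0
        assert params["n_estimators"] == 100
        assert params["max_depth"] == 1

    def test_svm_adapter_polynomial_degree_three(self):
        svm = make_model("svm")
        assert svm.get_params()["kernel"] == "poly"
        assert svm.get_params()["degree"] == 3

    def test_unknown_model_rejected(self):
        with pytest.raises(ParameterError):
            make_model("mystery")

    def test_xgboost_adapter_fits_five_classes(self):
        centers = np.arange(10.0).reshape(5, 2)
        table = synth_feature_table(8, centers, 0.1, "five_class", seed=0)
        model = make_model("xgb", seed=0)
        model.fit(table.values, table.labels)
        assert np.mean(model.predict(table.values) == table.labels) == 1.0
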