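"""Feature selection, LOSO splitting, elasticnet models and study metrics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import gdmkin.models as mdl
from gdmkin.models import (
    EvalReport,
    ModelConfig,
    evaluate,
    fit_predict_regressor,
    loso_evaluate,
    loso_splits,
    select_features_maxcorr,
)

FAST = ModelConfig(regularization_grid=(0.1,))


def make_table(rng, n_subjects=15, gap=3.0, n_features=8, visits_per_subject=1):
    """Synthetic subject-level feature table with 3 ordered classes."""
    groups = ["CTR", "pHD", "HD"]
    rows = []
    for i in range(n_subjects):
        group = groups[i % 3]
        rank = {"CTR": 0, "pHD": 1, "HD": 2}[group]
        for _ in range(visits_per_subject):
            row = {"subject_id": f"S{i}", "group": group, "rank": rank}
            for j in range(n_features):
                signal = rank * gap if j < 3 else 0.0
                row[f"f{j}"] = signal + rng.standard_normal()
            row["score"] = 10.0 * rank + rng.normal(0, 0.5)
            rows.append(row)
    return pd.DataFrame(rows)


class TestSelection:
    def test_feature_equal_to_target_ranked_first(self, rng):
        X = pd.DataFrame({"noise": rng.standard_normal(30), "exact": np.arange(30.0)})
        y = np.arange(30.0)
        assert select_features_maxcorr(X, y, 1) == ["exact"]

    def test_k_equals_all_is_identity(self, rng):
        X = pd.DataFrame(rng.standard_normal((20, 4)), columns=list("abcd"))
        y = rng.standard_normal(20)
        assert sorted(select_features_maxcorr(X, y, 4)) == list("abcd")

    def test_matches_brute_force_abs_rho_sort(self, rng):
        X = pd.DataFrame(rng.standard_normal((40, 10)), columns=[f"f{i}" for i in range(10)])
        y = rng.standard_normal(40)
        got = select_features_maxcorr(X, y, 5)
        scored = sorted(
            ((abs(sps.spearmanr(X[c], y).statistic), c) for c in X.columns),
            key=lambda t: (-t[0], t[1]),
        )
        assert got == [c for _, c in scored[:5]]

    def test_constant_feature_excluded_with_warning(self, rng):
        X = pd.DataFrame({"const": np.ones(20), "ok": rng.standard_normal(20)})
        with pytest.warns(UserWarning, match="constant feature"):
            assert select_features_maxcorr(X, rng.standard_normal(20), 1) == ["ok"]


class TestLosoSplits:
    def test_one_fold_per_subject(self):
        folds = loso_splits(np.array(["a", "b", "c", "d", "e"]))
        assert len(folds) == 5
        assert all(len(test) == 1 for _, test in folds)

    def test_repeat_visits_stay_in_test_fold(self):
        folds = loso_splits(np.array(["a", "b", "a", "c"]))
        test_sets = {tuple(test) for _, test in folds}
        assert (0, 2) in test_sets  # both of subject a's visits together

    def test_partition_property(self, rng):
        subjects = rng.choice(list("abcdefg"), size=25)
        folds = loso_splits(subjects)
        all_test = np.concatenate([test for _, test in folds])
        assert sorted(all_test) == list(range(25))
        for train, test in folds:
            assert not set(train) & set(test)

    def test_single_subject_rejected(self):
        with pytest.raises(ValueError):
            loso_splits(np.array(["a", "a"]))


class TestClassifier:
    def test_separable_classes_perfect_loso(self, rng):
        table = make_table(rng, n_subjects=15, gap=8.0)
        _, report = loso_evaluate(table, [f"f{i}" for i in range(8)], "group", "classification", config=FAST)
        assert report.balanced_accuracy == 1.0

    def test_visits_follow_subject(self, rng):
        table = make_table(rng, n_subjects=9, gap=8.0, visits_per_subject=2)
        preds, report = loso_evaluate(
            table, [f"f{i}" for i in range(8)], "group", "classification", config=FAST
        )
        assert len(preds) == 18
        assert report.balanced_accuracy > 0.9

    def test_selection_never_sees_test_rows(self, rng, monkeypatch):
        """Instrumented leakage check: every selection call runs on exactly
        the training rows of its fold."""
        table = make_table(rng, n_subjects=9, gap=5.0, visits_per_subject=2)
        sizes = []
        original = mdl.select_features_maxcorr

        def spy(X, y, k):
            sizes.append(len(X))
            return original(X, y, k)

        monkeypatch.setattr(mdl, "select_features_maxcorr", spy)
        loso_evaluate(table, [f"f{i}" for i in range(8)], "group", "classification", config=FAST)
        assert sizes == [16] * 9  # 18 rows minus the held-out subject's 2 visits

    def test_shuffled_labels_fall_to_chance(self, rng):
        """Permutation null: mean LOSO balanced accuracy over label shuffles
        sits within 0.05 of the 3-class chance level 1/3."""
        table = make_table(rng, n_subjects=30, gap=0.0)
        feature_cols = [f"f{i}" for i in range(8)]
        cfg = ModelConfig(regularization_grid=(0.1,), n_selected_features=3)
        bas = []
        for _ in range(60):
            shuffled = table.copy()
            shuffled["group"] = rng.permutation(shuffled["group"].to_numpy())
            _, report = loso_evaluate(shuffled, feature_cols, "group", "classification", config=cfg)
            bas.append(report.balanced_accuracy)
        assert abs(np.mean(bas) - 1 / 3) < 0.05

    def test_monotone_recovery_with_separation(self):
        """Widening the class separation never lowers mean LOSO balanced
        accuracy (averaged over 10 seeds)."""
        means = []
        for gap in (0.5, 1.5, 4.0):
            bas = []
            for seed in range(10):
                table = make_table(np.random.default_rng(seed), n_subjects=12, gap=gap)
                _, report = loso_evaluate(
                    table, [f"f{i}" for i in range(8)], "group", "classification", config=FAST
                )
                bas.append(report.balanced_accuracy)
            means.append(np.mean(bas))
        assert means[0] <= means[1] + 0.05 and means[1] <= means[2] + 0.05
        assert means[2] > means[0]

    def test_single_class_fold_constant_prediction(self, rng):
        X = pd.DataFrame(rng.standard_normal((4, 3)), columns=list("abc"))
        with pytest.warns(UserWarning, match="single-class"):
            preds, selected = mdl.fit_predict_classifier(X, np.array(["HD"] * 4), X.iloc[:2])
        assert list(preds) == ["HD", "HD"] and selected == []


class TestRegressor:
    def test_linear_target_recovered(self, rng):
        table = make_table(rng, n_subjects=15, gap=3.0)
        table["score"] = 2.0 * table["f0"] + 5.0
        cfg = ModelConfig(regularization_grid=(1e-4,), n_selected_features=3)
        preds, report = loso_evaluate(table, [f"f{i}" for i in range(8)], "score", "regression", config=cfg)
        assert report.r >= 0.99

    def test_pure_noise_target_has_no_explained_variance(self):
        evs = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            table = make_table(rng, n_subjects=12, gap=0.0)
            table["score"] = rng.standard_normal(len(table))
            _, report = loso_evaluate(
                table, [f"f{i}" for i in range(8)], "score", "regression", config=FAST
            )
            evs.append(report.explained_variance)
        assert np.mean(evs) <= 0.1

    def test_constant_target_flagged(self, rng):
        X = pd.DataFrame(rng.standard_normal((5, 3)), columns=list("abc"))
        with pytest.warns(UserWarning, match="constant training target"):
            preds, _ = fit_predict_regressor(X, np.full(5, 3.0), X.iloc[:2])
        assert list(preds) == [3.0, 3.0]


class TestEvaluate:
    def test_perfect_classification(self):
        y = np.array(["HD", "pHD", "CTR", "HD"])
        report = evaluate(y, y, "classification")
        assert report.balanced_accuracy == 1.0
        assert all(r == 1.0 for r in report.per_class_recall.values())
        np.testing.assert_allclose(np.diag(report.confusion.to_numpy()), 1.0)

    def test_balanced_accuracy_is_mean_recall(self, rng):
        y_true = np.array(["HD"] * 6 + ["pHD"] * 6 + ["CTR"] * 6)
        y_pred = rng.choice(["HD", "pHD", "CTR"], size=18)
        report = evaluate(y_true, y_pred, "classification")
        assert report.balanced_accuracy == pytest.approx(
            np.mean(list(report.per_class_recall.values()))
        )
        rows = report.confusion.sum(axis=1)
        np.testing.assert_allclose(rows, 1.0)

    def test_uniform_random_chance_level(self):
        """A uniformly random 3-class prediction scores 1/3 in expectation."""
        rng = np.random.default_rng(0)
        y_true = np.array(["HD"] * 10 + ["pHD"] * 10 + ["CTR"] * 10)
        bas = [
            evaluate(y_true, rng.choice(["HD", "pHD", "CTR"], size=30), "classification").balanced_accuracy
            for _ in range(200)
        ]
        assert abs(np.mean(bas) - 1 / 3) < 0.05

    def test_shifted_regression_metrics(self):
        y = np.arange(10.0)
        report = evaluate(y, y + 2.0, "regression")
        assert report.r == pytest.approx(1.0)
        assert report.explained_variance == pytest.approx(1.0)
        assert report.mae == pytest.approx(2.0)
        assert report.mse == pytest.approx(4.0)

    def test_model_config_validation(self):
        with pytest.raises(ValueError):
            ModelConfig(l1_ratio=1.5)
        with pytest.raises(ValueError):
            ModelConfig(regularization_grid=(0.0,))
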