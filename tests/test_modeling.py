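"""Modeling: SMOTE geometry, fold construction, training determinism,
grid-search rules, metric arithmetic and permutation importance."""

import numpy as np
import pandas as pd
import pytest

from breathfit import (
    CYCLE_FEATURE_NAMES,
    FoldPlan,
    ModelSpec,
    compute_metrics,
    evaluate,
    false_negative_rate,
    grid_search,
    make_folds,
    permutation_importance,
    smote_balance,
    train_classifier,
)
from breathfit.errors import ConfigError, ParameterError, TrainingError
from breathfit.modeling import predict_scores

FAMILIES = ("random_forest", "svm_rbf", "gradient_boosted_trees")


def _blobs(n_per_class=60, sep=8.0, seed=0, n_features=2):
    """Two well-separated Gaussian blobs: margin ≫ noise."""
    rng = np.random.default_rng(seed)
    X0 = rng.normal(0.0, 1.0, (n_per_class, n_features))
    X1 = rng.normal(sep, 1.0, (n_per_class, n_features))
    X = np.vstack([X0, X1])
    y = np.array(["fit"] * n_per_class + ["poor_fit"] * n_per_class, dtype=object)
    return X, y


def _toy_table(n_subjects=5, rows_per_subject=40, seed=0):
    """Feature-table-shaped frame with separable classes per subject."""
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_subjects):
        for i in range(rows_per_subject):
            label = "poor_fit" if i % 2 else "fit"
            mu = 3.0 if label == "poor_fit" else 0.0
            feats = dict(zip(CYCLE_FEATURE_NAMES, rng.normal(mu, 1.0, 22)))
            rows.append(
                {
                    "subject_id": f"S{s:02d}",
                    "session_id": "sess01",
                    "provenance": f"cycle[{i}]",
                    "label": label,
                    **feats,
                }
            )
    return pd.DataFrame(rows)


class TestSmote:
    def test_balances_exactly(self, rng):
        X = rng.normal(size=(100, 5))
        y = np.array(["fit"] * 60 + ["poor_fit"] * 40, dtype=object)
        Xb, yb = smote_balance(X, y, seed=3)
        _, counts = np.unique(yb, return_counts=True)
        assert list(counts) == [60, 60]

    def test_originals_unchanged_and_first(self, rng):
        X = rng.normal(size=(50, 4))
        y = np.array(["fit"] * 30 + ["poor_fit"] * 20, dtype=object)
        Xb, _ = smote_balance(X, y, seed=1)
        np.testing.assert_array_equal(Xb[:50], X)

    def test_synthetic_rows_on_minority_segments(self, rng):
        """Every synthetic row lies on a segment between a minority row and
        one of its k nearest minority neighbours (projection residual ≈ 0)."""
        X = rng.normal(size=(60, 3))
        y = np.array(["fit"] * 40 + ["poor_fit"] * 20, dtype=object)
        Xb, yb = smote_balance(X, y, k_neighbors=5, seed=7)
        minority = X[y == "poor_fit"]
        for r in Xb[60:]:
            best = np.inf
            for i in range(len(minority)):
                d = np.linalg.norm(minority - minority[i], axis=1)
                for j in np.argsort(d)[1:6]:
                    a, b = minority[i], minority[j]
                    ab = b - a
                    u = np.dot(r - a, ab) / np.dot(ab, ab)
                    if -1e-9 <= u <= 1 + 1e-9:
                        best = min(best, np.linalg.norm(r - (a + u * ab)))
            assert best < 1e-9

    def test_deterministic(self, rng):
        X = rng.normal(size=(50, 4))
        y = np.array(["fit"] * 30 + ["poor_fit"] * 20, dtype=object)
        a, _ = smote_balance(X, y, seed=5)
        b, _ = smote_balance(X, y, seed=5)
        np.testing.assert_array_equal(a, b)

    def test_errors(self, rng):
        X = rng.normal(size=(10, 2))
        with pytest.raises(TrainingError):
            smote_balance(X, np.array(["fit"] * 10, dtype=object))
        y = np.array(["fit"] * 7 + ["poor_fit"] * 3, dtype=object)
        with pytest.raises(ParameterError):
            smote_balance(X, y, k_neighbors=5)


class TestFolds:
    def test_loso_one_fold_per_subject(self):
        table = _toy_table(n_subjects=6)
        plan = make_folds(table, FoldPlan(scheme="loso"))
        assert len(plan.folds) == 6
        subjects = set(table["subject_id"])
        for _, held, test_idx in plan.folds:
            test_subj = set(table.iloc[test_idx]["subject_id"])
            train_subj = set(table.drop(table.index[test_idx])["subject_id"])
            assert test_subj == set(held)
            assert not (train_subj & set(held))
            assert train_subj | test_subj == subjects

    def test_kfold_sizes(self):
        table = _toy_table(n_subjects=5, rows_per_subject=40)  # 200 rows
        plan = make_folds(table, FoldPlan(scheme="kfold", k=5, seed=0))
        sizes = [len(idx) for _, _, idx in plan.folds]
        assert sizes == [40] * 5
        all_idx = np.sort(np.concatenate([idx for _, _, idx in plan.folds]))
        np.testing.assert_array_equal(all_idx, np.arange(200))

    def test_loso_single_subject_rejected(self):
        table = _toy_table(n_subjects=1)
        with pytest.raises(ConfigError):
            make_folds(table, FoldPlan(scheme="loso"))

    def test_group_loso(self):
        table = _toy_table(n_subjects=6)
        plan = make_folds(table, FoldPlan(scheme="loso", group_size=2))
        assert len(plan.folds) == 3
        assert all(len(held) == 2 for _, held, _ in plan.folds)


class TestTraining:
    @pytest.mark.parametrize("family", FAMILIES)
    def test_separable_blobs_perfect(self, family):
        X, y = _blobs()
        model = train_classifier(ModelSpec(family=family, seed=0), X, y)
        assert (model.predict(X) == (y == "poor_fit").astype(int)).all()

    @pytest.mark.parametrize("family", FAMILIES)
    def test_deterministic(self, family):
        X, y = _blobs(sep=2.0, seed=4)
        spec = ModelSpec(family=family, seed=11)
        a = train_classifier(spec, X, y)
        b = train_classifier(spec, X, y)
        np.testing.assert_array_equal(predict_scores(a, X), predict_scores(b, X))

    def test_single_class_rejected(self):
        X = np.zeros((10, 2))
        y = np.array(["fit"] * 10, dtype=object)
        with pytest.raises(TrainingError):
            train_classifier(ModelSpec(family="random_forest"), X, y)


class TestGridSearch:
    def test_single_point_returned(self):
        X, y = _blobs()
        spec = ModelSpec(family="random_forest", grid={"n_estimators": [50]})
        assert grid_search(spec, X, y, smote=False) == {"n_estimators": 50}

    def test_dominant_point_wins(self):
        """On XOR-structured labels depth-1 trees cannot beat depth-5 on any
        inner fold, so the deeper point must be selected."""
        rng = np.random.default_rng(2)
        X = rng.uniform(-1, 1, size=(240, 2))
        y = np.where(X[:, 0] * X[:, 1] > 0, "poor_fit", "fit").astype(object)
        spec = ModelSpec(
            family="random_forest",
            grid={"max_depth": [1, 5], "n_estimators": [50]},
        )
        assert grid_search(spec, X, y, smote=False)["max_depth"] == 5

    def test_tie_takes_first_in_order(self):
        """Perfectly separable data: every grid point scores 1.0, so the
        first point in documented grid order is returned."""
        X, y = _blobs(sep=10.0)
        spec = ModelSpec(
            family="random_forest", grid={"n_estimators": [100, 300], "max_depth": [None, 10]}
        )
        assert grid_search(spec, X, y, smote=False) == {
            "n_estimators": 100,
            "max_depth": None,
        }

    def test_empty_grid_rejected(self):
        with pytest.raises(ConfigError):
            ModelSpec(family="random_forest", grid={"n_estimators": []})


class TestMetrics:
    def test_confusion_counts_and_fn_rate(self):
        """TP=124, FN=12, TN=134, FP=0 → FN rate 8.8% (1 d.p.) and
        F1(poor_fit) = 248/260 ≈ 0.954."""
        y_true = np.array(["poor_fit"] * 136 + ["fit"] * 134, dtype=object)
        y_pred = np.array(
            ["poor_fit"] * 124 + ["fit"] * 12 + ["fit"] * 134, dtype=object
        )
        f1, auc, cm = compute_metrics(y_true, y_pred)
        np.testing.assert_array_equal(cm, [[124, 12], [0, 134]])
        assert round(100 * false_negative_rate(cm), 1) == 8.8
        assert f1 == pytest.approx(2 * 124 / (2 * 124 + 0 + 12), abs=1e-9)
        assert auc is None  # no scores supplied

    def test_perfect_prediction(self):
        y = np.array(["poor_fit", "fit", "poor_fit", "fit"], dtype=object)
        scores = np.array([0.9, 0.1, 0.8, 0.2])
        f1, auc, cm = compute_metrics(y, y, scores)
        assert f1 == 1.0 and auc == 1.0
        assert cm[0, 1] == 0 and cm[1, 0] == 0
        assert false_negative_rate(cm) == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ParameterError):
            compute_metrics(np.array(["fit"]), np.array(["fit", "fit"]))


class TestEvaluate:
    def test_separable_table_perfect_loso(self):
        table = _toy_table()
        report = evaluate(
            table,
            ModelSpec(family="random_forest", seed=0),
            FoldPlan(scheme="loso"),
        )
        assert len(report.folds) == 5
        assert report.f1_mean == 1.0
        for fold in report.folds:
            assert fold.f1 == 1.0 and fold.roc_auc == 1.0
            cm = np.asarray(fold.confusion)
            assert cm[0, 1] == 0 and cm[1, 0] == 0
            assert cm.sum() == fold.test_size

    def test_deterministic_report(self):
        table = _toy_table(seed=2)
        kwargs = dict(
            spec=ModelSpec(family="gradient_boosted_trees", seed=3),
            plan=FoldPlan(scheme="kfold", k=5, seed=3),
        )
        a = evaluate(table, kwargs["spec"], kwargs["plan"])
        b = evaluate(table, kwargs["spec"], kwargs["plan"])
        assert a.to_dict() == b.to_dict()

    def test_single_class_fold_auc_undefined(self):
        """A LOSO fold whose held-out subject saw only fit conditions gets
        roc_auc None while F1 is still computed."""
        table = _toy_table(n_subjects=3)
        table.loc[table["subject_id"] == "S00", "label"] = "fit"
        report = evaluate(
            table, ModelSpec(family="random_forest", seed=0), FoldPlan(scheme="loso")
        )
        fold0 = next(f for f in report.folds if f.test_subjects == ["S00"])
        assert fold0.roc_auc is None
        assert 0.0 <= fold0.f1 <= 1.0


class TestPermutationImportance:
    def test_signal_feature_ranks_first(self, rng):
        """A feature that alone determines the label dominates; pure-noise
        features sit near zero drop."""
        n = 300
        signal = np.concatenate([rng.normal(0, 1, n // 2), rng.normal(6, 1, n // 2)])
        noise = rng.normal(size=(n, 3))
        X = np.column_stack([signal, noise])
        y = np.array(["fit"] * (n // 2) + ["poor_fit"] * (n // 2), dtype=object)
        model = train_classifier(ModelSpec(family="random_forest", seed=0), X, y)
        imp = permutation_importance(
            model, X, y, feature_names=["signal", "n1", "n2", "n3"], n_repeats=10, seed=0
        )
        assert imp.iloc[0]["feature"] == "signal"
        for _, row in imp[imp["feature"] != "signal"].iterrows():
            assert abs(row["mean_drop"]) <= 2 * row["sd_drop"] + 1e-12

    def test_deterministic_ranking(self, rng):
        X = rng.normal(size=(120, 4))
        X[:, 0] += np.repeat([0.0, 2.0], 60)
        y = np.array(["fit"] * 60 + ["poor_fit"] * 60, dtype=object)
        model = train_classifier(ModelSpec(family="svm_rbf", seed=0), X, y)
        a = permutation_importance(model, X, y, n_repeats=5, seed=9)
        b = permutation_importance(model, X, y, n_repeats=5, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_invalid_repeats(self, rng):
        X, y = _blobs()
        model = train_classifier(ModelSpec(family="random_forest", seed=0), X, y)
        with pytest.raises(ConfigError):
            permutation_importance(model, X, y, n_repeats=0)
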