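"""SMOTE, scaling, boosted classifier, CV hygiene and the metric suite."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from earpipe.core import ValidationError
from earpipe.model import (
    BruxismModel,
    ModelConfig,
    SmoteConfig,
    SplitPlan,
    evaluate,
    run_pipeline,
    session_features,
    smote_oversample,
    stratified_cv,
    train_classifier,
    zstandardize,
)

from .oracles import metrics_naive


@pytest.fixture(scope="module")
def imbalanced():
    rng = np.random.default_rng(0)
    X = np.vstack([rng.normal(0, 1, (90, 4)), rng.normal(3, 1, (10, 4))])
    y = np.array([0] * 90 + [1] * 10)
    return X, y


@pytest.fixture(scope="session")
def study_features(small_study):
    """Per-session feature matrices for the small synthetic study."""
    return {rec.session_id: session_features(rec, anns) for rec, anns in small_study}


class TestSmote:
    def test_count_contract(self, imbalanced):
        X, y = imbalanced
        X2, y2 = smote_oversample(X, y, SmoteConfig(rng_seed=1))
        assert (y2 == 1).sum() == 90
        assert (y2 == 0).sum() == 90

    def test_originals_preserved_verbatim(self, imbalanced):
        X, y = imbalanced
        X2, y2 = smote_oversample(X, y, SmoteConfig(rng_seed=1))
        np.testing.assert_array_equal(X2[:100], X)
        np.testing.assert_array_equal(y2[:100], y)

    def test_balanced_input_unchanged(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(20, 3))
        y = np.array([0] * 10 + [1] * 10)
        X2, y2 = smote_oversample(X, y)
        np.testing.assert_array_equal(X2, X)
        np.testing.assert_array_equal(y2, y)

    def test_synthetic_rows_on_minority_segments(self, imbalanced):
        """Every synthetic row is a convex combination of two minority rows."""
        X, y = imbalanced
        X2, y2 = smote_oversample(X, y, SmoteConfig(rng_seed=3))
        minority = X[y == 1]
        for row in X2[100:]:
            ok = False
            for i in range(len(minority)):
                for j in range(len(minority)):
                    if i == j:
                        continue
                    d = minority[j] - minority[i]
                    denom = float(d @ d)
                    if denom == 0:
                        continue
                    u = float((row - minority[i]) @ d) / denom
                    if -1e-9 <= u <= 1 + 1e-9 and np.allclose(
                        minority[i] + u * d, row, atol=1e-8
                    ):
                        ok = True
                        break
                if ok:
                    break
            assert ok

    def test_single_class_errors(self):
        with pytest.raises(ValidationError):
            smote_oversample(np.zeros((5, 2)), np.zeros(5, dtype=int))

    def test_k_reduced_when_minority_small(self):
        rng = np.random.default_rng(4)
        X = np.vstack([rng.normal(0, 1, (20, 2)), rng.normal(5, 1, (3, 2))])
        y = np.array([0] * 20 + [1] * 3)
        X2, y2 = smote_oversample(X, y, SmoteConfig(k_neighbors=5))
        assert (y2 == 1).sum() == 20

    def test_deterministic(self, imbalanced):
        X, y = imbalanced
        a = smote_oversample(X, y, SmoteConfig(rng_seed=9))[0]
        b = smote_oversample(X, y, SmoteConfig(rng_seed=9))[0]
        np.testing.assert_array_equal(a, b)


class TestZStandardize:
    def test_train_moments(self, imbalanced):
        X, _ = imbalanced
        Z, _, _, _ = zstandardize(X)
        np.testing.assert_allclose(Z.mean(axis=0), 0.0, atol=1e-9)
        np.testing.assert_allclose(Z.std(axis=0), 1.0, atol=1e-9)

    def test_constant_column_zeroed(self):
        X = np.column_stack([np.arange(10.0), np.full(10, 7.0)])
        with pytest.warns(UserWarning, match="constant"):
            Z, _, _, sds = zstandardize(X)
        assert np.allclose(Z[:, 1], 0.0)
        assert sds[1] == 0

    def test_apply_uses_train_parameters(self):
        rng = np.random.default_rng(5)
        train = rng.normal(0, 1, (50, 3))
        test = train + 100.0  # shifted: its own z-scores would be ~N(0,1)
        _, test_Z, means, sds = zstandardize(train, test)
        np.testing.assert_allclose(test_Z, (test - means) / sds, atol=1e-12)
        assert test_Z.mean() > 50  # clearly not re-standardized on itself


class TestTrainClassifier:
    def test_separable_perfect_training_accuracy(self):
        rng = np.random.default_rng(6)
        X = np.vstack([rng.normal(-3, 0.2, (30, 2)), rng.normal(3, 0.2, (30, 2))])
        y = np.array([0] * 30 + [1] * 30)
        clf = train_classifier(X, y, ModelConfig(n_estimators=20, grid=None))
        assert (clf.predict(X) == y).mean() == 1.0

    def test_null_labels_give_chance_level_cv(self):
        """With labels independent of features, CV accuracy ≈ majority rate."""
        rng = np.random.default_rng(7)
        n = 300
        X = rng.normal(size=(n, 5))
        y = (rng.uniform(size=n) < 0.5).astype(int)
        from sklearn.model_selection import StratifiedKFold

        accs = []
        for tr, va in StratifiedKFold(5, shuffle=True, random_state=0).split(X, y):
            clf = train_classifier(X[tr], y[tr], ModelConfig(n_estimators=25, grid=None))
            accs.append((clf.predict(X[va]) == y[va]).mean())
        majority = max(y.mean(), 1 - y.mean())
        se = np.sqrt(majority * (1 - majority) / n)
        assert abs(np.mean(accs) - majority) <= 3 * se

    def test_deterministic_predictions(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(80, 4))
        y = (X[:, 0] + 0.5 * rng.normal(size=80) > 0).astype(int)
        cfg = ModelConfig(n_estimators=30, rng_seed=5, grid=None)
        p1 = train_classifier(X, y, cfg).predict(X)
        p2 = train_classifier(X, y, cfg).predict(X)
        np.testing.assert_array_equal(p1, p2)

    def test_single_class_errors(self):
        with pytest.raises(ValidationError):
            train_classifier(np.zeros((10, 2)), np.zeros(10, dtype=int))


@pytest.fixture(scope="module")
def cv_data():
    rng = np.random.default_rng(9)
    X = np.vstack([rng.normal(0, 1, (80, 4)), rng.normal(2, 1, (20, 4))])
    y = np.array([0] * 80 + [1] * 20)
    return X, y


class TestStratifiedCV:

    def test_fold_balance_and_partition(self, cv_data):
        X, y = cv_data
        from sklearn.model_selection import StratifiedKFold

        plan = SplitPlan(["S1", "S2"], "S3", cv_folds=5, rng_seed=0)
        folds = list(StratifiedKFold(plan.cv_folds, shuffle=True, random_state=0).split(X, y))
        sizes = [len(va) for _, va in folds]
        pos = [y[va].sum() for _, va in folds]
        assert max(sizes) - min(sizes) <= 1
        assert max(pos) - min(pos) <= 1
        all_idx = np.sort(np.concatenate([va for _, va in folds]))
        np.testing.assert_array_equal(all_idx, np.arange(len(y)))

    def test_selects_by_mean_f1(self, cv_data):
        X, y = cv_data
        plan = SplitPlan(["S1"], "S2", cv_folds=5, rng_seed=0)
        report = stratified_cv(
            X, y, plan,
            SmoteConfig(rng_seed=0),
            ModelConfig(grid={"n_estimators": [10, 30]}, rng_seed=0),
        )
        best = max(report["candidates"], key=lambda c: c["mean_f1"])
        assert report["best_params"] == best["params"]
        assert report["best_mean_f1"] == pytest.approx(best["mean_f1"])

    def test_minority_smaller_than_folds_errors(self):
        X = np.random.default_rng(0).normal(size=(20, 2))
        y = np.array([0] * 17 + [1] * 3)
        plan = SplitPlan(["S1"], "S2", cv_folds=5)
        with pytest.raises(ValidationError):
            stratified_cv(X, y, plan)


class TestEvaluate:
    def test_perfect_prediction(self):
        y = np.array([0, 1, 0, 1, 1])
        r = evaluate(y, y)
        assert (r.precision, r.recall, r.f1, r.mcc) == (1.0, 1.0, 1.0, 1.0)

    def test_all_negative_conventions(self):
        y_true = np.array([0, 1, 0, 1])
        y_pred = np.zeros(4, dtype=int)
        r = evaluate(y_true, y_pred)
        assert (r.recall, r.f1, r.mcc) == (0.0, 0.0, 0.0)
        assert r.precision == 0.0

    def test_formula_oracle(self):
        """Counts TP=37 FP=14 FN=13 TN=236 against direct formula evaluation."""
        y_true = np.array([1] * 37 + [0] * 14 + [1] * 13 + [0] * 236)
        y_pred = np.array([1] * 37 + [1] * 14 + [0] * 13 + [0] * 236)
        r = evaluate(y_true, y_pred)
        exp = metrics_naive(37, 14, 13, 236)
        assert r.precision == pytest.approx(exp["precision"], abs=1e-12)
        assert r.recall == pytest.approx(exp["recall"], abs=1e-12)
        assert r.f1 == pytest.approx(exp["f1"], abs=1e-12)
        assert r.mcc == pytest.approx(exp["mcc"], abs=1e-12)
        assert (r.tp, r.fp, r.fn, r.tn) == (37, 14, 13, 236)

    def test_counts_sum_to_n(self):
        rng = np.random.default_rng(10)
        y_true = rng.integers(0, 2, 50)
        y_pred = rng.integers(0, 2, 50)
        r = evaluate(y_true, y_pred)
        assert r.n_test == 50

    def test_length_mismatch_errors(self):
        with pytest.raises(ValidationError):
            evaluate(np.zeros(3, dtype=int), np.zeros(4, dtype=int))

    @given(seed=st.integers(0, 200))
    @settings(max_examples=40, deadline=None)
    def test_mcc_label_flip_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        y_true = rng.integers(0, 2, 60)
        y_pred = rng.integers(0, 2, 60)
        a = evaluate(y_true, y_pred).mcc
        b = evaluate(1 - y_true, 1 - y_pred).mcc
        assert a == pytest.approx(b, abs=1e-12)

    def test_matches_sklearn(self):
        from sklearn.metrics import f1_score, matthews_corrcoef

        rng = np.random.default_rng(11)
        y_true = rng.integers(0, 2, 200)
        y_pred = (y_true + (rng.uniform(size=200) < 0.3)) % 2
        r = evaluate(y_true, y_pred)
        assert r.f1 == pytest.approx(f1_score(y_true, y_pred), abs=1e-12)
        assert r.mcc == pytest.approx(matthews_corrcoef(y_true, y_pred), abs=1e-9)


class TestBruxismModel:
    def test_fit_produces_summary_and_log(self, study_features, split_plan):
        m = BruxismModel(study_features, split_plan,
                         model_cfg=ModelConfig(n_estimators=50, grid=None))
        res = m.fit(run_cv=False)
        text = res.summary()
        assert "MCC" in text and "S3" in text
        log = res.run_log()
        assert log["plan"]["test_session"] == "S3"
        assert set(log["report"]) >= {"tp", "fp", "fn", "tn", "precision", "recall", "f1", "mcc"}

    def test_no_leakage_canary(self, study_features, split_plan):
        """An extreme outlier in the test session changes no training-side state."""
        cfg = ModelConfig(n_estimators=30, grid=None, rng_seed=0)
        res_clean = BruxismModel(study_features, split_plan, model_cfg=cfg).fit(run_cv=False)

        poisoned = dict(study_features)
        fm = study_features["S3"]
        values = fm.values.copy()
        values[0] = 1e9
        poisoned["S3"] = dataclasses.replace(fm, values=values)
        res_poisoned = BruxismModel(poisoned, split_plan, model_cfg=cfg).fit(run_cv=False)

        np.testing.assert_array_equal(res_clean.scaler[0], res_poisoned.scaler[0])
        np.testing.assert_array_equal(res_clean.scaler[1], res_poisoned.scaler[1])
        # predictions on the untouched test rows are identical
        np.testing.assert_array_equal(res_clean.y_pred[1:], res_poisoned.y_pred[1:])

    def test_smote_output_independent_of_test_rows(self, study_features, split_plan):
        m = BruxismModel(study_features, split_plan)
        X1, y1 = smote_oversample(m.X_train, m.y_train, SmoteConfig(rng_seed=0))
        X2, y2 = smote_oversample(m.X_train, m.y_train, SmoteConfig(rng_seed=0))
        np.testing.assert_array_equal(X1, X2)
        np.testing.assert_array_equal(y1, y2)

    def test_shuffled_test_labels_mcc_near_zero(self, study_features, split_plan):
        m = BruxismModel(study_features, split_plan,
                         model_cfg=ModelConfig(n_estimators=50, grid=None))
        res = m.fit(run_cv=False)
        rng = np.random.default_rng(0)
        mccs = [
            evaluate(rng.permutation(m.y_test), res.y_pred).mcc for _ in range(50)
        ]
        assert abs(np.median(mccs)) < 0.1

    def test_end_to_end_deterministic(self, small_study, split_plan):
        kwargs = dict(model_cfg=ModelConfig(n_estimators=30, grid=None, rng_seed=1))
        r1, log1 = run_pipeline(small_study, split_plan, **kwargs)
        r2, log2 = run_pipeline(small_study, split_plan, **kwargs)
        assert r1.to_dict() == r2.to_dict()
        assert log1["cv"] == log2["cv"]

    def test_missing_test_session_errors(self, study_features):
        plan = SplitPlan(["S1", "S2"], "S9")
        with pytest.raises(ValidationError):
            BruxismModel(study_features, plan)
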