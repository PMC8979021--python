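import itertools

import numpy as np
import pandas as pd
import pytest

from smireg.model_training import (
    ALGORITHMS,
    N_FEATURES,
    CVResult,
    TrainedModelBundle,
    assemble_features,
    auc_score,
    cross_validate,
    evaluate_test,
    f1_score_at,
    feature_names,
    make_estimator,
    select_threshold,
    sens_spec,
    split_train_test,
    train_direction,
)


def oracle_auc(y, scores):
    """Exhaustive concordant-pair counting: ties count one half."""
    pos = [s for s, t in zip(scores, y) if t == 1]
    neg = [s for s, t in zip(scores, y) if t == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))


def oracle_best_f1(y, proba, grid):
    """Independent F1 scan: confusion-matrix arithmetic per threshold."""
    best_t, best_f1 = None, -1.0
    for t in grid:
        pred = [p >= t for p in proba]
        tp = sum(1 for pr, tr in zip(pred, y) if pr and tr == 1)
        fp = sum(1 for pr, tr in zip(pred, y) if pr and tr == 0)
        fn = sum(1 for pr, tr in zip(pred, y) if not pr and tr == 1)
        if tp == 0:
            f1 = 0.0
        else:
            prec, rec = tp / (tp + fp), tp / (tp + fn)
            f1 = 2 * prec * rec / (prec + rec)
        if f1 > best_f1:
            best_t, best_f1 = t, f1
    return best_t, best_f1


class _ConstantProba:
    """Stub model exposing predict_proba over fixed scores."""

    def __init__(self, proba):
        self.proba = np.asarray(proba, dtype=float)

    def predict_proba(self, X):
        p = self.proba[: len(X)]
        return np.column_stack([1 - p, p])


class TestAssembleFeatures:
    def test_shape_and_labels(self, up_balanced):
        X, y, keys = assemble_features(up_balanced)
        assert X.shape == (len(up_balanced.pairs), N_FEATURES)
        assert set(y) == {0, 1}
        assert list(X.columns) == feature_names()
        assert len(keys) == len(up_balanced.pairs)

    def test_toy_shape(self, datasets):
        ds = datasets["up"]
        X, y, _ = assemble_features(ds)
        assert X.shape[1] == 277 + 166
        assert (y == 1).all()

    def test_unfeaturizable_errors(self, datasets):
        import dataclasses

        ds = datasets["up"]
        broken = dataclasses.replace(ds)
        broken.fingerprints = {}  # bypass post-init recompute (no SMILES either)
        broken.molecules = {}
        with pytest.raises(ValueError, match="unfeaturizable"):
            assemble_features(broken)


class TestSplitTrainTest:
    def test_stratified_even(self):
        X = pd.DataFrame(np.arange(200).reshape(100, 2))
        y = np.array([0, 1] * 50)
        X_tr, X_te, y_tr, y_te = split_train_test(X, y, seed=0)
        assert len(X_tr) == len(X_te) == 50
        assert y_tr.sum() == y_te.sum() == 25
        assert set(X_tr.index).isdisjoint(X_te.index)
        assert set(X_tr.index) | set(X_te.index) == set(X.index)

    def test_deterministic(self):
        X = pd.DataFrame(np.arange(100).reshape(50, 2))
        y = np.array([0, 1] * 25)
        a = split_train_test(X, y, seed=3)
        b = split_train_test(X, y, seed=3)
        assert list(a[0].index) == list(b[0].index)

    def test_odd_counts_differ_by_at_most_one(self):
        X = pd.DataFrame(np.arange(42).reshape(21, 2))
        y = np.array([0] * 11 + [1] * 10)
        X_tr, X_te, y_tr, y_te = split_train_test(X, y, seed=0)
        for cls in (0, 1):
            assert abs(int((y_tr == cls).sum()) - int((y_te == cls).sum())) <= 1

    def test_single_class_errors(self):
        X = pd.DataFrame(np.zeros((4, 2)))
        with pytest.raises(ValueError, match="both classes"):
            split_train_test(X, np.ones(4, dtype=int))


class TestAucScore:
    def test_perfect(self):
        assert auc_score([1, 1, 0, 0], [0.9, 0.8, 0.2, 0.1]) == 1.0

    def test_hand_example_eight_ninths(self):
        y = [1, 1, 0, 1, 0, 0]
        s = [0.9, 0.8, 0.7, 0.6, 0.5, 0.4]
        assert auc_score(y, s) == pytest.approx(8 / 9)

    def test_null_behaviour(self, rng):
        y = np.array([0, 1] * 2000)
        s = rng.random(4000)
        assert auc_score(y, s) == pytest.approx(0.5, abs=0.05)

    def test_single_class_errors(self):
        with pytest.raises(ValueError, match="both classes"):
            auc_score([1, 1], [0.5, 0.6])

    def test_exhaustive_small_oracle(self):
        # all discretized score sets of size <= 8: binary scores exhaustively,
        # plus a 3-level alphabet up to size 5
        levels_by_n = {n: [0.0, 1.0] for n in range(2, 9)}
        for n in range(2, 6):
            levels_by_n[n] = [0.0, 0.5, 1.0]
        for n, levels in levels_by_n.items():
            for labels in itertools.product([0, 1], repeat=n):
                if len(set(labels)) < 2:
                    continue
                for scores in itertools.product(levels, repeat=n):
                    assert auc_score(labels, scores) == pytest.approx(
                        oracle_auc(labels, scores), abs=1e-12
                    )


class TestSensSpec:
    def test_basic(self):
        se, sp = sens_spec([1, 1, 0, 0], [0.9, 0.2, 0.8, 0.1])
        assert se == 0.5 and sp == 0.5


class TestCrossValidate:
    def test_separable_rf_high_auc(self, up_balanced):
        X, y, _ = assemble_features(up_balanced)
        cv = cross_validate(X, y, "rf", grid=[21], seed=0)
        assert isinstance(cv, CVResult)
        assert cv.best_auc >= 0.9
        assert list(cv.table.columns) == ["param", "ROC", "Sens", "Spec", "ROCSD", "SensSD", "SpecSD"]

    def test_tie_breaks_to_smaller_param(self, monkeypatch, rng):
        # identical per-fold AUCs for every grid value -> smallest param wins
        X = pd.DataFrame(rng.random((40, 3)))
        y = np.array([0, 1] * 20)

        class Dummy:
            def __init__(self):
                pass

            def fit(self, X, y):
                return self

            def predict_proba(self, X):
                p = np.linspace(0, 1, len(X))
                return np.column_stack([1 - p, p])

        monkeypatch.setattr(
            "smireg.model_training.make_estimator", lambda algo, param, seed=0: Dummy()
        )
        cv = cross_validate(X, y, "rf", grid=[100, 5, 21], seed=0)
        assert cv.best_param == 5

    def test_empty_grid_errors(self, rng):
        X = pd.DataFrame(rng.random((20, 3)))
        y = np.array([0, 1] * 10)
        with pytest.raises(ValueError, match="empty"):
            cross_validate(X, y, "rf", grid=[])

    def test_degenerate_fold_errors(self, rng):
        X = pd.DataFrame(rng.random((10, 3)))
        y = np.array([1] * 9 + [0])
        with pytest.raises(ValueError):
            cross_validate(X, y, "rf", grid=[1], seed=0)

    def test_unknown_algorithm(self):
        with pytest.raises(ValueError, match="unknown algorithm"):
            make_estimator("gbm", 1)


class TestEvaluateTest:
    def test_auc_and_curve(self, up_balanced, trained_bundle):
        X, y, _ = assemble_features(up_balanced)
        auc, curve = evaluate_test(trained_bundle.model, X, y)
        assert 0.9 <= auc <= 1.0
        assert {"fpr", "tpr", "threshold"} <= set(curve.columns)
        assert curve["fpr"].is_monotonic_increasing

    def test_single_class_errors(self, trained_bundle, up_balanced):
        X, y, _ = assemble_features(up_balanced)
        with pytest.raises(ValueError):
            evaluate_test(trained_bundle.model, X, np.ones_like(y))


class TestSelectThreshold:
    def test_separated_scores_lowest_grid_tiebreak(self):
        # positives at 0.9, negatives at 0.1: F1=1 anywhere in (0.1, 0.9];
        # the first grid point above 0.1 is 0.11
        y = np.array([1] * 5 + [0] * 5)
        model = _ConstantProba([0.9] * 5 + [0.1] * 5)
        X = pd.DataFrame(np.zeros((10, 1)))
        t, f1 = select_threshold(model, X, y)
        assert f1 == 1.0
        assert t == pytest.approx(0.11)

    def test_matches_bruteforce_oracle(self, rng):
        grid = np.round(np.arange(0.0, 1.0001, 0.01), 2)
        for _ in range(100):
            n = int(rng.integers(4, 30))
            y = rng.integers(0, 2, size=n)
            if len(set(y)) < 2:
                continue
            proba = np.round(rng.random(n), 3)
            model = _ConstantProba(proba)
            X = pd.DataFrame(np.zeros((n, 1)))
            t, f1 = select_threshold(model, X, y)
            ot, of1 = oracle_best_f1(y, proba, grid)
            assert f1 == pytest.approx(of1, abs=1e-12)
            assert t == pytest.approx(ot)

    def test_no_positive_prediction_errors(self):
        y = np.array([1, 0])
        model = _ConstantProba([0.2, 0.1])
        with pytest.raises(ValueError, match="predicted positive"):
            select_threshold(model, pd.DataFrame(np.zeros((2, 1))), y, grid=[0.5, 0.9])

    def test_single_class_errors(self):
        model = _ConstantProba([0.5, 0.6])
        with pytest.raises(ValueError, match="both classes"):
            select_threshold(model, pd.DataFrame(np.zeros((2, 1))), np.array([1, 1]))

    def test_f1_at_zero_predictions(self):
        assert f1_score_at([1, 0], [0.1, 0.1], 0.5) == 0.0


class TestTrainDirection:
    def test_bundle_fields(self, trained_bundle, up_balanced):
        b = trained_bundle
        assert b.direction == "up"
        assert b.algorithm == "rf"
        assert 0.0 < b.threshold < 1.0
        assert 0.5 <= b.test_auc <= 1.0
        assert b.feature_columns == feature_names()

    def test_report_layout(self, up_balanced):
        _, report = train_direction(
            up_balanced, algorithms=["rf", "knn"], grids={"rf": [21], "knn": [5]}, seed=1
        )
        assert list(report["Model"]) == ["RF", "KNN"]
        for col in ["ROC", "Sens", "Spec", "ROCSD", "SensSD", "SpecSD", "test_AUC"]:
            assert col in report.columns
        assert report[["ROC", "Sens", "Spec"]].le(1).all().all()
        assert report[["ROCSD", "SensSD", "SpecSD"]].ge(0).all().all()

    def test_serialization_roundtrip(self, trained_bundle, up_balanced, tmp_path):
        X, _, _ = assemble_features(up_balanced)
        fixture = X.iloc[:50]
        before = trained_bundle.model.predict_proba(fixture)[:, 1]
        out = trained_bundle.save(tmp_path / "bundle")
        reloaded = TrainedModelBundle.load(out)
        after = reloaded.model.predict_proba(fixture)[:, 1]
        assert (before == after).all()
        assert reloaded.threshold == trained_bundle.threshold
        assert reloaded.algorithm == trained_bundle.algorithm
        assert reloaded.feature_columns == trained_bundle.feature_columns


@pytest.mark.parametrize("algo", [a for a in ALGORITHMS if a != "rf"])
def test_all_algorithms_trainable(algo, up_balanced):
    """Each family fits and predicts probabilities on a small matrix."""
    X, y, _ = assemble_features(up_balanced)
    idx = np.concatenate([np.flatnonzero(y == 1)[:40], np.flatnonzero(y == 0)[:40]])
    X, y = X.iloc[idx], y[idx]
    param = {"glm": 0.5, "knn": 5, "svm": 0, "ann": 0.5}[algo]
    est = make_estimator(algo, param, seed=0)
    est.fit(X, y)
    proba = est.predict_proba(X)[:, 1]
    assert proba.shape == (80,)
    assert ((proba >= 0) & (proba <= 1)).all()
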