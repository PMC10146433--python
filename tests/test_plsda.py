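"""PLS-DA fitting, decision rules, cross-validation and metrics."""

import numpy as np
import pytest
from sklearn.cross_decomposition import PLSRegression

from herbscreen import (
    FingerprintMatrix,
    cross_validate_lv,
    evaluate,
    fit_plsda,
    predict_classes,
    predict_scores,
)
from herbscreen.exceptions import StratificationError
from herbscreen.plsda import PLSDAModel, predict_scores_per_factor, stratified_folds


def fm(values, labels=None):
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    return FingerprintMatrix(
        values=values,
        feature_wavelengths=np.full(p, 254.0),
        feature_times=np.arange(p, dtype=float),
        sample_ids=[f"s{i}" for i in range(n)],
        labels=None if labels is None else np.asarray(labels),
    )


def separable_toy(n_per_class=10, p=5, seed=0):
    """Two classes separated by feature 0; other features carry only a
    whisper of variation (keeps the predictor block full rank)."""
    rng = np.random.default_rng(seed)
    shared = 0.01 * rng.normal(size=(2 * n_per_class, p - 1))
    x0 = np.r_[np.zeros(n_per_class), np.ones(n_per_class)]
    X = np.column_stack([x0, shared])
    labels = np.r_[np.ones(n_per_class, int), np.full(n_per_class, 2)]
    return fm(X, labels), labels


def identity_model(coding, classes):
    q = 1 if coding == "binary" else len(classes)
    return PLSDAModel(
        x_means=np.zeros(q),
        y_means=np.zeros(q),
        weights=np.eye(q),
        x_loadings=np.eye(q),
        y_loadings=np.eye(q),
        n_factors=q,
        coding=coding,
        classes=np.asarray(classes),
        regression_coefficients=np.eye(q),
    )


class TestFit:
    def test_separable_toy_perfect_training_fit(self):
        matrix, labels = separable_toy()
        model = fit_plsda(matrix, labels, n_factors=1, coding="binary")
        assert (predict_classes(model, matrix) == labels).all()

    @pytest.mark.parametrize("coding,n,p", [("binary", 25, 6), ("multiclass", 30, 5)])
    def test_full_rank_matches_least_squares(self, coding, n, p):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(n, p))
        labels = rng.integers(1, 3 if coding == "binary" else 4, size=n)
        labels[:3] = [1, 2, 2 if coding == "binary" else 3]
        matrix = fm(X, labels)
        model = fit_plsda(matrix, labels, n_factors=p, coding=coding)
        fitted = predict_scores(model, matrix)
        # closed-form least squares on centered data
        Xc = X - X.mean(axis=0)
        if coding == "binary":
            Y = labels.astype(float)[:, None]
        else:
            classes = np.unique(labels)
            Y = (labels[:, None] == classes[None, :]).astype(float)
        Yc = Y - Y.mean(axis=0)
        beta, *_ = np.linalg.lstsq(Xc, Yc, rcond=None)
        np.testing.assert_allclose(fitted, Xc @ beta + Y.mean(axis=0), atol=1e-8)

    def test_mean_input_predicts_mean_code(self):
        matrix, labels = separable_toy()
        model = fit_plsda(matrix, labels, n_factors=2, coding="binary")
        np.testing.assert_allclose(model.y_means, [1.5])
        yhat = predict_scores(model, matrix.values.mean(axis=0, keepdims=True))
        np.testing.assert_allclose(yhat, [[1.5]], atol=1e-10)

    def test_single_class_rejected(self):
        matrix = fm(np.random.default_rng(0).normal(size=(6, 3)), [1] * 6)
        with pytest.raises(ValueError):
            fit_plsda(matrix, matrix.labels, 1, "binary")

    def test_excessive_factors_rejected(self):
        matrix, labels = separable_toy(n_per_class=4, p=3)
        with pytest.raises(ValueError):
            fit_plsda(matrix, labels, n_factors=20, coding="binary")

    def test_training_residual_monotone_in_factors(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(20, 10))
        labels = rng.integers(1, 3, size=20)
        labels[:2] = [1, 2]
        matrix = fm(X, labels)
        Y = labels.astype(float)[:, None]
        norms = []
        for k in range(1, 9):
            model = fit_plsda(matrix, labels, k, "binary")
            norms.append(np.linalg.norm(Y - predict_scores(model, matrix)))
        assert all(a >= b - 1e-10 for a, b in zip(norms, norms[1:]))

    def test_sample_order_permutation_invariant_predictions(self):
        matrix, labels = separable_toy(n_per_class=8, p=6, seed=5)
        model = fit_plsda(matrix, labels, 3, "binary")
        perm = np.random.default_rng(6).permutation(matrix.n_samples)
        model_p = fit_plsda(matrix.take(perm), labels[perm], 3, "binary")
        probe = np.random.default_rng(7).normal(size=(5, 6))
        assert (predict_classes(model, probe) == predict_classes(model_p, probe)).all()

    @pytest.mark.parametrize("coding", ["binary", "multiclass"])
    def test_matches_sklearn_pls_regression(self, coding):
        rng = np.random.default_rng(8)
        n_classes = 2 if coding == "binary" else 4
        labels = rng.integers(1, n_classes + 1, size=30)
        labels[:n_classes] = np.arange(1, n_classes + 1)
        X = rng.normal(size=(30, 12))
        X[:, :n_classes] += 3.0 * (labels[:, None] == np.arange(1, n_classes + 1))
        matrix = fm(X, labels)
        model = fit_plsda(matrix, labels, n_factors=4, coding=coding)
        classes = np.unique(labels)
        Y = (
            labels.astype(float)[:, None]
            if coding == "binary"
            else (labels[:, None] == classes[None, :]).astype(float)
        )
        sk = PLSRegression(n_components=4, scale=False, tol=1e-10, max_iter=5000).fit(X, Y)
        probe = rng.normal(size=(7, 12))
        np.testing.assert_allclose(
            predict_scores(model, probe), sk.predict(probe), atol=1e-5
        )


class TestDecisionRules:
    def test_binary_midpoint_threshold(self):
        model = identity_model("binary", [1, 2])
        scores = np.array([[1.0], [2.0], [1.5], [1.49999]])
        assert predict_classes(model, scores).tolist() == [1, 2, 2, 1]

    def test_multiclass_argmax_with_low_class_ties(self):
        model = identity_model("multiclass", [1, 2, 3, 4, 5])
        scores = np.array(
            [[0.9, 0.1, 0.1, 0.05, 0.0], [0.2, 0.2, 0.1, 0.0, 0.0]]
        )
        assert predict_classes(model, scores).tolist() == [1, 1]

    def test_feature_mismatch_rejected(self):
        matrix, labels = separable_toy()
        model = fit_plsda(matrix, labels, 1, "binary")
        with pytest.raises(ValueError):
            predict_classes(model, np.zeros((2, 99)))


class TestCrossValidation:
    def test_separable_toy_chooses_one_factor(self):
        matrix, labels = separable_toy(n_per_class=10, p=5)
        cv = cross_validate_lv(matrix, labels, "binary", folds=5, max_factors=4, seed=0)
        assert cv.ccr_by_factor[0] == 100.0
        assert cv.n_factors == 1  # tie rule: fewest factors
        assert cv.ccr_by_factor.size == 4

    def test_table_matches_manual_fold_loop(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(24, 8))
        labels = np.r_[np.ones(14, int), np.full(10, 2)]
        X[labels == 2, 0] += 1.5
        matrix = fm(X, labels)
        max_factors = 4
        cv = cross_validate_lv(matrix, labels, "binary", folds=4, max_factors=max_factors, seed=2)
        # independent oracle: refit each fold separately per factor count
        n = matrix.n_samples
        pred = np.empty((max_factors, n), dtype=int)
        for held in cv.folds:
            keep = np.setdiff1d(np.arange(n), held)
            for k in range(1, max_factors + 1):
                model = fit_plsda(matrix.take(keep), labels[keep], k, "binary")
                pred[k - 1, held] = predict_classes(model, matrix.values[held])
        expected = 100.0 * (pred == labels[None, :]).mean(axis=1)
        np.testing.assert_allclose(cv.ccr_by_factor, expected, atol=1e-10)

    def test_truncated_predictions_equal_refits(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(18, 6))
        labels = rng.integers(1, 3, size=18)
        labels[:2] = [1, 2]
        matrix = fm(X, labels)
        full = fit_plsda(matrix, labels, 4, "binary")
        per_k = predict_scores_per_factor(full, X)
        for k in (1, 2, 3, 4):
            sub = fit_plsda(matrix, labels, k, "binary")
            np.testing.assert_allclose(per_k[k - 1], predict_scores(sub, X), atol=1e-8)

    def test_folds_are_seeded_stratified_disjoint(self):
        labels = np.r_[np.ones(12, int), np.full(4, 2)]
        folds = stratified_folds(labels, 4, seed=3)
        again = stratified_folds(labels, 4, seed=3)
        assert all(np.array_equal(a, b) for a, b in zip(folds, again))
        allidx = np.sort(np.concatenate(folds))
        np.testing.assert_array_equal(allidx, np.arange(16))

    def test_stratification_failure_signalled(self):
        labels = np.r_[np.ones(9, int), [2]]
        with pytest.raises(StratificationError):
            stratified_folds(labels, 10, seed=0)


class TestEvaluate:
    def test_printed_ccr_values(self):
        true = np.r_[np.ones(47, int), np.full(3, 2)]
        pred = np.ones(50, int)  # 3 blanks misread as positives
        report = evaluate(true, pred)
        assert report.ccr == pytest.approx(94.0)
        assert report.ccr_display == 94
        true17 = np.r_[np.ones(16, int), [2]]
        assert evaluate(true17, np.ones(17, int)).ccr_display == 94

    def test_all_correct(self):
        labels = np.array([1, 2, 1, 2])
        report = evaluate(labels, labels)
        assert report.ccr == 100.0
        assert report.confusion[0, 1] == 0 and report.confusion[1, 0] == 0
        assert report.misclassified_ids == []

    def test_misclassified_ids_named(self):
        report = evaluate([1, 2], [1, 1], sample_ids=["a", "b"])
        assert report.misclassified_ids == ["b"]

    def test_label_outside_coding_rejected(self):
        with pytest.raises(ValueError):
            evaluate([1, 3], [1, 1], classes=[1, 2])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            evaluate([1, 2], [1])
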