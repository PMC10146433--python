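"""PLS-DA: latent-variable regression on class codes, factor selection by
stratified 10-fold cross-validation, prediction and classification metrics.

Class coding follows chemometric convention for screening models:

* binary -- a single response column coded 1 (contains the target plant)
  or 2 (blank); the decision rule is the 1.5 midpoint, with the boundary
  itself assigned to class 2;
* multiclass -- one 0/1 indicator column per class (plants 1..K, blank
  K+1); the predicted class is the argmax of the indicator predictions,
  ties resolving to the lowest class.

Latent variables are extracted by NIPALS: predictors and responses are
mean-centered (no scaling); each factor maximizes covariance between an X
score and a Y score, followed by deflation of both blocks, so factors are
nested -- the k-factor model is the truncation of the K-factor model,
which cross-validation exploits by fitting each fold once.  Convergence
tolerance is 1e-12 on the score vector with at most 500 iterations per
factor; single-column responses converge in one step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion

from .cube import FingerprintMatrix
from .exceptions import StratificationError

__all__ = [
    "PLSDAModel",
    "ClassificationReport",
    "CVResult",
    "fit_plsda",
    "predict_scores",
    "predict_classes",
    "cross_validate_lv",
    "evaluate",
]

_TOL = 1e-12
_MAX_ITER = 500


@dataclass
class PLSDAModel:
    """Fitted PLS-DA state: centering vectors, per-factor weights/loadings,
    class coding and the derived regression coefficients."""

    x_means: np.ndarray  # (p,)
    y_means: np.ndarray  # (q,)
    weights: np.ndarray  # W, (p, k)
    x_loadings: np.ndarray  # P, (p, k)
    y_loadings: np.ndarray  # Q, (q, k)
    n_factors: int
    coding: str  # "binary" | "multiclass"
    classes: np.ndarray  # sorted class labels
    regression_coefficients: np.ndarray  # B = W (P'W)^-1 Q', (p, q)


@dataclass
class ClassificationReport:
    """Confusion counts, correct classification rate and the misclassified ids.

    ``ccr`` is kept at full precision (percent); ``ccr_display`` rounds to
    the nearest integer percent for tabulation.
    """

    confusion: np.ndarray  # (n_classes, n_classes), rows = true
    classes: np.ndarray
    ccr: float
    misclassified_ids: list[str]

    @property
    def ccr_display(self) -> int:
        return int(round(self.ccr))


@dataclass
class CVResult:
    n_factors: int  # argmax ccr, ties -> fewest factors
    ccr_by_factor: np.ndarray  # percent, index k-1 = k factors
    folds: list[np.ndarray]  # held-out index sets


def _code_responses(labels: np.ndarray, coding: str) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels, dtype=int)
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError("training set must contain at least 2 classes")
    if coding == "binary":
        if not np.array_equal(classes, [1, 2]):
            raise ValueError("binary coding expects labels {1, 2}")
        Y = labels.astype(float)[:, None]
    elif coding == "multiclass":
        Y = (labels[:, None] == classes[None, :]).astype(float)
    else:
        raise ValueError("coding must be 'binary' or 'multiclass'")
    return Y, classes


def _nipals(Xc: np.ndarray, Yc: np.ndarray, n_factors: int):
    """Iterative covariance-maximizing extraction with deflation."""
    n, p = Xc.shape
    q = Yc.shape[1]
    W = np.empty((p, n_factors))
    P = np.empty((p, n_factors))
    Q = np.empty((q, n_factors))
    X = Xc.copy()
    Y = Yc.copy()
    for k in range(n_factors):
        if q == 1:
            u = Y[:, 0]
            w = X.T @ u
            w /= np.linalg.norm(w)
            t = X @ w
            qv = (Y.T @ t) / (t @ t)
        else:
            u = Y[:, int(np.argmax(Y.var(axis=0)))].copy()
            t_old = None
            for _ in range(_MAX_ITER):
                w = X.T @ u
                w /= np.linalg.norm(w)
                t = X @ w
                qv = (Y.T @ t) / (t @ t)
                u = (Y @ qv) / (qv @ qv)
                if t_old is not None and np.linalg.norm(t - t_old) <= _TOL * np.linalg.norm(t):
                    break
                t_old = t
        p_load = (X.T @ t) / (t @ t)
        X -= np.outer(t, p_load)
        Y -= np.outer(t, qv)
        W[:, k] = w
        P[:, k] = p_load
        Q[:, k] = qv
    return W, P, Q


def fit_plsda(
    train: FingerprintMatrix, labels, n_factors: int, coding: str
) -> PLSDAModel:
    """Fit a PLS-DA model on a calibration fingerprint matrix.

    Reproducible bit-for-bit on identical input: the extraction involves
    no randomness.
    """
    X = np.asarray(train.values, dtype=float)
    Y, classes = _code_responses(labels, coding)
    if Y.shape[0] != X.shape[0]:
        raise ValueError("labels length does not match rows")
    n, p = X.shape
    if not 1 <= n_factors <= min(n - 1, p):
        raise ValueError(
            f"n_factors must lie in [1, min(n_train - 1, n_features)] = "
            f"[1, {min(n - 1, p)}]"
        )
    x_means = X.mean(axis=0)
    y_means = Y.mean(axis=0)
    W, P, Q = _nipals(X - x_means, Y - y_means, n_factors)
    B = W @ np.linalg.solve(P.T @ W, Q.T)
    return PLSDAModel(
        x_means=x_means,
        y_means=y_means,
        weights=W,
        x_loadings=P,
        y_loadings=Q,
        n_factors=n_factors,
        coding=coding,
        classes=classes,
        regression_coefficients=B,
    )


def predict_scores(model: PLSDAModel, samples: FingerprintMatrix | np.ndarray) -> np.ndarray:
    """Predicted response codes, shape (n, q)."""
    X = samples.values if isinstance(samples, FingerprintMatrix) else np.asarray(samples)
    if X.shape[1] != model.x_means.size:
        raise ValueError("feature count does not match the model")
    return (X - model.x_means) @ model.regression_coefficients + model.y_means


def _scores_to_classes(model: PLSDAModel, yhat: np.ndarray) -> np.ndarray:
    if model.coding == "binary":
        return np.where(yhat[:, 0] < 1.5, 1, 2)
    return model.classes[np.argmax(yhat, axis=1)]  # first max -> lowest class


def predict_classes(model: PLSDAModel, samples) -> np.ndarray:
    """Class labels from predicted codes (1.5 midpoint / indicator argmax)."""
    return _scores_to_classes(model, predict_scores(model, samples))


def predict_scores_per_factor(model: PLSDAModel, samples) -> np.ndarray:
    """Predicted codes for every truncation 1..n_factors, shape (k, n, q).

    Uses the test-deflation recursion (scores t_k from W with P-deflation),
    which reproduces the coefficient form exactly for nested factors.
    """
    X = samples.values if isinstance(samples, FingerprintMatrix) else np.asarray(samples)
    Xc = X - model.x_means
    out = np.empty((model.n_factors, X.shape[0], model.y_means.size))
    yhat = np.tile(model.y_means, (X.shape[0], 1))
    Xd = Xc.copy()
    for k in range(model.n_factors):
        t = Xd @ model.weights[:, k]
        yhat = yhat + np.outer(t, model.y_loadings[:, k])
        Xd -= np.outer(t, model.x_loadings[:, k])
        out[k] = yhat
    return out


def stratified_folds(labels: np.ndarray, folds: int, seed: int) -> list[np.ndarray]:
    """Seeded, label-stratified, disjoint fold index sets."""
    labels = np.asarray(labels, dtype=int)
    n = labels.size
    if n < folds:
        raise ValueError("need at least as many samples as folds")
    rng = np.random.default_rng(seed)
    assignment = np.empty(n, dtype=int)
    pos = 0
    for cls in np.unique(labels):
        members = np.nonzero(labels == cls)[0]
        rng.shuffle(members)
        assignment[members] = (pos + np.arange(members.size)) % folds
        pos += members.size
    out = [np.nonzero(assignment == f)[0] for f in range(folds)]
    for f, held in enumerate(out):
        if held.size == 0 or np.unique(labels[np.setdiff1d(np.arange(n), held)]).size < 2:
            raise StratificationError(
                f"fold {f} leaves fewer than 2 classes in its training part"
            )
    return out


def cross_validate_lv(
    train: FingerprintMatrix,
    labels,
    coding: str,
    folds: int = 10,
    max_factors: int = 30,
    seed: int = 0,
) -> CVResult:
    """Choose the factor count by pooled held-out ccr over stratified folds.

    For each factor count 1..max_factors the ccr is computed over all
    held-out predictions pooled; the chosen count is the argmax, ties
    resolving to the fewest factors.
    """
    labels = np.asarray(labels, dtype=int)
    fold_sets = stratified_folds(labels, folds, seed)
    n = labels.size
    predictions = np.empty((max_factors, n), dtype=int)
    for held in fold_sets:
        keep = np.setdiff1d(np.arange(n), held)
        sub = train.take(keep)
        limit = min(keep.size - 1, train.n_features)
        if max_factors > limit:
            raise ValueError(
                f"max_factors {max_factors} not admissible in a fold "
                f"(limit {limit})"
            )
        model = fit_plsda(sub, labels[keep], max_factors, coding)
        yhats = predict_scores_per_factor(model, train.values[held])
        for k in range(max_factors):
            predictions[k, held] = _scores_to_classes(model, yhats[k])
    ccr = 100.0 * (predictions == labels[None, :]).mean(axis=1)
    chosen = int(np.argmax(ccr)) + 1  # first max -> fewest factors
    return CVResult(n_factors=chosen, ccr_by_factor=ccr, folds=fold_sets)


def evaluate(true_labels, predicted_labels, sample_ids=None, classes=None) -> ClassificationReport:
    """Confusion matrix and ccr% for a prediction set."""
    true_labels = np.asarray(true_labels, dtype=int)
    predicted_labels = np.asarray(predicted_labels, dtype=int)
    if true_labels.shape != predicted_labels.shape:
        raise ValueError("label vectors must have equal length")
    if classes is None:
        classes = np.unique(np.concatenate([true_labels, predicted_labels]))
    else:
        classes = np.asarray(classes, dtype=int)
        known = set(classes.tolist())
        bad = [x for x in np.concatenate([true_labels, predicted_labels]) if int(x) not in known]
        if bad:
            raise ValueError(f"label {bad[0]} outside the coding classes {classes}")
    conf = _sk_confusion(true_labels, predicted_labels, labels=classes)
    n = true_labels.size
    ccr = 100.0 * np.trace(conf) / n
    wrong = np.nonzero(true_labels != predicted_labels)[0]
    ids = (
        [sample_ids[int(i)] for i in wrong]
        if sample_ids is not None
        else [str(int(i)) for i in wrong]
    )
    return ClassificationReport(confusion=conf, classes=classes, ccr=float(ccr), misclassified_ids=ids)
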