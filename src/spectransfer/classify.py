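"""Species discrimination: PLS-DA and RBF-SVM classifiers plus metrics.

PLS-DA regresses a one-hot class indicator matrix Y on the spectra X,
Y = X b + e, and assigns the class with the largest predicted score.  The
number of latent variables is chosen by seeded stratified 10-fold
cross-validation, counting a sample as misclassified when its predicted
score for the true class deviates from the target 1 by more than 0.5.

The SVM uses an RBF kernel with (C, gamma) chosen by seeded stratified
grid-search cross-validation on accuracy (one-vs-one multiclass); ties
break to the smaller C, then the smaller gamma.

Confusion-matrix metrics follow the usual one-vs-rest definitions:
accuracy = (TP+TN)/(TP+TN+FP+FN) (multiclass: trace/total), sensitivity =
TP/(TP+FN), precision = TP/(TP+FP).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

__all__ = [
    "PLSDAClassifier",
    "PLSDAResults",
    "SVMClassifier",
    "SVMResults",
    "ConfusionReport",
    "fit_plsda",
    "predict_plsda",
    "fit_svm",
    "evaluate",
    "before_after_comparison",
]


def _mat(X) -> np.ndarray:
    return np.atleast_2d(np.asarray(getattr(X, "spectra", X), dtype=float))


def _check_classes(labels) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels)
    classes = np.unique(labels)  # alphabetical class order
    if classes.size < 2:
        raise ValueError("at least 2 classes are required")
    codes = np.searchsorted(classes, labels)
    return classes, codes


def _stratified_folds(codes: np.ndarray, n_folds: int, seed: int):
    counts = np.bincount(codes)
    if counts.min() < 2:
        raise ValueError("every class needs at least 2 samples for stratified CV")
    n_folds = min(n_folds, int(counts.min()))
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros_like(codes), codes))


# ---------------------------------------------------------------------------
# PLS-DA
# ---------------------------------------------------------------------------

@dataclass
class PLSDAResults:
    """Fitted PLS-DA model (one-hot PLS regression, argmax decision)."""

    n_components: int
    coefficients: np.ndarray          # wavelengths x classes
    intercept: np.ndarray             # classes
    class_order: np.ndarray
    cv_table: pd.DataFrame
    n_wavelengths: int

    def scores(self, X) -> np.ndarray:
        X = _mat(X)
        if X.shape[1] != self.n_wavelengths:
            raise ValueError(
                f"input has {X.shape[1]} wavelengths; model was trained on "
                f"{self.n_wavelengths}"
            )
        return X @ self.coefficients + self.intercept

    def predict(self, X) -> np.ndarray:
        return self.class_order[np.argmax(self.scores(X), axis=1)]

    def summary(self) -> str:
        return (
            "PLS-DA classifier\n"
            f"  latent variables = {self.n_components}\n"
            f"  classes          = {', '.join(map(str, self.class_order))}\n"
            f"  CV misclassifications by component count:\n"
            f"{self.cv_table.to_string(index=False)}"
        )


class PLSDAClassifier:
    """PLS-DA model: one-hot PLS regression with CV component selection."""

    def __init__(self, X, labels, max_components: int = 10,
                 n_folds: int = 10, seed: int = 0):
        self.X = _mat(X)
        self.class_order, self.codes = _check_classes(labels)
        m, n = self.X.shape
        self.max_components = int(min(max_components, m - 1, n))
        self.n_folds = n_folds
        self.seed = seed

    def fit(self) -> PLSDAResults:
        Y = np.eye(self.class_order.size)[self.codes]
        folds = _stratified_folds(self.codes, self.n_folds, self.seed)
        rows = []
        for nc in range(1, self.max_components + 1):
            errors = 0
            for tr, te in folds:
                pls = PLSRegression(n_components=nc, scale=False)
                pls.fit(self.X[tr], Y[tr])
                pred = pls.predict(self.X[te])
                true_scores = pred[np.arange(te.size), self.codes[te]]
                errors += int(np.sum(np.abs(true_scores - 1.0) > 0.5))
            rows.append((nc, errors))
        table = pd.DataFrame(rows, columns=["n_components", "cv_errors"])
        best = int(table.loc[table["cv_errors"].idxmin(), "n_components"])
        pls = PLSRegression(n_components=best, scale=False)
        pls.fit(self.X, Y)
        coef = pls.coef_.T                      # wavelengths x classes
        intercept = Y.mean(axis=0) - self.X.mean(axis=0) @ coef
        return PLSDAResults(best, coef, intercept, self.class_order,
                            table, self.X.shape[1])


def fit_plsda(X, labels, max_components: int = 10, n_folds: int = 10,
              seed: int = 0) -> PLSDAResults:
    return PLSDAClassifier(X, labels, max_components, n_folds, seed).fit()


def predict_plsda(model: PLSDAResults, X) -> tuple[np.ndarray, np.ndarray]:
    """Predicted labels and the raw class-score matrix."""
    return model.predict(X), model.scores(X)


# ---------------------------------------------------------------------------
# SVM
# ---------------------------------------------------------------------------

@dataclass
class SVMResults:
    """Fitted RBF-SVM with its grid-search record."""

    C: float
    gamma: float
    class_order: np.ndarray
    cv_table: pd.DataFrame
    estimator: SVC
    n_wavelengths: int

    def predict(self, X) -> np.ndarray:
        X = _mat(X)
        if X.shape[1] != self.n_wavelengths:
            raise ValueError(
                f"input has {X.shape[1]} wavelengths; model was trained on "
                f"{self.n_wavelengths}"
            )
        return self.estimator.predict(X)

    def summary(self) -> str:
        return (
            "RBF-SVM classifier\n"
            f"  C = {self.C}, gamma = {self.gamma}\n"
            f"  classes = {', '.join(map(str, self.class_order))}\n"
            f"  grid-search CV accuracy:\n{self.cv_table.to_string(index=False)}"
        )


class SVMClassifier:
    """RBF-SVM model with seeded grid-search cross-validation."""

    def __init__(self, X, labels, C_grid=(1.0, 10.0, 100.0),
                 gamma_grid=(0.01, 0.1, 1.0), n_folds: int = 5, seed: int = 0):
        self.X = _mat(X)
        self.labels = np.asarray(labels)
        self.class_order, self.codes = _check_classes(self.labels)
        if not len(C_grid) or not len(gamma_grid):
            raise ValueError("C and gamma grids must be nonempty")
        self.C_grid = sorted(float(c) for c in C_grid)
        self.gamma_grid = sorted(float(g) for g in gamma_grid)
        self.n_folds = n_folds
        self.seed = seed

    def fit(self) -> SVMResults:
        folds = _stratified_folds(self.codes, self.n_folds, self.seed)
        rows = []
        best = (-1.0, None, None)
        for C in self.C_grid:                 # ascending: ties keep smaller C
            for gamma in self.gamma_grid:     # then smaller gamma
                correct = total = 0
                for tr, te in folds:
                    clf = SVC(C=C, gamma=gamma, kernel="rbf")
                    clf.fit(self.X[tr], self.labels[tr])
                    correct += int(np.sum(clf.predict(self.X[te]) == self.labels[te]))
                    total += te.size
                acc = correct / total
                rows.append((C, gamma, acc))
                if acc > best[0]:
                    best = (acc, C, gamma)
        table = pd.DataFrame(rows, columns=["C", "gamma", "cv_accuracy"])
        clf = SVC(C=best[1], gamma=best[2], kernel="rbf")
        clf.fit(self.X, self.labels)
        return SVMResults(best[1], best[2], self.class_order, table, clf,
                          self.X.shape[1])


def fit_svm(X, labels, C_grid=(1.0, 10.0, 100.0), gamma_grid=(0.01, 0.1, 1.0),
            n_folds: int = 5, seed: int = 0) -> SVMResults:
    return SVMClassifier(X, labels, C_grid, gamma_grid, n_folds, seed).fit()


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

@dataclass
class ConfusionReport:
    """Confusion matrix (rows = actual, cols = predicted) with metrics.

    Precision of a class that is never predicted (TP+FP = 0) is NaN.
    """

    matrix: np.ndarray
    class_order: np.ndarray
    accuracy: float
    sensitivity: dict
    precision: dict

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.class_order,
                            columns=self.class_order)

    def summary(self) -> str:
        per_class = pd.DataFrame(
            {"sensitivity": self.sensitivity, "precision": self.precision}
        )
        return (
            f"accuracy = {self.accuracy:.4f}\n\nconfusion matrix "
            f"(rows=actual):\n{self.to_frame().to_string()}\n\n"
            f"{per_class.to_string()}"
        )


def evaluate(labels_true, labels_pred, class_order=None) -> ConfusionReport:
    """Confusion matrix and accuracy / per-class sensitivity / precision."""
    labels_true = np.asarray(labels_true)
    labels_pred = np.asarray(labels_pred)
    if labels_true.shape != labels_pred.shape:
        raise ValueError("label vectors must have equal length")
    if class_order is None:
        class_order = np.unique(labels_true)
    class_order = np.asarray(class_order)
    seen = np.union1d(np.unique(labels_true), np.unique(labels_pred))
    unknown = np.setdiff1d(seen, class_order)
    if unknown.size:
        raise ValueError(f"labels {unknown.tolist()} not in class_order")
    cm = confusion_matrix(labels_true, labels_pred, labels=class_order)
    total = cm.sum()
    accuracy = float(np.trace(cm) / total)
    sens, prec = {}, {}
    for k, name in enumerate(class_order):
        tp = cm[k, k]
        fn = cm[k].sum() - tp
        fp = cm[:, k].sum() - tp
        sens[name] = float(tp / (tp + fn)) if tp + fn else float("nan")
        prec[name] = float(tp / (tp + fp)) if tp + fp else float("nan")
    return ConfusionReport(cm, class_order, accuracy, sens, prec)


def before_after_comparison(classifiers: dict, slave_test_X, slave_test_labels,
                            transfers: dict) -> pd.DataFrame:
    """Accuracy of master-trained classifiers on (transformed) slave spectra.

    ``transfers`` maps method name -> fitted transfer results (or None for
    the untransformed baseline); ``classifiers`` maps classifier name ->
    fitted classifier results.  Rows failing to transform are recorded with
    a note instead of an accuracy.
    """
    X = _mat(slave_test_X)
    labels = np.asarray(slave_test_labels)
    rows = []
    for tname, transfer in transfers.items():
        if transfer is None:
            Xt, note = X, ""
        else:
            try:
                Xt, note = transfer.transform(X), ""
            except Exception as exc:  # record and skip
                for cname in classifiers:
                    rows.append((tname, cname, np.nan, f"transfer failed: {exc}"))
                continue
        for cname, clf in classifiers.items():
            pred = clf.predict(Xt)
            acc = float(np.mean(pred == labels))
            rows.append((tname, cname, 100.0 * acc, note))
    return pd.DataFrame(rows, columns=["transfer", "classifier",
                                       "accuracy_pct", "note"])
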