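"""Soft-margin linear SVM fitting, margin status and scoring.

The classifier is the classical L2-regularized hinge-loss SVM; multiclass
problems use one-vs-rest.  Margin status per training cell follows the KKT
characterization of the dual: with functional margin ``m_i = y_i (w.x_i + b)``,

* ``m_i > 1``  — outside the margin (dual coefficient 0),
* ``m_i = 1``  — on the margin (0 < alpha <= C),
* ``m_i < 1``  — margin violator (alpha = C).

Status is derived from functional margins with tolerance ``tol`` rather than
from explicit dual coefficients, which is equivalent under the KKT conditions
and independent of which solver produced ``(w, b)``.

Fitting goes through libsvm's C-SVC with a linear kernel (the exact dual with
an unregularized bias), called through scikit-learn's low-level binding to
keep per-fit overhead small — the gene-scoring loop refits thousands of tiny
SVMs per iteration.  A plain :class:`sklearn.svm.SVC` fallback covers the
same math if the binding is unavailable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

try:  # fast path: libsvm C-SVC without estimator overhead
    from sklearn.svm import _libsvm

    _libsvm.set_verbosity_wrap(0)

    def _libsvm_fit(X, y, C, tol):
        out = _libsvm.fit(X, y, svm_type=0, kernel="linear", C=C, tol=tol)
        support_vectors, sv_coef, intercept = out[1], out[3], out[4]
        # the raw decision is positive for the smaller label value; negate so
        # that the positive side is the +1 class, matching sklearn's SVC
        w = -np.asarray(sv_coef @ support_vectors).ravel()
        b = -float(intercept[0])
        return w, b
except ImportError:  # pragma: no cover - exercised only on unusual builds
    _libsvm_fit = None

try:  # fast path: liblinear dual coordinate descent without estimator overhead
    from sklearn.svm import _liblinear

    _liblinear.set_verbosity_wrap(0)
    _L2R_L1LOSS_SVC_DUAL = 3

    def _liblinear_fit(X, y01, C, tol, max_iter):
        raw, _ = _liblinear.train_wrap(
            X, y01, False, _L2R_L1LOSS_SVC_DUAL, tol, 1.0, C,
            np.ones(2), max_iter, 0, 0.1, np.ones(X.shape[0]))
        return raw[0, :-1].copy(), float(raw[0, -1])
except ImportError:  # pragma: no cover
    _liblinear_fit = None

from sklearn.svm import SVC, LinearSVC

MARGIN_TOL = 1e-4
SOLVER_TOL = 1e-6

OUTSIDE, ON_MARGIN, VIOLATOR = 1, 0, -1
_CATEGORY_NAMES = {OUTSIDE: "outside", ON_MARGIN: "on_margin", VIOLATOR: "violator"}


@dataclass
class SVMState:
    """Fitted one-vs-rest linear SVM over a selected gene set.

    ``coef`` has one row per binary classifier: a single row for two classes
    (positive side = ``classes[1]``), otherwise one row per class.
    """

    genes: np.ndarray          # ordered selected gene indices, length |J|
    classes: np.ndarray        # sorted distinct class ids
    coef: np.ndarray           # (n_classifiers, |J|)
    intercept: np.ndarray      # (n_classifiers,)
    C: float

    @property
    def n_classifiers(self) -> int:
        return self.coef.shape[0]

    def decision_values(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.shape[1] != self.coef.shape[1]:
            raise ValueError(
                f"block has {X.shape[1]} genes, state expects {self.coef.shape[1]}")
        return X @ self.coef.T + self.intercept

    def predict(self, X: np.ndarray) -> np.ndarray:
        dec = self.decision_values(X)
        if self.n_classifiers == 1:
            return np.where(dec[:, 0] >= 0, self.classes[1], self.classes[0])
        return self.classes[np.argmax(dec, axis=1)]


@dataclass
class MarginReport:
    """Per-cell, per-classifier functional margins and margin categories."""

    functional_margins: np.ndarray  # (n_cells, n_classifiers)
    categories: np.ndarray          # same shape, values in {OUTSIDE, ON_MARGIN, VIOLATOR}
    tol: float

    def eligible(self, criterion: str = "violators") -> np.ndarray:
        """Boolean pool-eligibility per cell: margin trouble in any class."""
        if criterion == "violators":
            return np.any(self.categories == VIOLATOR, axis=1)
        if criterion == "violators_or_margin":
            return np.any(self.categories != OUTSIDE, axis=1)
        raise ValueError(f"unknown pool criterion {criterion!r}")


def _fit_binary(X: np.ndarray, y_signed: np.ndarray, C: float, tol: float):
    """Fit one binary C-SVC; y_signed must be +/-1 with both signs present."""
    X = np.ascontiguousarray(X, dtype=np.float64)
    y_signed = np.ascontiguousarray(y_signed, dtype=np.float64)
    if _libsvm_fit is not None:
        return _libsvm_fit(X, y_signed, float(C), float(tol))
    est = SVC(kernel="linear", C=C, tol=tol).fit(X, y_signed)
    return est.coef_.ravel().copy(), float(est.intercept_[0])


def fit_hinge_primal(X: np.ndarray, y_signed: np.ndarray, C: float,
                     tol: float = 1e-4, max_iter: int = 20000):
    """Liblinear-formulation hinge SVM: the bias is an L2-regularized feature.

    This is the solver of the gene-scoring loop, where thousands of tiny
    SVMs are refit per iteration and only the ranking of rotation angles
    matters.  It minimizes ``(||w||^2 + b^2)/2 + C sum hinge`` by dual
    coordinate descent (deterministic: fixed internal shuffling seed).
    Returns ``(w, b)`` with the positive side belonging to the +1 class.
    """
    X = np.ascontiguousarray(X, dtype=np.float64)
    y01 = np.ascontiguousarray(y_signed > 0, dtype=np.float64)
    if _liblinear_fit is not None:
        return _liblinear_fit(X, y01, float(C), float(tol), int(max_iter))
    est = LinearSVC(loss="hinge", C=C, tol=tol, max_iter=max_iter,
                    random_state=0).fit(X, y01)
    return est.coef_.ravel().copy(), float(est.intercept_[0])


def fit_linear_svm(block: np.ndarray, labels: np.ndarray, C: float = 1.0,
                   genes=None, tol: float = SOLVER_TOL) -> SVMState:
    """Train the (one-vs-rest) soft-margin linear SVM on a dense block.

    ``block`` is cells x |J|; ``labels`` are the class ids of those cells.
    Deterministic given the data order and solver tolerance.
    """
    block = np.asarray(block, dtype=np.float64)
    if block.ndim != 2 or block.shape[1] < 1:
        raise ValueError("need a cells x genes block with at least one gene")
    if C <= 0:
        raise ValueError("C must be positive")
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError("training cells contain a single class")
    if block.shape[0] != labels.size:
        raise ValueError("block rows and labels length differ")

    if classes.size == 2:
        y = np.where(labels == classes[1], 1.0, -1.0)
        w, b = _fit_binary(block, y, C, tol)
        coef, intercept = w[None, :], np.array([b])
    else:
        rows, bs = [], []
        for z in classes:
            y = np.where(labels == z, 1.0, -1.0)
            w, b = _fit_binary(block, y, C, tol)
            rows.append(w)
            bs.append(b)
        coef, intercept = np.vstack(rows), np.array(bs)

    genes = np.arange(block.shape[1]) if genes is None else np.asarray(genes)
    return SVMState(genes=genes, classes=classes, coef=coef,
                    intercept=intercept, C=float(C))


def signed_indicators(classes: np.ndarray, labels: np.ndarray,
                      n_classifiers: int) -> np.ndarray:
    """(n_cells, n_classifiers) matrix of +/-1 one-vs-rest targets."""
    labels = np.asarray(labels)
    if n_classifiers == 1:
        return np.where(labels == classes[1], 1.0, -1.0)[:, None]
    return np.where(labels[:, None] == classes[None, :], 1.0, -1.0)


def margin_report(state: SVMState, block: np.ndarray, labels: np.ndarray,
                  tol: float = MARGIN_TOL) -> MarginReport:
    """Categorize every cell against every classifier's margin."""
    dec = state.decision_values(block)
    y = signed_indicators(state.classes, labels, state.n_classifiers)
    fm = y * dec
    cats = np.full(fm.shape, ON_MARGIN, dtype=np.int8)
    cats[fm > 1.0 + tol] = OUTSIDE
    cats[fm < 1.0 - tol] = VIOLATOR
    return MarginReport(functional_margins=fm, categories=cats, tol=tol)


def hinge_loss(functional_margin):
    """``max(0, 1 - m)`` elementwise."""
    return np.maximum(0.0, 1.0 - np.asarray(functional_margin, dtype=np.float64))


def predict_and_score(state: SVMState, block: np.ndarray, labels) -> float:
    """Fraction of cells whose predicted class matches the label."""
    labels = np.asarray(labels)
    pred = state.predict(block)
    if pred.size != labels.size:
        raise ValueError("block rows and labels length differ")
    return float(np.mean(pred == labels))
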