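"""Independent brute-force oracles used only by the test suite.

These deliberately avoid the production code paths: the soft-margin SVM dual
is solved as a small constrained quadratic program with scipy's SLSQP, and
the naive gene-selection oracle recomputes margin-rotation scores from those
QP solutions with its own cosine code.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize


def svm_dual_qp(X, y, C, tol=1e-12):
    """Exact soft-margin linear SVM dual (free bias, sum alpha_i y_i = 0).

    Maximizes ``sum a - 1/2 sum a_i a_j y_i y_j <x_i, x_j>`` over the box
    ``[0, C]`` subject to the equality constraint; returns ``(w, b, alpha)``
    with ``w = sum alpha_i y_i x_i`` and b recovered from the KKT conditions.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = y.size
    G = (y[:, None] * X) @ (y[:, None] * X).T

    def fun(a):
        return 0.5 * a @ G @ a - a.sum()

    def jac(a):
        return G @ a - 1.0

    best = None
    for x0 in (np.zeros(n), np.full(n, 0.5 * min(C, 1.0)), np.full(n, C)):
        res = minimize(fun, x0, jac=jac, bounds=[(0.0, C)] * n,
                       constraints=[{"type": "eq", "fun": lambda a: a @ y,
                                     "jac": lambda a: y}],
                       method="SLSQP",
                       options={"maxiter": 1000, "ftol": tol})
        if best is None or res.fun < best.fun:
            best = res
    a = np.clip(best.x, 0.0, C)
    w = (a * y) @ X
    # b from on-margin support vectors, else from the KKT feasibility interval
    margins = X @ w
    on = (a > 1e-6 * C) & (a < C * (1 - 1e-6))
    if on.any():
        b = float(np.mean(y[on] - margins[on]))
    else:
        lo, hi = -np.inf, np.inf
        for i in range(n):
            if a[i] < C * (1 - 1e-6):   # requires y_i (w x_i + b) >= 1
                if y[i] > 0:
                    lo = max(lo, 1.0 - margins[i])
                else:
                    hi = min(hi, -1.0 - margins[i])
            if a[i] > 1e-6 * C:         # requires y_i (w x_i + b) <= 1
                if y[i] > 0:
                    hi = min(hi, 1.0 - margins[i])
                else:
                    lo = max(lo, -1.0 - margins[i])
        if not np.isfinite(lo):
            lo = hi
        if not np.isfinite(hi):
            hi = lo
        b = float(0.5 * (lo + hi)) if np.isfinite(lo) else 0.0
    return w, b, a


def hinge_primal_qp(X, y, C, tol=1e-12):
    """Dual of the hinge SVM with the bias as a regularized feature.

    Same box QP as :func:`svm_dual_qp` but on augmented inner products
    ``<x_i, x_j> + 1`` and without the equality constraint; returns
    ``(w, b, alpha)`` with ``b = sum alpha_i y_i``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = y.size
    Xa = np.hstack([X, np.ones((n, 1))])
    G = (y[:, None] * Xa) @ (y[:, None] * Xa).T

    def fun(a):
        return 0.5 * a @ G @ a - a.sum()

    def jac(a):
        return G @ a - 1.0

    best = None
    for x0 in (np.zeros(n), np.full(n, 0.5 * min(C, 1.0)), np.full(n, C)):
        res = minimize(fun, x0, jac=jac, bounds=[(0.0, C)] * n,
                       method="SLSQP", options={"maxiter": 1000, "ftol": tol})
        if best is None or res.fun < best.fun:
            best = res
    a = np.clip(best.x, 0.0, C)
    wb = (a * y) @ Xa
    return wb[:-1], float(wb[-1]), a


def rotation_angle_oracle(w_ref, w_new):
    """Angle via an explicitly normalized cosine (independent code path)."""
    w_ref = np.concatenate([np.asarray(w_ref, float), [0.0]])
    w_new = np.asarray(w_new, float)
    nr, nn = np.sqrt(w_ref @ w_ref), np.sqrt(w_new @ w_new)
    if nr == 0.0 or nn == 0.0:
        return 0.0
    c = min(1.0, max(-1.0, float(w_ref @ w_new) / (nr * nn)))
    return float(np.arccos(c))


def naive_select_next_gene(X, y, J, candidates, C):
    """Sequential re-implementation of rotation-based gene selection.

    Fits every SVM with the hinge-primal QP oracle instead of the production
    coordinate-descent solver.  Returns ``(gene, {gene: angle})``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size == 2:
        targets = [np.where(y == classes[1], 1.0, -1.0)]
    else:
        targets = [np.where(y == z, 1.0, -1.0) for z in classes]
    base = X[:, J]
    refs = [hinge_primal_qp(base, t, C)[0] for t in targets]
    angles = {}
    for j in candidates:
        total = 0.0
        if np.ptp(X[:, j]) > 0.0:  # constant genes score zero by convention
            Xj = np.column_stack([base, X[:, j]])
            for w_ref, t in zip(refs, targets):
                w_new, _, _ = hinge_primal_qp(Xj, t, C)
                total += rotation_angle_oracle(w_ref, w_new)
        angles[int(j)] = total
    best = max(sorted(angles), key=lambda g: angles[g])
    return best, angles
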