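"""Independent reference implementations used only to check the package.

These deliberately re-derive results by the most literal route available —
textbook NIPALS with double deflation, normal-equation least squares, an
explicit percentile bootstrap — and share no code with ``soilspec``.
"""

from __future__ import annotations

import numpy as np


def nipals_pls2_reference(X, Y, n_components, tol=1e-13, max_iter=5000):
    """Textbook NIPALS-PLS2: iterative inner loop, X *and* Y deflation.

    Returns (x_mean, y_mean, W, T, P, Q).  Signs of w/t/q columns are
    iteration-dependent and must be aligned before comparison.
    """
    X = np.asarray(X, dtype=float).copy()
    Y = np.asarray(Y, dtype=float).copy()
    x_mean, y_mean = X.mean(axis=0), Y.mean(axis=0)
    E, F = X - x_mean, Y - y_mean
    n, p = E.shape
    K = F.shape[1]
    W = np.zeros((p, n_components))
    T = np.zeros((n, n_components))
    P = np.zeros((p, n_components))
    Q = np.zeros((K, n_components))
    for a in range(n_components):
        u = F[:, int(np.argmax(F.var(axis=0)))].copy()
        t_old = None
        for _ in range(max_iter):
            w = E.T @ u
            w = w / np.linalg.norm(w)
            t = E @ w
            q = F.T @ t / (t @ t)
            u = F @ q / (q @ q)
            if t_old is not None and np.linalg.norm(t - t_old) < tol * np.linalg.norm(t):
                break
            t_old = t
        p_a = E.T @ t / (t @ t)
        E = E - np.outer(t, p_a)
        F = F - np.outer(t, q)
        W[:, a], T[:, a], P[:, a], Q[:, a] = w, t, p_a, q
    return x_mean, y_mean, W, T, P, Q


def nipals_reference_predict(X, Y, n_components, X_new):
    """Predictions of the reference NIPALS model at full component count."""
    x_mean, y_mean, W, T, P, Q = nipals_pls2_reference(X, Y, n_components)
    R = W @ np.linalg.inv(P.T @ W)
    B = R @ Q.T
    return (np.asarray(X_new, dtype=float) - x_mean) @ B + y_mean


def ols_predict(X, Y, X_new):
    """Multiresponse least squares on centered data (normal-equations route)."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    x_mean, y_mean = X.mean(axis=0), Y.mean(axis=0)
    B, *_ = np.linalg.lstsq(X - x_mean, Y - y_mean, rcond=None)
    return (np.asarray(X_new, dtype=float) - x_mean) @ B + y_mean


def ols_coefficients(X, Y):
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    B, *_ = np.linalg.lstsq(X - X.mean(axis=0), Y - Y.mean(axis=0), rcond=None)
    return B


def bootstrap_median_ci(x, n_boot, seed, lo=2.5, hi=97.5):
    """Plain percentile bootstrap of the median (loop form)."""
    rng = np.random.default_rng(seed)
    x = np.asarray(x, dtype=float)
    meds = np.empty(n_boot)
    for b in range(n_boot):
        meds[b] = np.median(x[rng.integers(0, x.size, size=x.size)])
    return float(np.percentile(meds, lo)), float(np.percentile(meds, hi))


def align_signs(A, ref):
    """Flip columns of A to match the signs of ref (for NIPALS comparisons)."""
    A = A.copy()
    for j in range(A.shape[1]):
        if np.dot(A[:, j], ref[:, j]) < 0:
            A[:, j] = -A[:, j]
    return A
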