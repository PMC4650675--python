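"""From-scratch PLS2 regression with VIP variable importance.

The estimator extracts latent variables from mean-centered predictors and a
mean-centered multivariate response, deflating X only (Y-deflation changes
nothing in PLS2 because successive X residuals are orthogonal to earlier
scores).  No variance scaling is applied: NIR absorbance features share a
common magnitude, so centering is the whole pretreatment.

Each weight vector is the dominant eigenvector of ``E'Y Y'E`` — the exact
fixed point of the classical NIPALS inner iteration — computed directly
from the small ``K x K`` eigenproblem ``(Y'E)(E'Y) b = lambda b`` with
``w = E'Y b`` normalized.  This is algebraically the converged NIPALS
component (up to the irrelevant sign of ``w``) at a fraction of the cost
when the number of responses K is small.

Notation follows the chemometrics convention:

* ``W`` (p x A) — X weights, unit norm per component
* ``T`` (n x A) — X scores, mutually orthogonal
* ``P`` (p x A) — X loadings
* ``Q`` (K x A) — Y loadings
* ``R = W (P'W)^-1`` — rotations mapping centered X directly to scores

Regression coefficients at ``a`` components are ``B_a = R[:, :a] Q[:, :a]'``
(valid truncation because ``P'W`` is unit upper triangular).
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import eigh, solve_triangular
from sklearn.base import BaseEstimator, RegressorMixin

_EPS = np.finfo(float).eps


class PLS2Regression(RegressorMixin, BaseEstimator):
    """Multiresponse partial least squares regression (PLS2, NIPALS).

    Parameters
    ----------
    n_components : int
        Number of latent variables A to extract; must satisfy
        ``A <= min(n - 1, p)``.

    Attributes
    ----------
    x_mean_, y_mean_ : column means of the training data
    x_weights_, x_scores_, x_loadings_, y_loadings_ : W, T, P, Q above
    x_rotations_ : R = W (P'W)^-1

    Examples
    --------
    >>> rng = np.random.default_rng(0)
    >>> X = rng.normal(size=(10, 6)); Y = rng.normal(size=(10, 2))
    >>> model = PLS2Regression(n_components=3).fit(X, Y)
    >>> model.predict(X).shape
    (10, 2)
    """

    def __init__(self, n_components: int = 2):
        self.n_components = n_components

    # ------------------------------------------------------------------
    def fit(self, X, Y) -> "PLS2Regression":
        X = np.atleast_2d(np.asarray(X, dtype=float))
        Y = np.asarray(Y, dtype=float)
        if Y.ndim == 1:
            Y = Y[:, None]
        n, p = X.shape
        K = Y.shape[1]
        if Y.shape[0] != n:
            raise ValueError(f"X has {n} rows but Y has {Y.shape[0]}")
        if not (np.all(np.isfinite(X)) and np.all(np.isfinite(Y))):
            raise ValueError("X and Y must be finite")
        A = int(self.n_components)
        if A < 1:
            raise ValueError("n_components must be >= 1")
        if n < 2:
            raise ValueError("need at least 2 samples")
        if A > min(n - 1, p):
            raise ValueError(
                f"n_components={A} exceeds min(n-1, p)={min(n - 1, p)} "
                f"for n={n}, p={p}"
            )
        self.x_mean_ = X.mean(axis=0)
        self.y_mean_ = Y.mean(axis=0)
        Xc = X - self.x_mean_
        Yc = Y - self.y_mean_
        if np.linalg.norm(Yc) < _EPS * max(1.0, np.linalg.norm(Y)):
            raise ValueError("Y has zero variance; nothing to model")

        W = np.empty((p, A))
        T = np.empty((n, A))
        P = np.empty((p, A))
        Q = np.empty((K, A))
        E = Xc.copy()  # X residual, deflated in place
        x_norm = np.linalg.norm(Xc)
        for a in range(A):
            Z = E.T @ Yc  # (p, K) cross-covariance
            # w = dominant eigenvector of Z Z' via the K x K problem Z'Z
            _, vecs = eigh(Z.T @ Z)
            w = Z @ vecs[:, -1]
            wn = np.linalg.norm(w)
            if wn <= _EPS * max(1.0, x_norm) * np.linalg.norm(Yc):
                raise ValueError(
                    f"X residual exhausted at component {a + 1}; "
                    f"reduce n_components (rank < {A})"
                )
            w /= wn
            t = E @ w
            q = Yc.T @ t / (t @ t)
            tt = t @ t
            if tt <= (_EPS * x_norm) ** 2:
                raise ValueError(
                    f"degenerate score at component {a + 1}; reduce n_components"
                )
            p_load = E.T @ t / tt
            E -= np.outer(t, p_load)
            W[:, a], T[:, a], P[:, a], Q[:, a] = w, t, p_load, q

        self.x_weights_ = W
        self.x_scores_ = T
        self.x_loadings_ = P
        self.y_loadings_ = Q
        # P'W is unit upper triangular -> stable triangular solve
        self.x_rotations_ = solve_triangular(
            (P.T @ W).T, W.T, lower=True, unit_diagonal=True
        ).T
        self.n_features_in_ = p
        self.n_targets_ = K
        return self

    # ------------------------------------------------------------------
    def _check_a(self, n_components: int | None) -> int:
        a = self.x_weights_.shape[1] if n_components is None else int(n_components)
        if not 1 <= a <= self.x_weights_.shape[1]:
            raise ValueError(
                f"n_components must be in 1..{self.x_weights_.shape[1]}, got {a}"
            )
        return a

    def coefficients(self, n_components: int | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Affine map ``Y ≈ X @ B + b0`` truncated at ``n_components``.

        Returns
        -------
        B : (p, K) coefficient matrix
        b0 : (K,) intercept
        """
        a = self._check_a(n_components)
        B = self.x_rotations_[:, :a] @ self.y_loadings_[:, :a].T
        b0 = self.y_mean_ - self.x_mean_ @ B
        return B, b0

    def predict(self, X, n_components: int | None = None) -> np.ndarray:
        """Predicted responses on the original (uncentered) scale."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features; model was fitted with "
                f"{self.n_features_in_}"
            )
        B, b0 = self.coefficients(n_components)
        return X @ B + b0

    def predict_all_components(self, X) -> np.ndarray:
        """Predictions at every truncation 1..A in one pass.

        Returns an ``(A, m, K)`` array whose slice ``a-1`` equals
        ``predict(X, n_components=a)``; used by accuracy-vs-components
        curves and cross-validation so each fold is fitted once.
        """
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features; model was fitted with "
                f"{self.n_features_in_}"
            )
        T_new = (X - self.x_mean_) @ self.x_rotations_  # (m, A)
        # per-component additive contributions to the prediction
        contrib = T_new[:, :, None] * self.y_loadings_.T[None, :, :]  # (m, A, K)
        cum = np.cumsum(contrib, axis=1) + self.y_mean_  # broadcast intercept
        return np.moveaxis(cum, 1, 0)

    # ------------------------------------------------------------------
    def vip(self, n_components: int | None = None) -> np.ndarray:
        """Per-feature, per-response VIP scores at ``n_components``.

        VIP_jk = sqrt( p * sum_c SSY_ck (w_jc/||w_c||)^2 / sum_c SSY_ck )
        with SSY_ck = q_ck^2 (t_c' t_c), the response-k variance explained
        by component c.  The normalization identity
        ``sum_j VIP_jk^2 = p`` holds for every response k.
        """
        a = self._check_a(n_components)
        W = self.x_weights_[:, :a]
        wnorm2 = (W**2).sum(axis=0)
        Wn2 = W**2 / wnorm2  # columns sum to 1
        tt = (self.x_scores_[:, :a] ** 2).sum(axis=0)  # (a,)
        ssy = (self.y_loadings_[:, :a] ** 2) * tt  # (K, a)
        denom = ssy.sum(axis=1)  # (K,)
        if np.any(denom <= 0):
            bad = int(np.argmin(denom))
            raise ValueError(
                f"response column {bad} has zero explained variance over the "
                f"first {a} components; VIP undefined"
            )
        p = W.shape[0]
        return np.sqrt(p * (Wn2 @ ssy.T) / denom)  # (p, K)


def high_vip_features(
    vip_scores: np.ndarray, threshold: float = 1.0
) -> tuple[list[np.ndarray], np.ndarray]:
    """Features with VIP >= threshold, per response class and their intersection.

    Parameters
    ----------
    vip_scores : (p, K) array as returned by :meth:`PLS2Regression.vip`
    threshold : importance cutoff; the conventional value is 1.

    Returns
    -------
    per_class : list of K index arrays (features important for each class)
    shared : index array of features important for every class
    """
    V = np.atleast_2d(np.asarray(vip_scores, dtype=float))
    mask = V >= threshold
    per_class = [np.flatnonzero(mask[:, k]) for k in range(V.shape[1])]
    shared = np.flatnonzero(mask.all(axis=1))
    return per_class, shared
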