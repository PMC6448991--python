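"""Minimal PLS1 (single-response NIPALS) used by the rdCV discovery engine.

The repeated double cross-validation loop performs on the order of 10^5 to
10^6 small PLS fits (variable-elimination steps times inner folds times
permutations), so the fit is a handful of BLAS calls with no per-call
validation overhead.  Numerical agreement with scikit-learn's PLSRegression
is asserted in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_EPS = 1e-12


@dataclass
class PLS1Model:
    x_mean: np.ndarray
    W: np.ndarray       # loading weights, (p, A)
    P: np.ndarray       # x loadings, (p, A)
    q: np.ndarray       # inner-relation coefficients, (A,)
    n_components: int

    def coef(self, ncomp: int | None = None) -> np.ndarray:
        """Regression vector using the first ``ncomp`` components."""
        a = self.n_components if ncomp is None else min(ncomp, self.n_components)
        if a == 0:
            return np.zeros(self.W.shape[0])
        W, P, q = self.W[:, :a], self.P[:, :a], self.q[:a]
        # B = W (P^T W)^{-1} q ; P^T W is upper triangular for NIPALS
        R = np.linalg.solve(P.T @ W, np.eye(a))
        return W @ (R @ q)

    def coefs_per_ncomp(self) -> list[np.ndarray]:
        return [self.coef(a) for a in range(1, self.n_components + 1)]

    def predict(self, X: np.ndarray, ncomp: int | None = None) -> np.ndarray:
        return (X - self.x_mean) @ self.coef(ncomp)

    def importance(self, ncomp: int | None = None) -> np.ndarray:
        """Per-variable |loading weight x inner-relation coefficient| summed
        over components — the elimination criterion of the rdCV engine."""
        a = self.n_components if ncomp is None else min(ncomp, self.n_components)
        if a == 0:
            return np.zeros(self.W.shape[0])
        return np.abs(self.W[:, :a] * self.q[:a]).sum(axis=1)


def fit_pls1(X: np.ndarray, y: np.ndarray, ncomp: int) -> PLS1Model:
    """NIPALS PLS1 on centered copies of ``X`` and ``y``.

    Stops early when the residual covariance with the response vanishes.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    x_mean = X.mean(axis=0)
    Xd = X - x_mean
    yd = y - y.mean()
    n, p = Xd.shape
    ncomp = min(ncomp, p, max(n - 1, 1))
    W = np.empty((p, ncomp))
    P = np.empty((p, ncomp))
    q = np.empty(ncomp)
    a = 0
    for a in range(ncomp):
        w = Xd.T @ yd
        nw = np.linalg.norm(w)
        if nw < _EPS:
            break
        w /= nw
        t = Xd @ w
        tt = t @ t
        if tt < _EPS:
            break
        p_a = (Xd.T @ t) / tt
        q_a = (yd @ t) / tt
        Xd -= np.outer(t, p_a)
        yd = yd - q_a * t
        W[:, a], P[:, a], q[a] = w, p_a, q_a
    else:
        a = ncomp
        return PLS1Model(x_mean, W, P, q, ncomp)
    return PLS1Model(x_mean, W[:, :a], P[:, :a], q[:a], a)
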