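"""Independent oracles used by the test suite.

These deliberately avoid the package's own REML/BLUP code paths: the
restricted log-likelihood is evaluated in closed form through an
eigendecomposition, maximized by brute-force grid search; BLUP predictions
are recomputed by solving Henderson's mixed-model equations directly; ridge
solutions use the explicit penalized normal equations.
"""

from __future__ import annotations

import numpy as np


def single_kernel_loglik(y: np.ndarray, K: np.ndarray):
    """Closed-form restricted log-likelihood evaluator for V = sg*K + se*I.

    Returns a function f(sg, se) using one eigendecomposition of K; the
    intercept is the only fixed effect.
    """
    n = y.size
    w, U = np.linalg.eigh((K + K.T) / 2.0)
    yt = U.T @ y
    xt = U.T @ np.ones(n)

    def f(sg: float, se: float) -> float:
        d = sg * w + se
        if np.any(d <= 0):
            return -np.inf
        di = 1.0 / d
        xvx = float(np.sum(xt**2 * di))
        ypy = float(np.sum(yt**2 * di) - np.sum(xt * yt * di) ** 2 / xvx)
        return -0.5 * (float(np.sum(np.log(d))) + np.log(xvx) + ypy)

    return f


def grid_maximize(y: np.ndarray, K: np.ndarray, m: int = 200):
    """Single-pass dense m x m grid maximization over (0, 3 var(y)]^2."""
    f = single_kernel_loglik(y, K)
    vary = np.var(y, ddof=1)
    vals = np.linspace(3 * vary / m, 3 * vary, m)
    best = (-np.inf, (np.nan, np.nan))
    for sg in vals:
        for se in vals:
            ll = f(sg, se)
            if ll > best[0]:
                best = (ll, (sg, se))
    return best


def zoomed_grid_maximize(y: np.ndarray, K: np.ndarray, m: int = 200,
                         zooms: int = 3):
    """Brute-force grid maximization refined by re-gridding around the
    running argmax (pure evaluation, no gradients)."""
    f = single_kernel_loglik(y, K)
    vary = np.var(y, ddof=1)
    lo = np.array([3 * vary / m] * 2)
    hi = np.array([3 * vary] * 2)
    best = (-np.inf, (np.nan, np.nan))
    for _ in range(zooms):
        gs = [np.linspace(lo[i], hi[i], m) for i in range(2)]
        best = (-np.inf, (np.nan, np.nan))
        for sg in gs[0]:
            for se in gs[1]:
                ll = f(sg, se)
                if ll > best[0]:
                    best = (ll, (sg, se))
        c = np.array(best[1])
        step = (hi - lo) / (m - 1)
        lo = np.maximum(c - 2 * step, 1e-12)
        hi = c + 2 * step
    return best


def mme_predict(y_train, K_full, train_idx, test_idx, sigma_u, sigma_e):
    """Henderson's mixed-model equations with test records unobserved.

    Solves for the intercept and the random effect over ALL lines using the
    incidence matrix that maps the training records to their levels; returns
    mu + u[test].  Requires K_full to be invertible.
    """
    n_all = K_full.shape[0]
    n_tr = len(train_idx)
    X = np.ones((n_tr, 1))
    Zi = np.zeros((n_tr, n_all))
    Zi[np.arange(n_tr), train_idx] = 1.0
    Kinv = np.linalg.inv(K_full)
    lam = sigma_e / sigma_u
    lhs = np.block([
        [X.T @ X, X.T @ Zi],
        [Zi.T @ X, Zi.T @ Zi + lam * Kinv],
    ])
    rhs = np.concatenate([X.T @ y_train, Zi.T @ y_train])
    sol = np.linalg.solve(lhs, rhs)
    mu = sol[0]
    u = sol[1:]
    return mu + u[np.asarray(test_idx)]


def ridge_effects(M: np.ndarray, y_centered: np.ndarray, lam: float) -> np.ndarray:
    """Penalized normal-equation solution beta = (M'M + lam I)^-1 M' y."""
    m = M.shape[1]
    return np.linalg.solve(M.T @ M + lam * np.eye(m), M.T @ y_centered)
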