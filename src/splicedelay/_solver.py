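"""Numerical kernels: cyclic coordinate descent for the L1-penalized
least-squares objective

    (1/N) * ||y - X b||^2 + lam * ||b||_1

on internally standardized predictors, plus a leave-one-out evaluator over a
penalty path.  The kernels are JIT-compiled with numba when available (the
grid search over delays x penalties x folds makes millions of tiny solves);
pure-Python fallbacks implement the identical arithmetic.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(f):
            return f

        return wrap


MAX_ITER = 100_000
CD_TOL = 1e-13


@njit(cache=True)
def _cd(G, c, thr, beta, max_iter, tol):  # pragma: no cover - jitted
    """Coordinate descent on the standardized problem.

    Minimizes beta' G beta / N - 2 c' beta / N + lam ||beta||_1 where
    G = Xs'Xs, c = Xs'y and thr = lam * N / 2.  ``beta`` is updated in
    place (warm starts across a penalty path).
    """
    p = c.shape[0]
    for _ in range(max_iter):
        dmax = 0.0
        for j in range(p):
            gjj = G[j, j]
            if gjj <= 0.0:
                beta[j] = 0.0
                continue
            rho = c[j] + gjj * beta[j]
            for k in range(p):
                rho -= G[j, k] * beta[k]
            if rho > thr:
                b = (rho - thr) / gjj
            elif rho < -thr:
                b = (rho + thr) / gjj
            else:
                b = 0.0
            d = b - beta[j]
            if d < 0.0:
                d = -d
            if d > dmax:
                dmax = d
            beta[j] = b
        if dmax <= tol:
            break
    return beta


@njit(cache=True)
def _loocv_path(X, y, lams, max_iter, tol):  # pragma: no cover - jitted
    """Mean squared leave-one-out residual for every penalty in ``lams``.

    For each held-out row i the model is refit on the remaining rows
    (standardization included), sweeping the path from the largest penalty
    down with warm starts.  Returns an array of MSEs aligned with ``lams``.
    """
    N, p = X.shape
    L = lams.shape[0]
    sse = np.zeros(L)
    Xf = np.empty((N - 1, p))
    yf = np.empty(N - 1)
    for i in range(N):
        k = 0
        for r in range(N):
            if r == i:
                continue
            for j in range(p):
                Xf[k, j] = X[r, j]
            yf[k] = y[r]
            k += 1
        n = N - 1
        ym = 0.0
        for r in range(n):
            ym += yf[r]
        ym /= n
        sy = 0.0
        for r in range(n):
            sy += (yf[r] - ym) ** 2
        sy = np.sqrt(sy / n)
        if sy <= 0.0:
            # constant target: every model predicts the mean
            for li in range(L):
                sse[li] += (y[i] - ym) ** 2
            continue
        mx = np.zeros(p)
        sd = np.zeros(p)
        for j in range(p):
            m = 0.0
            for r in range(n):
                m += Xf[r, j]
            m /= n
            v = 0.0
            for r in range(n):
                v += (Xf[r, j] - m) ** 2
            mx[j] = m
            sd[j] = np.sqrt(v / n)
        Xs = np.zeros((n, p))
        for j in range(p):
            if sd[j] > 0.0:
                for r in range(n):
                    Xs[r, j] = (Xf[r, j] - mx[j]) / sd[j]
        G = Xs.T @ Xs
        yc = (yf - ym) / sy
        c = Xs.T @ yc
        beta = np.zeros(p)
        for li in range(L - 1, -1, -1):
            thr = (lams[li] / sy) * n / 2.0
            _cd(G, c, thr, beta, max_iter, tol)
            pred = ym
            for j in range(p):
                if sd[j] > 0.0 and beta[j] != 0.0:
                    pred += sy * beta[j] * (X[i, j] - mx[j]) / sd[j]
            sse[li] += (y[i] - pred) ** 2
    return sse / N


def solve_standardized(X: np.ndarray, y: np.ndarray, lam: float) -> tuple[np.ndarray, float]:
    """Solve the penalized objective; coefficients on the original scale.

    Predictors are standardized to zero mean / unit (population) variance
    and the response is centered internally; zero-variance predictors get a
    zero coefficient.  Returns ``(beta, intercept)``.
    """
    N, p = X.shape
    ym = y.mean()
    yc = y - ym
    sy = float(np.sqrt(np.mean(yc**2)))
    if sy <= 0.0:
        return np.zeros(p), float(ym)
    mx = X.mean(axis=0)
    sd = np.sqrt(np.mean((X - mx) ** 2, axis=0))
    ok = sd > 0.0
    Xs = np.zeros_like(X, dtype=float)
    Xs[:, ok] = (X[:, ok] - mx[ok]) / sd[ok]
    ycn = yc / sy
    if lam == 0.0:
        # unpenalized: minimum-norm least squares on the standardized design
        bs, *_ = np.linalg.lstsq(Xs[:, ok], ycn, rcond=None)
        beta_s = np.zeros(p)
        beta_s[ok] = bs
    else:
        G = Xs.T @ Xs
        c = Xs.T @ ycn
        beta_s = np.zeros(p)
        _cd(G, c, (lam / sy) * N / 2.0, beta_s, MAX_ITER, CD_TOL)
    beta = np.zeros(p)
    beta[ok] = sy * beta_s[ok] / sd[ok]
    intercept = float(ym - beta @ mx)
    return beta, intercept


def loocv_path(X: np.ndarray, y: np.ndarray, lams: np.ndarray) -> np.ndarray:
    """Leave-one-out MSE for each penalty in ``lams`` (ascending order)."""
    return _loocv_path(
        np.ascontiguousarray(X, dtype=float),
        np.ascontiguousarray(y, dtype=float),
        np.ascontiguousarray(lams, dtype=float),
        MAX_ITER,
        CD_TOL,
    )


def warmup() -> None:
    """Trigger JIT compilation on a tiny instance (no-op without numba)."""
    X = np.arange(12.0).reshape(4, 3)
    y = np.array([0.0, 1.0, 0.5, 2.0])
    solve_standardized(X, y, 0.1)
    loocv_path(X, y, np.array([0.05, 0.5]))
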