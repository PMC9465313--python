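"""Independent oracle implementations used to cross-check the package.

These deliberately avoid the package's solver/loop code paths: the QP
oracle solves the penalized objective as a smooth bound-constrained
program on the positive/negative split of the coefficients, and the
double-CV oracle spells out the nested loops with numpy primitives.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize

from splicedelay import lambda_path, lasso_solve


def lasso_qp_oracle(X, y, lam):
    """Solve min (1/N)||yc - Xs b||^2 + lam ||b||_1 via L-BFGS-B on b+/b-.

    Standardization convention mirrors the documented contract (population
    sd, centered response, coefficients returned on the original scale).
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    N, p = X.shape
    ym = y.mean()
    yc = y - ym
    mx = X.mean(axis=0)
    sd = np.sqrt(np.mean((X - mx) ** 2, axis=0))
    ok = sd > 0
    Xs = np.zeros_like(X)
    Xs[:, ok] = (X[:, ok] - mx[ok]) / sd[ok]

    def fun(z):
        b = z[:p] - z[p:]
        r = yc - Xs @ b
        f = (r @ r) / N + lam * z.sum()
        g = -2.0 / N * (Xs.T @ r)
        return f, np.concatenate([g + lam, -g + lam])

    res = optimize.minimize(
        fun,
        np.zeros(2 * p),
        jac=True,
        method="L-BFGS-B",
        bounds=[(0, None)] * 2 * p,
        options={"maxiter": 20000, "ftol": 1e-16, "gtol": 1e-12},
    )
    bs = res.x[:p] - res.x[p:]
    beta = np.zeros(p)
    beta[ok] = bs[ok] / sd[ok]
    intercept = ym - beta @ mx
    return beta, float(intercept)


def interp_clamped(times, values, queries):
    """np.interp with the same boundary clamping the package documents."""
    return np.interp(np.atleast_1d(queries), times, values)


def loocv_oracle(X, y, lam):
    """Explicit leave-one-out loop around lasso_solve."""
    N = len(y)
    sse = 0.0
    for i in range(N):
        keep = np.arange(N) != i
        beta, b0 = lasso_solve(X[keep], y[keep], lam)
        sse += (y[i] - (X[i] @ beta + b0)) ** 2
    return sse / N


def double_cv_oracle(gene, protein, delays, n_lams, eps=1e-3):
    """Nested two-loop re-implementation of the double cross-validation.

    Outer loop: hold out each measured protein point within the mRNA
    horizon.  Inner loop: for every (tau, lam) run an explicit LOO over the
    design rows built from the remaining protein measurements; pick the
    smallest mean squared residual (ties: smallest tau, then largest lam),
    refit, predict the held-out measurement.
    """
    mt = gene.grid.times
    keep_cols = mt <= protein.y.grid.times[-1]
    times = mt[keep_cols]
    Xd = gene.X[:, np.searchsorted(mt, times)].T
    s_all = protein.y.grid.times
    y_all = protein.y.values
    preds = []
    for i in np.flatnonzero(s_all <= mt[-1] + 1e-9):
        mask = np.arange(s_all.size) != i
        st, sv = s_all[mask], y_all[mask]
        rows = np.abs(times - s_all[i]) > 1e-9
        if rows.sum() < 3:
            continue
        Xr, tr = Xd[rows], times[rows]
        best = None  # (mse, tau, lam)
        for tau in delays:
            targets = interp_clamped(st, sv, tr + tau)
            lams = lambda_path(Xr, targets, n_lams, eps)
            for lam in lams:
                mse = loocv_oracle(Xr, targets, lam)
                if (
                    best is None
                    or mse < best[0]
                    or (mse == best[0] and tau == best[1] and lam > best[2])
                ):
                    best = (mse, float(tau), float(lam))
        _, tau, lam = best
        targets = interp_clamped(st, sv, tr + tau)
        beta, b0 = lasso_solve(Xr, targets, lam)
        x_at = np.array(
            [
                interp_clamped(mt, gene.X[k], max(s_all[i] - tau, 0.0))[0]
                for k in range(gene.X.shape[0])
            ]
        )
        preds.append((int(i), float(b0 + beta @ x_at), float(y_all[i]), tau, lam))
    return preds


def bh_oracle(p):
    """Step-up BH via explicit sort + reverse cumulative minimum."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        val = min(prev, p[idx] * m / rank)
        q[idx] = val
        prev = val
    return np.minimum(q, 1.0)


def kruskal_oracle(values, groups):
    """Textbook H with midranks and tie correction."""
    values = np.asarray(values, float)
    groups = np.asarray(groups)
    n = values.size
    order = np.argsort(values)
    ranks = np.empty(n)
    sv = values[order]
    i = 0
    while i < n:
        j = i
        while j + 1 < n and sv[j + 1] == sv[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    h = 0.0
    for lab in np.unique(groups):
        r = ranks[groups == lab]
        h += r.sum() ** 2 / r.size
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    # tie correction
    _, counts = np.unique(values, return_counts=True)
    denom = 1.0 - np.sum(counts**3 - counts) / (n**3 - n)
    return h / denom
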