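"""Per-protein delayed L1-penalized linear model.

For a gene with splice-variant expression matrix X(t) and a protein
trajectory Y, the model predicts the delayed protein abundance

    Y(t + tau) = beta . X(t) + intercept + noise

with a sparse coefficient vector beta (one entry per transcript), a penalty
weight lam and a protein-specific delay tau.  (tau, lam) are chosen by
leave-one-out cross-validation on a delay grid x penalty path; truly
out-of-sample predictions come from a double cross-validation in which one
time point is removed before any hyperparameter selection takes place.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import _solver
from .errors import FitError
from .timecourse import (
    DelayGrid,
    Series,
    TimeGrid,
    align_timepoints,
    interpolate_linear,
)

__all__ = [
    "TimeSeriesGene",
    "ProteinSeries",
    "ModelFit",
    "OOSPrediction",
    "lasso_solve",
    "lambda_path",
    "delayed_design",
    "loocv_mse",
    "fit_protein_model",
    "double_cv_predict",
    "fit_dataset",
]

logger = logging.getLogger(__name__)

#: default number of penalties on the regularization path
DEFAULT_N_LAMS = 50
#: ratio between the smallest and largest penalty on the path
LAMBDA_EPS = 1e-3


@dataclass(frozen=True)
class TimeSeriesGene:
    """One gene's splice-variant expression matrix on a time grid.

    ``X`` has one row per transcript and one column per time point.
    """

    gene_id: str
    transcript_ids: tuple[str, ...]
    X: np.ndarray
    grid: TimeGrid

    def __post_init__(self) -> None:
        X = np.atleast_2d(np.asarray(self.X, dtype=float))
        if X.shape[0] != len(self.transcript_ids) or len(self.transcript_ids) < 1:
            raise ValueError(
                f"{self.gene_id}: X has {X.shape[0]} rows but "
                f"{len(self.transcript_ids)} transcript ids"
            )
        if X.shape[1] != len(self.grid):
            raise ValueError(
                f"{self.gene_id}: X has {X.shape[1]} columns but the grid has "
                f"{len(self.grid)} times"
            )
        if not np.all(np.isfinite(X)):
            raise ValueError(f"{self.gene_id}: non-finite transcript abundance")
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "transcript_ids", tuple(self.transcript_ids))

    @property
    def n_transcripts(self) -> int:
        return self.X.shape[0]


@dataclass(frozen=True)
class ProteinSeries:
    """One protein's abundance trajectory."""

    protein_id: str
    gene_id: str
    y: Series

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.y.values)):
            raise ValueError(f"{self.protein_id}: non-finite protein abundance")


@dataclass(frozen=True)
class ModelFit:
    """Fitted coefficients, penalty, delay and CV error for one protein."""

    protein_id: str
    gene_id: str
    transcript_ids: tuple[str, ...]
    beta: np.ndarray
    lam: float
    tau: float
    loocv_mse: float
    intercept: float
    n_nonzero: int = field(init=False)

    def __post_init__(self) -> None:
        beta = np.asarray(self.beta, dtype=float)
        if beta.shape != (len(self.transcript_ids),):
            raise ValueError("beta length must match transcript_ids")
        if self.lam < 0:
            raise ValueError("lam must be >= 0")
        if self.tau < 0:
            raise ValueError("tau must be >= 0")
        object.__setattr__(self, "beta", beta)
        object.__setattr__(self, "transcript_ids", tuple(self.transcript_ids))
        object.__setattr__(self, "n_nonzero", int(np.count_nonzero(beta)))


@dataclass(frozen=True)
class OOSPrediction:
    """A double-cross-validated out-of-sample prediction for one time point.

    The held-out point was excluded from all fitting and hyperparameter
    selection that produced ``predicted``.
    """

    protein_id: str
    heldout_index: int
    predicted: float
    observed: float
    tau_used: float
    lam_used: float


def _check_design(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.size:
        raise ValueError(f"X has {X.shape[0]} rows but y has {y.size} entries")
    if y.size < 2:
        raise ValueError("need at least two observations")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("X and y must be finite")
    return X, y


def lasso_solve(X, y, lam: float) -> tuple[np.ndarray, float]:
    """Minimize ``(1/N)||y - X b - intercept||^2 + lam ||b||_1``.

    ``X`` is (observations x transcripts).  Predictors are standardized and
    the response centered internally; coefficients are returned on the
    original scale together with the intercept.

    Returns
    -------
    (beta, intercept)
    """
    X, y = _check_design(X, y)
    if lam < 0:
        raise ValueError("lam must be >= 0")
    return _solver.solve_standardized(X, y, float(lam))


def lambda_max(X, y) -> float:
    """Smallest penalty at which every coefficient shrinks to zero.

    Closed form: ``(2/N) max_j |xs_j . yc|`` with standardized predictors
    and centered response.
    """
    X, y = _check_design(X, y)
    N = y.size
    yc = y - y.mean()
    mx = X.mean(axis=0)
    sd = np.sqrt(np.mean((X - mx) ** 2, axis=0))
    ok = sd > 0
    if not ok.any():
        return 0.0
    Xs = (X[:, ok] - mx[ok]) / sd[ok]
    return float(2.0 / N * np.max(np.abs(Xs.T @ yc)))


def lambda_path(X, y, n_lams: int = DEFAULT_N_LAMS, eps: float = LAMBDA_EPS) -> np.ndarray:
    """Ascending log-spaced penalty path from ``lam_max * eps`` to ``lam_max``.

    At the largest value the solution is exactly the zero vector.  A
    zero-variance design (or constant response) collapses the path to the
    single unpenalized value ``[0]``.
    """
    if n_lams < 2:
        raise ValueError("n_lams must be >= 2")
    lmax = lambda_max(X, y)
    if lmax == 0.0:
        return np.array([0.0])
    return np.geomspace(lmax * eps, lmax, n_lams)


def _delayed_targets(times: np.ndarray, protein: Series, tau: float) -> np.ndarray:
    return interpolate_linear(protein, times + tau)


def delayed_design(
    g: TimeSeriesGene, p: ProteinSeries, tau: float
) -> tuple[np.ndarray, np.ndarray]:
    """Design matrix and delayed targets for one candidate delay.

    Aligns the two grids, takes transcript abundance at the paired times t
    (rows = time points, columns = transcripts) and interpolates the protein
    trajectory at t + tau (clamped at the protein horizon).
    """
    if tau < 0:
        raise ValueError("tau must be >= 0")
    paired, _ = align_timepoints(g.grid, p.y)
    cols = np.searchsorted(g.grid.times, paired.times)
    X_t = g.X[:, cols].T
    y_shift = _delayed_targets(paired.times, p.y, tau)
    return X_t, y_shift


def loocv_mse(g: TimeSeriesGene, p: ProteinSeries, tau: float, lam: float) -> float:
    """Mean squared leave-one-out residual of the delayed design at (tau, lam)."""
    X_t, y_shift = delayed_design(g, p, tau)
    if y_shift.size < 3:
        raise ValueError("leave-one-out CV needs at least three paired time points")
    return float(_solver.loocv_path(X_t, y_shift, np.array([float(lam)]))[0])


def _as_delays(delays) -> np.ndarray:
    if isinstance(delays, DelayGrid):
        return delays.delays
    d = np.asarray(delays, dtype=float).ravel()
    if d.size < 1 or np.any(d < 0):
        raise ValueError("delays must be non-negative")
    return d


def _select_tau_lam(
    X_by_tau: list[np.ndarray],
    y_by_tau: list[np.ndarray],
    delays: np.ndarray,
    n_lams: int,
    eps: float = LAMBDA_EPS,
) -> tuple[int, float, float]:
    """Grid search over delays x penalty path; returns (tau index, lam, mse).

    Ties are broken toward the smallest tau, then the largest lam (prefer no
    delay and more sparsity absent evidence).
    """
    best = (np.inf, -1, 0.0)
    for ti, tau in enumerate(delays):
        lams = lambda_path(X_by_tau[ti], y_by_tau[ti], n_lams, eps)
        mse = _solver.loocv_path(X_by_tau[ti], y_by_tau[ti], lams)
        # largest lam among within-tau ties (lams are ascending)
        li = int(np.flatnonzero(mse == mse.min())[-1])
        if np.isfinite(mse[li]) and mse[li] < best[0]:
            best = (float(mse[li]), ti, float(lams[li]))
    if best[1] < 0:
        raise FitError("cross-validation surface is all NaN")
    return best[1], best[2], best[0]


def fit_protein_model(
    g: TimeSeriesGene,
    p: ProteinSeries,
    delay_grid,
    n_lams: int = DEFAULT_N_LAMS,
    eps: float = LAMBDA_EPS,
) -> ModelFit:
    """Exhaustive (tau, lam) selection by LOO CV, then a refit on all points.

    ``delay_grid`` may be a :class:`DelayGrid` or any sequence of candidate
    delays in hours (e.g. ``[0.0]`` for the static, no-delay model).
    """
    delays = _as_delays(delay_grid)
    X_by_tau, y_by_tau = [], []
    for tau in delays:
        X_t, y_shift = delayed_design(g, p, tau)
        X_by_tau.append(X_t)
        y_by_tau.append(y_shift)
    if y_by_tau[0].size < 3:
        raise ValueError("need at least three paired time points")
    ti, lam, mse = _select_tau_lam(X_by_tau, y_by_tau, delays, n_lams, eps)
    beta, intercept = lasso_solve(X_by_tau[ti], y_by_tau[ti], lam)
    return ModelFit(
        protein_id=p.protein_id,
        gene_id=g.gene_id,
        transcript_ids=g.transcript_ids,
        beta=beta,
        lam=lam,
        tau=float(delays[ti]),
        loocv_mse=mse,
        intercept=intercept,
    )


def double_cv_predict(
    g: TimeSeriesGene,
    p: ProteinSeries,
    delay_grid,
    n_lams: int = DEFAULT_N_LAMS,
    eps: float = LAMBDA_EPS,
) -> list[OOSPrediction]:
    """Double cross-validation: one unbiased prediction per protein point.

    For every measured protein time point inside the mRNA horizon:
    (1) remove it from the protein series; (2) rebuild the delayed targets
    from the remaining measurements and run leave-one-out CV over the
    design rows for every (tau, lam); (3) refit at the best pair and
    predict the removed measurement from transcript abundance interpolated
    at s_i - tau; (4) repeat for every such point.  The held-out value
    never enters interpolation, fitting or hyperparameter selection.
    """
    delays = _as_delays(delay_grid)
    paired, _ = align_timepoints(g.grid, p.y)
    times = paired.times
    cols = np.searchsorted(g.grid.times, times)
    X_design = g.X[:, cols].T  # (N, p)
    s_all = p.y.grid.times
    y_all = p.y.values
    hold = np.flatnonzero(s_all <= g.grid.times[-1] + 1e-9)
    if hold.size < 4 or times.size < 4:
        raise ValueError("double cross-validation needs at least four paired points")
    tx_series = [Series(g.X[k], g.grid) for k in range(g.n_transcripts)]
    out: list[OOSPrediction] = []
    for i in hold:
        keep = np.arange(s_all.size) != i
        reduced = Series(y_all[keep], TimeGrid(s_all[keep]))
        # drop design rows at the held-out measurement time: training runs
        # on the *remaining* points only
        rows = np.abs(times - s_all[i]) > 1e-9
        if rows.sum() < 3:
            continue
        X_rows = X_design[rows]
        t_rows = times[rows]
        X_by_tau, y_by_tau = [], []
        for tau in delays:
            X_by_tau.append(X_rows)
            y_by_tau.append(_delayed_targets(t_rows, reduced, tau))
        ti, lam, _ = _select_tau_lam(X_by_tau, y_by_tau, delays, n_lams, eps)
        tau = float(delays[ti])
        beta, intercept = lasso_solve(X_rows, y_by_tau[ti], lam)
        # predict the held-out measurement: Y(s_i) = beta . X(s_i - tau)
        x_at = np.array(
            [interpolate_linear(s, max(s_all[i] - tau, 0.0))[0] for s in tx_series]
        )
        out.append(
            OOSPrediction(
                protein_id=p.protein_id,
                heldout_index=int(i),
                predicted=float(intercept + beta @ x_at),
                observed=float(y_all[i]),
                tau_used=tau,
                lam_used=lam,
            )
        )
    return out


def fit_dataset(
    dataset, delay_grid, n_lams: int = DEFAULT_N_LAMS
) -> list[ModelFit]:
    """Fit every (gene, protein) pair; pairs that fail to align are skipped."""
    fits = []
    for g, p in dataset:
        if g.n_transcripts == 0 or not np.any(g.X > 0):
            logger.warning("%s: no expressed transcripts, skipped", p.protein_id)
            continue
        try:
            fits.append(fit_protein_model(g, p, delay_grid, n_lams))
        except (ValueError, FitError) as exc:
            logger.warning("%s: skipped (%s)", p.protein_id, exc)
    return fits
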