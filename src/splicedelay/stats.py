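"""Correlation-based model evaluation and enrichment statistics.

Four model classes are compared per gene: summed splice-variant expression,
the best single splice variant, the cross-validated static multi-variant
model (delay forced to 0) and the cross-validated delayed multi-variant
model.  Enrichment of significant correlations is assessed with exact
binomial tail probabilities computed in log space.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .model import (
    OOSPrediction,
    TimeSeriesGene,
    ProteinSeries,
    double_cv_predict,
    fit_dataset,
)
from .timecourse import Series, TimeGrid, align_timepoints

__all__ = [
    "CorrelationSummary",
    "EnrichmentResult",
    "pearson",
    "correlation_table",
    "median_by_class",
    "significance_threshold",
    "expected_significant",
    "binomial_enrichment",
    "directional_agreement_p",
    "scramble_control",
    "evaluate_dataset",
]

MODEL_CLASSES = ("sum", "best_single", "static_multi", "delayed_multi")


@dataclass(frozen=True)
class CorrelationSummary:
    """Per-gene Pearson correlations under the four model classes.

    Entries are ``None`` where a class is undefined for the gene (e.g. zero
    variance in either vector).
    """

    gene_id: str
    rho_sum: float | None
    rho_best_single: float | None
    rho_static_multi: float | None
    rho_delayed_multi: float | None


@dataclass(frozen=True)
class EnrichmentResult:
    """One-sided exact binomial enrichment of an observed count."""

    observed: int
    expected: float
    n: int
    p0: float
    p_value: float
    log10_p: float
    odds_ratio: float


def pearson(x, y) -> float | None:
    """Product-moment correlation; ``None`` when undefined (zero variance)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("pearson needs two equal-length vectors of length >= 3")
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        return None
    return float(sps.pearsonr(x, y).statistic)


def _oos_rho(preds: list[OOSPrediction] | None) -> float | None:
    if not preds:
        return None
    obs = np.array([p.observed for p in preds])
    est = np.array([p.predicted for p in preds])
    if obs.size < 3 or np.std(obs) == 0.0 or np.std(est) == 0.0:
        return None
    return pearson(obs, est)


def correlation_table(
    dataset,
    oos_delayed: dict[str, list[OOSPrediction]] | None = None,
    oos_static: dict[str, list[OOSPrediction]] | None = None,
) -> list[CorrelationSummary]:
    """Per-gene correlation of observed protein with the four model classes.

    ``dataset`` is an iterable of ``(TimeSeriesGene, ProteinSeries)``.  The
    two prediction dictionaries map protein ids to out-of-sample predictions
    of the delayed and the static (tau = 0) multi-variant models; classes
    without predictions are left missing.
    """
    out = []
    for g, p in dataset:
        paired, aligned = align_timepoints(g.grid, p.y)
        cols = np.searchsorted(g.grid.times, paired.times)
        Xp = g.X[:, cols]
        yv = aligned.values
        rho_sum = pearson(Xp.sum(axis=0), yv) if np.std(yv) > 0 else None
        rho_best = None
        for k in range(Xp.shape[0]):
            r = pearson(Xp[k], yv) if np.std(yv) > 0 else None
            if r is not None and (rho_best is None or abs(r) > abs(rho_best)):
                rho_best = r
        out.append(
            CorrelationSummary(
                gene_id=g.gene_id,
                rho_sum=rho_sum,
                rho_best_single=rho_best,
                rho_static_multi=_oos_rho((oos_static or {}).get(p.protein_id)),
                rho_delayed_multi=_oos_rho((oos_delayed or {}).get(p.protein_id)),
            )
        )
    return out


def median_by_class(summaries: list[CorrelationSummary]) -> dict[str, float]:
    """Median rho per model class, ignoring missing entries (NaN if all missing)."""
    cols = {
        "sum": [s.rho_sum for s in summaries],
        "best_single": [s.rho_best_single for s in summaries],
        "static_multi": [s.rho_static_multi for s in summaries],
        "delayed_multi": [s.rho_delayed_multi for s in summaries],
    }
    out = {}
    for name, vals in cols.items():
        vals = [v for v in vals if v is not None]
        out[name] = float(np.median(vals)) if vals else float("nan")
    return out


def significance_threshold(n_points: int, alpha: float = 0.05) -> float:
    """Two-sided critical |rho| from the t distribution with n - 2 df."""
    if n_points < 3:
        raise ValueError("need at least three points")
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    df = n_points - 2
    tc = sps.t.ppf(1 - alpha / 2, df)
    return float(tc / math.sqrt(df + tc**2))


def expected_significant(n_genes: int, tail_prob: float) -> float:
    """Expected count of per-gene significant correlations under the null."""
    if n_genes < 0:
        raise ValueError("n_genes must be >= 0")
    if not 0 <= tail_prob <= 1:
        raise ValueError("tail_prob must be a probability")
    return n_genes * tail_prob


def binomial_enrichment(
    observed: int, n: int, p0: float, direction: str = "greater"
) -> EnrichmentResult:
    """Exact one-sided binomial tail probability, stable in extreme tails.

    The upper tail (``direction="greater"``) tests enrichment of the
    observed count over the null expectation ``n * p0``; the tail is
    computed in log space so that p-values far below float underflow are
    still reported via ``log10_p``.
    """
    if not 0 <= observed <= n:
        raise ValueError("need 0 <= observed <= n")
    if not 0.0 < p0 < 1.0:
        raise ValueError("p0 must be in (0, 1)")
    if direction == "greater":
        logp = sps.binom.logsf(observed - 1, n, p0)  # P[K >= observed]
    elif direction == "less":
        logp = sps.binom.logcdf(observed, n, p0)
    else:
        raise ValueError("direction must be 'greater' or 'less'")
    logp = float(min(logp, 0.0))
    expected = n * p0
    if observed in (0, n) or expected in (0, n):
        odds = math.inf if observed > expected else 0.0
        if observed == expected:
            odds = 1.0
    else:
        odds = (observed / (n - observed)) / (expected / (n - expected))
    return EnrichmentResult(
        observed=int(observed),
        expected=float(expected),
        n=int(n),
        p0=float(p0),
        p_value=float(math.exp(logp)),
        log10_p=logp / math.log(10),
        odds_ratio=float(odds),
    )


def directional_agreement_p(per_protein_match_probs) -> float:
    """Probability that every predicted direction agrees with external
    reports by chance: the product of per-protein chance-match probabilities.
    """
    probs = np.asarray(list(per_protein_match_probs), dtype=float)
    if probs.size == 0:
        return 1.0
    if np.any(probs <= 0) or np.any(probs > 1):
        raise ValueError("match probabilities must lie in (0, 1]")
    return float(np.prod(probs))


def evaluate_dataset(
    dataset, delay_grid, n_lams: int = 20
) -> tuple[list, dict[str, list[OOSPrediction]], dict[str, list[OOSPrediction]], list[CorrelationSummary]]:
    """Fit, cross-validate and correlate a whole dataset.

    Returns ``(fits, oos_delayed, oos_static, correlation summaries)``.
    """
    fits = fit_dataset(dataset, delay_grid, n_lams)
    oos_delayed: dict[str, list[OOSPrediction]] = {}
    oos_static: dict[str, list[OOSPrediction]] = {}
    for g, p in dataset:
        try:
            oos_delayed[p.protein_id] = double_cv_predict(g, p, delay_grid, n_lams)
            oos_static[p.protein_id] = double_cv_predict(g, p, [0.0], n_lams)
        except ValueError:
            continue
    table = correlation_table(dataset, oos_delayed, oos_static)
    return fits, oos_delayed, oos_static, table


def scramble_control(
    dataset,
    n_perm: int,
    seed: int,
    delay_grid=None,
    n_lams: int = 20,
) -> np.ndarray:
    """Null distribution of the median delayed-model correlation under
    protein time-point scrambling.

    Each permutation shuffles the order of every protein's measured values
    (grids unchanged) with a seeded generator, reruns the double
    cross-validation and records the median per-gene correlation between the
    scrambled observations and their out-of-sample predictions.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if delay_grid is None:
        delay_grid = [0.0, 1.0, 2.0, 6.0, 24.0]
    rng = np.random.default_rng(seed)
    medians = np.empty(n_perm)
    for b in range(n_perm):
        rhos = []
        for g, p in dataset:
            perm = rng.permutation(len(p.y))
            p_scr = ProteinSeries(
                p.protein_id, p.gene_id, Series(p.y.values[perm], p.y.grid)
            )
            try:
                preds = double_cv_predict(g, p_scr, delay_grid, n_lams)
            except ValueError:
                continue
            r = _oos_rho(preds)
            if r is not None:
                rhos.append(r)
        medians[b] = np.median(rhos) if rhos else np.nan
    return medians
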