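"""Differential predicted-protein (DEPP) screening on case/control cohorts.

Raw transcript counts are z-normalized per transcript across samples,
combined into per-sample predicted-protein scores with the fitted model
coefficients, and tested for group differences with a Kruskal-Wallis test;
Benjamini-Hochberg FDR is applied across all tested proteins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .model import ModelFit

__all__ = [
    "CohortMatrix",
    "DEPPResult",
    "GainReport",
    "znormalize",
    "predict_protein_cohort",
    "kruskal_wallis",
    "bh_fdr",
    "depp_analysis",
    "per_transcript_tests",
    "model_gain",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CohortMatrix:
    """Transcripts x samples expression with per-sample group labels."""

    transcript_ids: tuple[str, ...]
    counts: np.ndarray
    sample_ids: tuple[str, ...]
    group_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        counts = np.atleast_2d(np.asarray(self.counts, dtype=float))
        if counts.shape != (len(self.transcript_ids), len(self.sample_ids)):
            raise ValueError(
                f"counts shape {counts.shape} inconsistent with "
                f"{len(self.transcript_ids)} transcripts x {len(self.sample_ids)} samples"
            )
        if len(self.group_labels) != len(self.sample_ids):
            raise ValueError("one group label per sample required")
        labels, sizes = np.unique(self.group_labels, return_counts=True)
        if labels.size < 2:
            raise ValueError("need at least two sample groups")
        if np.any(sizes < 2):
            raise ValueError("every group needs at least two samples")
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "transcript_ids", tuple(self.transcript_ids))
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        object.__setattr__(self, "group_labels", tuple(self.group_labels))

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def row_index(self) -> dict[str, int]:
        return {t: i for i, t in enumerate(self.transcript_ids)}


@dataclass(frozen=True)
class DEPPResult:
    """One protein's differential predicted-protein test."""

    protein_id: str
    score_per_sample: np.ndarray
    kw_stat: float
    p_value: float
    q_value: float
    n_transcripts_used: int


@dataclass(frozen=True)
class GainReport:
    """Nominal-significance gain of model scores over ingoing transcripts."""

    frac_proteins: float
    frac_transcripts: float
    n_proteins: int
    n_transcripts: int
    p_value: float
    alpha: float


def znormalize(counts) -> np.ndarray:
    """Per-row z-scores across samples; zero-variance rows map to zeros."""
    counts = np.atleast_2d(np.asarray(counts, dtype=float))
    if counts.shape[1] < 2:
        raise ValueError("z-normalization needs at least two samples")
    mean = counts.mean(axis=1, keepdims=True)
    sd = counts.std(axis=1, keepdims=True)
    z = np.zeros_like(counts)
    # relative tolerance: float cancellation can give a constant row a tiny
    # nonzero sd, which would blow up into spurious +-1 z-scores
    ok = sd[:, 0] > 1e-12 * np.maximum(1.0, np.abs(mean[:, 0]))
    z[ok] = (counts[ok] - mean[ok]) / sd[ok]
    return z


def predict_protein_cohort(
    z: np.ndarray, fit: ModelFit, row_index: dict[str, int]
) -> tuple[np.ndarray, int] | None:
    """Per-sample predicted-protein score ``sum_k beta_k z_k``.

    ``row_index`` maps transcript ids to rows of ``z``.  Transcripts with a
    nonzero coefficient that are absent from the cohort are dropped (their
    z-score is treated as 0); if no nonzero-coefficient transcript is
    present, ``None`` is returned.  Returns ``(scores, n_transcripts_used)``.
    """
    score = np.zeros(z.shape[1])
    used = 0
    for tid, b in zip(fit.transcript_ids, fit.beta):
        if b == 0.0:
            continue
        row = row_index.get(tid)
        if row is None:
            logger.warning(
                "%s: transcript %s missing from cohort, term dropped",
                fit.protein_id,
                tid,
            )
            continue
        score += b * z[row]
        used += 1
    if used == 0:
        return None
    return score, used


def kruskal_wallis(values, groups) -> tuple[float, float]:
    """Kruskal-Wallis H (midrank tie correction) and chi-square p-value.

    All-tied values give ``(0, 1)``.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.shape != groups.shape:
        raise ValueError("values and groups must have equal length")
    labels, sizes = np.unique(groups, return_counts=True)
    if labels.size < 2 or np.any(sizes < 2):
        raise ValueError("need >= 2 groups with >= 2 members each")
    samples = [values[groups == lab] for lab in labels]
    if np.all(values == values[0]):
        return 0.0, 1.0
    h, p = sps.kruskal(*samples)
    return float(h), float(p)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def depp_analysis(cohort: CohortMatrix, atlas: list[ModelFit]) -> list[DEPPResult]:
    """Full DEPP screen: z-normalize, score, test, BH-adjust, sort by q."""
    if not atlas:
        return []
    z = znormalize(cohort.counts)
    row_index = cohort.row_index()
    groups = np.asarray(cohort.group_labels)
    rows = []
    for fit in atlas:
        scored = predict_protein_cohort(z, fit, row_index)
        if scored is None:
            logger.warning("%s: no overlapping transcripts, skipped", fit.protein_id)
            continue
        score, used = scored
        h, p = kruskal_wallis(score, groups)
        rows.append((fit.protein_id, score, h, p, used))
    if not rows:
        return []
    q = bh_fdr([r[3] for r in rows])
    results = [
        DEPPResult(
            protein_id=pid,
            score_per_sample=score,
            kw_stat=h,
            p_value=p,
            q_value=float(qv),
            n_transcripts_used=used,
        )
        for (pid, score, h, p, used), qv in zip(rows, q)
    ]
    results.sort(key=lambda r: (r.q_value, r.p_value, r.protein_id))
    return results


def per_transcript_tests(
    cohort: CohortMatrix, transcript_ids=None
) -> dict[str, float]:
    """Kruskal-Wallis p-value per transcript on the raw cohort counts."""
    groups = np.asarray(cohort.group_labels)
    index = cohort.row_index()
    ids = list(transcript_ids) if transcript_ids is not None else list(cohort.transcript_ids)
    out = {}
    for tid in ids:
        row = index.get(tid)
        if row is None:
            continue
        _, p = kruskal_wallis(cohort.counts[row], groups)
        out[tid] = p
    return out


def model_gain(
    depp: list[DEPPResult],
    transcript_tests: dict[str, float],
    alpha: float = 0.05,
) -> GainReport:
    """Fractions of nominally significant predicted proteins vs ingoing
    transcripts, with a one-sided binomial comparison of the two.

    The protein-significant count is tested against the transcript fraction
    as the null rate (floored at ``alpha`` so a signal-free transcript set
    does not make the comparison trivially significant).
    """
    if not depp or not transcript_tests:
        raise ValueError("model_gain needs non-empty DEPP and transcript results")
    n_prot = len(depp)
    k_prot = sum(1 for r in depp if r.p_value < alpha)
    tvals = np.array(list(transcript_tests.values()))
    n_tx = tvals.size
    k_tx = int(np.sum(tvals < alpha))
    frac_tx = k_tx / n_tx
    p0 = min(max(frac_tx, alpha), 1.0 - 1e-12)
    p = float(sps.binomtest(k_prot, n_prot, p0, alternative="greater").pvalue)
    return GainReport(
        frac_proteins=k_prot / n_prot,
        frac_transcripts=frac_tx,
        n_proteins=n_prot,
        n_transcripts=n_tx,
        p_value=p,
        alpha=alpha,
    )
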