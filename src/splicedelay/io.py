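"""Tab-separated readers/writers and run configuration.

All formats are plain TSV with a header row.  Temporal column names carry a
unit suffix (``0h``, ``30min``, ``2d``) and are converted to hours at parse
time; columns without a parseable unit are treated as sample ids.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .depp import CohortMatrix, DEPPResult, GainReport
from .errors import ParseError
from .model import ModelFit, ProteinSeries, TimeSeriesGene
from .simulate import SyntheticTruth
from .stats import CorrelationSummary
from .timecourse import Series, TimeGrid

__all__ = [
    "MappingTable",
    "RunConfig",
    "read_expression_table",
    "read_protein_table",
    "read_mapping",
    "read_sample_sheet",
    "read_cohort",
    "write_model_atlas",
    "read_model_atlas",
    "write_depp",
    "write_correlation_report",
    "write_expression_table",
    "write_protein_table",
    "write_mapping",
    "write_cohort",
    "write_truth_table",
    "read_truth_table",
]

_TIME_RE = re.compile(r"^([0-9]*\.?[0-9]+)\s*(h|hr|hrs|hour|hours|min|m|d|day|days)$", re.I)
_TIME_FACTORS = {
    "h": 1.0, "hr": 1.0, "hrs": 1.0, "hour": 1.0, "hours": 1.0,
    "min": 1.0 / 60.0, "m": 1.0 / 60.0,
    "d": 24.0, "day": 24.0, "days": 24.0,
}


def _parse_time_column(name: str) -> float | None:
    m = _TIME_RE.match(name.strip())
    if m is None:
        return None
    return float(m.group(1)) * _TIME_FACTORS[m.group(2).lower()]


def _format_time_column(hours: float) -> str:
    if hours < 1.0 and hours > 0:
        minutes = hours * 60.0
        return f"{minutes:g}min"
    return f"{hours:g}h"


@dataclass(frozen=True)
class MappingTable:
    """gene <-> transcript <-> protein identifier mapping.

    Transcript ids are unique per gene and every protein maps to exactly
    one gene.
    """

    rows: tuple[tuple[str, str, str], ...]
    gene_of_protein: dict[str, str] = field(init=False)
    transcripts_of_gene: dict[str, tuple[str, ...]] = field(init=False)

    def __post_init__(self) -> None:
        gene_of_protein: dict[str, str] = {}
        tx: dict[str, list[str]] = {}
        for gene_id, transcript_id, protein_id in self.rows:
            prev = gene_of_protein.get(protein_id)
            if prev is not None and prev != gene_id:
                raise ParseError(
                    f"protein {protein_id} maps to two genes ({prev}, {gene_id})"
                )
            gene_of_protein[protein_id] = gene_id
            bucket = tx.setdefault(gene_id, [])
            if transcript_id in bucket:
                raise ParseError(
                    f"transcript {transcript_id} duplicated under gene {gene_id}"
                )
            bucket.append(transcript_id)
        object.__setattr__(self, "gene_of_protein", gene_of_protein)
        object.__setattr__(
            self, "transcripts_of_gene", {g: tuple(t) for g, t in tx.items()}
        )


@dataclass
class RunConfig:
    """Validated run parameters with documented defaults."""

    delay_n: int = 200
    delay_max: float = 24.0
    n_lams: int = 50
    alpha: float = 0.05
    fdr: float = 0.05
    extrapolation: str = "clamp"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.delay_n < 2:
            raise ValueError("delay_n must be >= 2")
        if self.delay_max <= 0:
            raise ValueError("delay_max must be positive")
        if self.n_lams < 2:
            raise ValueError("n_lams must be >= 2")
        if not (0 < self.alpha <= 1 and 0 < self.fdr <= 1):
            raise ValueError("alpha and fdr must lie in (0, 1]")
        if self.extrapolation not in ("clamp", "linear"):
            raise ValueError("extrapolation must be 'clamp' or 'linear'")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ParseError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _read_tsv(path, required: list[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except Exception as exc:  # noqa: BLE001 - rewrap with file context
        raise ParseError(f"{path}: cannot read TSV ({exc})") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    return df


def _numeric_block(df: pd.DataFrame, cols: list[str], path) -> np.ndarray:
    block = np.empty((len(df), len(cols)))
    for j, c in enumerate(cols):
        vals = pd.to_numeric(df[c], errors="coerce")
        bad = vals.isna() & df[c].notna() | df[c].isna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ParseError(
                f"{path}: non-numeric value {df[c].iloc[row]!r} at row {row + 2}, "
                f"column {c!r}"
            )
        block[:, j] = vals.to_numpy()
    return block


def read_expression_table(path):
    """Read a transcript abundance TSV.

    Expected columns: ``gene_id``, ``transcript_id`` and then either time
    columns (unit suffix, converted to hours) or sample-id columns.

    Returns
    -------
    (gene_ids, transcript_ids, values, grid, sample_ids)
        ``grid`` is a :class:`TimeGrid` when all value columns are temporal
        (``sample_ids`` is then None), and vice versa.
    """
    df = _read_tsv(path, ["gene_id", "transcript_id"])
    value_cols = [c for c in df.columns if c not in ("gene_id", "transcript_id")]
    if not value_cols:
        raise ParseError(f"{path}: no value columns")
    dup = df.duplicated(subset=["gene_id", "transcript_id"])
    if dup.any():
        tid = df.loc[dup, "transcript_id"].iloc[0]
        raise ParseError(f"{path}: duplicated transcript row {tid!r}")
    times = [_parse_time_column(c) for c in value_cols]
    values = _numeric_block(df, value_cols, path)
    gene_ids = df["gene_id"].tolist()
    transcript_ids = df["transcript_id"].tolist()
    if all(t is not None for t in times):
        order = np.argsort(times)
        grid = TimeGrid(np.asarray(times, dtype=float)[order])
        return gene_ids, transcript_ids, values[:, order], grid, None
    return gene_ids, transcript_ids, values, None, value_cols


def genes_from_expression(path) -> dict[str, TimeSeriesGene]:
    """Group a temporal expression table into per-gene objects."""
    gene_ids, transcript_ids, values, grid, sample_ids = read_expression_table(path)
    if grid is None:
        raise ParseError(f"{path}: expected temporal columns, found sample ids")
    genes: dict[str, TimeSeriesGene] = {}
    buckets: dict[str, list[int]] = {}
    for i, g in enumerate(gene_ids):
        buckets.setdefault(g, []).append(i)
    for g, idx in buckets.items():
        genes[g] = TimeSeriesGene(
            gene_id=g,
            transcript_ids=tuple(transcript_ids[i] for i in idx),
            X=values[idx],
            grid=grid,
        )
    return genes


def read_protein_table(path) -> dict[str, ProteinSeries]:
    """Read a protein abundance TSV: protein_id, gene_id, then time columns."""
    df = _read_tsv(path, ["protein_id", "gene_id"])
    value_cols = [c for c in df.columns if c not in ("protein_id", "gene_id")]
    times = [_parse_time_column(c) for c in value_cols]
    if not value_cols or any(t is None for t in times):
        raise ParseError(f"{path}: protein table needs temporal columns")
    if df["protein_id"].duplicated().any():
        pid = df.loc[df["protein_id"].duplicated(), "protein_id"].iloc[0]
        raise ParseError(f"{path}: duplicated protein row {pid!r}")
    values = _numeric_block(df, value_cols, path)
    order = np.argsort(times)
    grid = TimeGrid(np.asarray(times, dtype=float)[order])
    out = {}
    for i, row in df.iterrows():
        out[row["protein_id"]] = ProteinSeries(
            protein_id=row["protein_id"],
            gene_id=row["gene_id"],
            y=Series(values[i, order], grid),
        )
    return out


def read_mapping(path) -> MappingTable:
    df = _read_tsv(path, ["gene_id", "transcript_id", "protein_id"])
    return MappingTable(
        rows=tuple(
            (r.gene_id, r.transcript_id, r.protein_id) for r in df.itertuples()
        )
    )


def read_sample_sheet(path) -> dict[str, str]:
    df = _read_tsv(path, ["sample_id", "group"])
    if df["sample_id"].duplicated().any():
        raise ParseError(f"{path}: duplicated sample_id")
    return dict(zip(df["sample_id"], df["group"]))


def read_cohort(expression_path, sample_sheet_path) -> CohortMatrix:
    """Cohort matrix from a sample-column expression table + sample sheet."""
    gene_ids, transcript_ids, values, grid, sample_ids = read_expression_table(
        expression_path
    )
    if sample_ids is None:
        raise ParseError(f"{expression_path}: expected sample columns, found times")
    groups = read_sample_sheet(sample_sheet_path)
    missing = [s for s in sample_ids if s not in groups]
    if missing:
        raise ParseError(f"{sample_sheet_path}: no group for samples {missing}")
    return CohortMatrix(
        transcript_ids=tuple(transcript_ids),
        counts=values,
        sample_ids=tuple(sample_ids),
        group_labels=tuple(groups[s] for s in sample_ids),
    )


_F = "%.17g"  # lossless float round-trip


def write_model_atlas(fits: list[ModelFit], path) -> None:
    """One TSV row per protein; coefficients as ``transcript:beta`` pairs."""
    lines = ["protein_id\tgene_id\ttau_hours\tlambda\tloocv_mse\tintercept\tbetas"]
    for f in fits:
        pairs = ",".join(
            f"{t}:{_F % b}" for t, b in zip(f.transcript_ids, f.beta)
        )
        lines.append(
            f"{f.protein_id}\t{f.gene_id}\t{_F % f.tau}\t{_F % f.lam}\t"
            f"{_F % f.loocv_mse}\t{_F % f.intercept}\t{pairs}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_model_atlas(path) -> list[ModelFit]:
    df = _read_tsv(
        path,
        ["protein_id", "gene_id", "tau_hours", "lambda", "loocv_mse", "intercept", "betas"],
    )
    df = df.rename(columns={"lambda": "lam"})
    fits = []
    for r in df.itertuples():
        try:
            pairs = [item.rsplit(":", 1) for item in r.betas.split(",")]
            tids = tuple(t for t, _ in pairs)
            beta = np.array([float(b) for _, b in pairs])
        except (ValueError, AttributeError) as exc:
            raise ParseError(f"{path}: malformed betas field {r.betas!r}") from exc
        fits.append(
            ModelFit(
                protein_id=r.protein_id,
                gene_id=r.gene_id,
                transcript_ids=tids,
                beta=beta,
                lam=float(r.lam),
                tau=float(r.tau_hours),
                loocv_mse=float(r.loocv_mse),
                intercept=float(r.intercept),
            )
        )
    return fits


def write_depp(results: list[DEPPResult], path, gain: GainReport | None = None) -> None:
    lines = ["protein_id\tkw_stat\tp_value\tq_value\tn_transcripts_used"]
    for r in results:
        lines.append(
            f"{r.protein_id}\t{_F % r.kw_stat}\t{_F % r.p_value}\t"
            f"{_F % r.q_value}\t{r.n_transcripts_used}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
    if gain is not None:
        gain_path = Path(path).with_suffix(".gain.txt")
        gain_path.write_text(
            "model gain report\n"
            f"nominal alpha: {gain.alpha}\n"
            f"predicted proteins with p < alpha: {gain.frac_proteins:.4f} "
            f"(of {gain.n_proteins})\n"
            f"ingoing transcripts with p < alpha: {gain.frac_transcripts:.4f} "
            f"(of {gain.n_transcripts})\n"
            f"one-sided binomial p-value: {gain.p_value:.3e}\n"
        )


def write_correlation_report(
    summaries: list[CorrelationSummary], path, medians: dict[str, float] | None = None
) -> None:
    def fmt(v):
        return _F % v if v is not None else "NA"

    lines = ["gene_id\trho_sum\trho_best_single\trho_static_multi\trho_delayed_multi"]
    for s in summaries:
        lines.append(
            f"{s.gene_id}\t{fmt(s.rho_sum)}\t{fmt(s.rho_best_single)}\t"
            f"{fmt(s.rho_static_multi)}\t{fmt(s.rho_delayed_multi)}"
        )
    if medians:
        lines.append("# medians\t" + "\t".join(f"{k}={v:.4f}" for k, v in medians.items()))
    Path(path).write_text("\n".join(lines) + "\n")


def write_expression_table(dataset, path) -> None:
    """Write per-gene transcript matrices as a temporal expression TSV."""
    genes = [g for g, _ in dataset]
    grid = genes[0].grid
    header = "gene_id\ttranscript_id\t" + "\t".join(
        _format_time_column(t) for t in grid.times
    )
    lines = [header]
    for g in genes:
        for k, tid in enumerate(g.transcript_ids):
            vals = "\t".join(_F % v for v in g.X[k])
            lines.append(f"{g.gene_id}\t{tid}\t{vals}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_protein_table(dataset, path) -> None:
    proteins = [p for _, p in dataset]
    grid = proteins[0].y.grid
    header = "protein_id\tgene_id\t" + "\t".join(
        _format_time_column(t) for t in grid.times
    )
    lines = [header]
    for p in proteins:
        vals = "\t".join(_F % v for v in p.y.values)
        lines.append(f"{p.protein_id}\t{p.gene_id}\t{vals}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_mapping(dataset, path) -> None:
    lines = ["gene_id\ttranscript_id\tprotein_id"]
    for g, p in dataset:
        for tid in g.transcript_ids:
            lines.append(f"{g.gene_id}\t{tid}\t{p.protein_id}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_cohort(cohort: CohortMatrix, expression_path, sample_sheet_path) -> None:
    header = "gene_id\ttranscript_id\t" + "\t".join(cohort.sample_ids)
    lines = [header]
    for i, tid in enumerate(cohort.transcript_ids):
        gene = tid.rsplit(".", 1)[0]
        vals = "\t".join(_F % v for v in cohort.counts[i])
        lines.append(f"{gene}\t{tid}\t{vals}")
    Path(expression_path).write_text("\n".join(lines) + "\n")
    sheet = ["sample_id\tgroup"]
    for s, g in zip(cohort.sample_ids, cohort.group_labels):
        sheet.append(f"{s}\t{g}")
    Path(sample_sheet_path).write_text("\n".join(sheet) + "\n")


def write_truth_table(truths: list[SyntheticTruth], path) -> None:
    lines = ["gene_id\ttranscript_ids\tbeta_true\ttau_true\tsigma\tsigma_is_relative"]
    for t in truths:
        lines.append(
            f"{t.gene_id}\t{','.join(t.transcript_ids)}\t"
            f"{','.join(_F % b for b in t.beta_true)}\t{_F % t.tau_true}\t"
            f"{_F % t.sigma}\t{int(t.sigma_is_relative)}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_truth_table(path) -> list[SyntheticTruth]:
    df = _read_tsv(
        path,
        ["gene_id", "transcript_ids", "beta_true", "tau_true", "sigma", "sigma_is_relative"],
    )
    return [
        SyntheticTruth(
            gene_id=r.gene_id,
            transcript_ids=tuple(r.transcript_ids.split(",")),
            beta_true=np.array([float(b) for b in r.beta_true.split(",")]),
            tau_true=float(r.tau_true),
            sigma=float(r.sigma),
            sigma_is_relative=bool(int(r.sigma_is_relative)),
        )
        for r in df.itertuples()
    ]
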