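"""Expression thresholding, differential-expression intake and cis-pairing.

Expression is supplied as an FPKM matrix (genes x samples) with a sample
sidecar giving each sample's cell type and condition (control/stimulated).
Differential expression arrives pre-computed, one record per gene per cell
type with a log2 fold change and an FDR-adjusted q-value; this module only
filters and summarizes it.

Cell-type specificity is summarized as a multiplicity spectrum: for k
cell types, how many genes appear in exactly k of the per-cell-type sets
(a Venn diagram collapsed onto its overlap orders).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import GeneModel
from .catalog import CatalogRecord, PositionalClass

__all__ = [
    "ExpressionMatrix",
    "DERecord",
    "CorrelationResult",
    "ExpressionError",
    "round_half_up",
    "expressed_genes",
    "multiplicity_summary",
    "class_distribution",
    "de_filter",
    "expression_stats",
    "nearest_coding_gene",
    "genes_within_window",
    "fold_change_correlation",
    "read_expression_matrix",
    "read_de_table",
]


class ExpressionError(ValueError):
    pass


def round_half_up(x: float) -> int:
    """Round to nearest integer, halves away from zero upward (display rule)."""
    return int(math.floor(x + 0.5))


@dataclass
class ExpressionMatrix:
    """FPKM per gene per sample plus per-sample (cell_type, condition) labels."""

    values: pd.DataFrame  # genes x samples, non-negative FPKM
    sample_meta: pd.DataFrame  # index: sample; columns: cell_type, condition

    def __post_init__(self) -> None:
        if (self.values.to_numpy() < 0).any():
            raise ExpressionError("negative FPKM values")
        missing = set(self.values.columns) - set(self.sample_meta.index)
        if missing:
            raise ExpressionError(f"samples without metadata: {sorted(missing)}")
        bad = set(self.sample_meta["condition"]) - {"control", "stimulated"}
        if bad:
            raise ExpressionError(f"unknown conditions: {sorted(bad)}")

    @property
    def cell_types(self) -> list[str]:
        return sorted(self.sample_meta["cell_type"].unique())

    def condition_means(self) -> pd.DataFrame:
        """Mean FPKM per gene for each (cell_type, condition) sample group."""
        groups = self.sample_meta.groupby(["cell_type", "condition"]).groups
        cols = {
            (ct, cond): self.values[list(samples)].mean(axis=1)
            for (ct, cond), samples in groups.items()
        }
        out = pd.DataFrame(cols)
        out.columns = pd.MultiIndex.from_tuples(out.columns, names=["cell_type", "condition"])
        return out


@dataclass(frozen=True)
class DERecord:
    gene_id: str
    cell_type: str
    log2fc: float
    q_value: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.q_value <= 1.0:
            raise ExpressionError(
                f"q-value {self.q_value} outside [0, 1] for {self.gene_id}"
            )


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p_value: float
    n: int


def expressed_genes(
    matrix: ExpressionMatrix, threshold: float = 1.0
) -> dict[str, set[str]]:
    """Per cell type, genes whose mean FPKM strictly exceeds ``threshold``
    in the control condition or in the stimulated condition."""
    means = matrix.condition_means()
    out: dict[str, set[str]] = {}
    for ct in matrix.cell_types:
        sub = means[ct]
        mask = (sub > threshold).any(axis=1)
        out[ct] = set(sub.index[mask])
    return out


@dataclass
class MultiplicitySummary:
    counts: dict[int, int]  # multiplicity k -> number of genes in exactly k sets
    union_size: int
    percentages: dict[int, float]  # unrounded, of union
    rounded: dict[int, int]

    def genes_at(self, k: int) -> int:
        return self.counts.get(k, 0)


def multiplicity_summary(sets: Mapping[str, set[str]]) -> MultiplicitySummary:
    """Collapse per-cell-type gene sets onto their overlap-order spectrum."""
    if not sets:
        raise ExpressionError("need at least one gene set")
    union: dict[str, int] = {}
    for s in sets.values():
        for g in s:
            union[g] = union.get(g, 0) + 1
    n_sets = len(sets)
    counts = {k: 0 for k in range(1, n_sets + 1)}
    for mult in union.values():
        counts[mult] += 1
    total = len(union)
    pct = {k: (100.0 * c / total if total else 0.0) for k, c in counts.items()}
    return MultiplicitySummary(
        counts, total, pct, {k: round_half_up(p) for k, p in pct.items()}
    )


@dataclass
class ClassDistribution:
    counts: dict[PositionalClass, int]
    total: int  # EXCLUDED_SAME_STRAND records are not in the denominator
    percentages: dict[PositionalClass, float]
    rounded: dict[PositionalClass, int]


def class_distribution(
    records: Iterable[CatalogRecord | PositionalClass],
) -> ClassDistribution:
    """Count positional classes; percentages over non-excluded records."""
    labels = [
        r.positional_class if isinstance(r, CatalogRecord) else PositionalClass(r)
        for r in records
    ]
    counts: dict[PositionalClass, int] = {}
    for lab in labels:
        counts[lab] = counts.get(lab, 0) + 1
    total = sum(
        c for lab, c in counts.items() if lab is not PositionalClass.EXCLUDED_SAME_STRAND
    )
    pct = {
        lab: 100.0 * c / total
        for lab, c in counts.items()
        if lab is not PositionalClass.EXCLUDED_SAME_STRAND and total
    }
    return ClassDistribution(counts, total, pct, {k: round_half_up(v) for k, v in pct.items()})


def de_filter(
    records: Iterable[DERecord], alpha: float = 0.05
) -> tuple[dict[str, set[str]], set[str]]:
    """Per-cell-type sets of differentially expressed genes (q strictly < alpha),
    plus their union."""
    sets: dict[str, set[str]] = {}
    for rec in records:
        sets.setdefault(rec.cell_type, set())
        if rec.q_value < alpha:
            sets[rec.cell_type].add(rec.gene_id)
    union = set().union(*sets.values()) if sets else set()
    return sets, union


def expression_stats(
    gene_ids: Iterable[str], matrix: ExpressionMatrix
) -> tuple[float, float]:
    """Mean and SEM of per-gene peak expression.

    Each gene contributes its maximum condition-mean FPKM over all
    (cell type, condition) groups; SEM is sample SD / sqrt(n) (0 for n = 1).
    """
    ids = list(gene_ids)
    if not ids:
        raise ExpressionError("empty gene set")
    missing = set(ids) - set(matrix.values.index)
    if missing:
        raise ExpressionError(f"genes absent from matrix: {sorted(missing)[:5]}")
    peaks = matrix.condition_means().loc[ids].max(axis=1).to_numpy(float)
    mean = float(np.mean(peaks))
    sem = float(np.std(peaks, ddof=1) / math.sqrt(len(peaks))) if len(peaks) > 1 else 0.0
    return mean, sem


def nearest_coding_gene(
    lnc: GeneModel, coding: Sequence[GeneModel], max_dist: int = 1_000_000
) -> tuple[str, int] | None:
    """Nearest coding gene by span gap on the same chromosome, or None beyond
    ``max_dist``.  Ties break toward the smaller start, then lexicographic id."""
    best: tuple[int, int, str] | None = None
    span = lnc.span
    for cg in coding:
        gap = span.gap_to(cg.span)
        if gap is None or gap > max_dist:
            continue
        key = (gap, cg.span.start, cg.gene_id)
        if best is None or key < best:
            best = key
    if best is None:
        return None
    return best[2], best[0]


def genes_within_window(
    lnc: GeneModel, coding: Sequence[GeneModel], max_dist: int = 1_000_000
) -> list[tuple[str, int]]:
    """All coding genes with span gap <= ``max_dist``, nearest first."""
    span = lnc.span
    hits = []
    for cg in coding:
        gap = span.gap_to(cg.span)
        if gap is not None and gap <= max_dist:
            hits.append((gap, cg.span.start, cg.gene_id))
    hits.sort()
    return [(gid, gap) for gap, _start, gid in hits]


def fold_change_correlation(
    pairs: Sequence[tuple[float, float]]
) -> CorrelationResult:
    """Pearson correlation between paired lncRNA and mRNA log2 fold changes.

    The p-value is the two-sided t-test with n - 2 degrees of freedom.
    """
    if len(pairs) < 3:
        raise ExpressionError("need at least 3 pairs for a correlation")
    x = np.asarray([p[0] for p in pairs], float)
    y = np.asarray([p[1] for p in pairs], float)
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ExpressionError("non-finite fold changes")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ExpressionError("zero variance: correlation undefined")
    res = stats.pearsonr(x, y)
    return CorrelationResult(float(res.statistic), float(res.pvalue), len(pairs))


# ---------------------------------------------------------------------------
# Tab-delimited intake
# ---------------------------------------------------------------------------

def read_expression_matrix(fpkm_path: str | Path, meta_path: str | Path) -> ExpressionMatrix:
    """Read a genes x samples FPKM table and its sample sidecar
    (columns: sample, cell_type, condition)."""
    values = pd.read_csv(fpkm_path, sep="\t", index_col=0)
    meta = pd.read_csv(meta_path, sep="\t", index_col=0)
    return ExpressionMatrix(values, meta)


def read_de_table(path: str | Path) -> list[DERecord]:
    """Read a differential-expression table
    (columns: gene_id, cell_type, log2fc, q_value)."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "cell_type", "log2fc", "q_value"}
    if not required.issubset(df.columns):
        raise ExpressionError(f"DE table missing columns {required - set(df.columns)}")
    return [
        DERecord(r.gene_id, r.cell_type, float(r.log2fc), float(r.q_value))
        for r in df.itertuples(index=False)
    ]
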