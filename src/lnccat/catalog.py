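"""lncRNA catalog identification rules and positional classification.

The catalog is built from assembled candidate gene models by (1) removing
genes whose exonic length is under 200 nt, (2) splitting single- from
multi-exonic genes, (3) flagging candidates that share same-strand exonic
sequence with a reference lncRNA annotation as *known* (the rest are
*novel*), (4) removing candidates an external coding-potential calculator
labelled coding, and (5) classifying each survivor by its position relative
to protein-coding genes:

* ``AS`` — overlaps a protein-coding gene on the opposite strand;
* ``AS_UPSTREAM`` / ``AS_DOWNSTREAM`` — within a window (default 5 kb) of a
  protein-coding gene on the opposite strand, on the 5' (TSS) or 3' side of
  that coding gene's own orientation;
* ``LINCRNA`` — more than the window away from every protein-coding gene;
* ``EXCLUDED_SAME_STRAND`` — overlaps or lies within the window of a
  same-strand coding gene; such candidates may be unannotated gene
  extensions and are removed before any antisense call is made.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

from .annotation import GeneModel

__all__ = [
    "PositionalClass",
    "CatalogRecord",
    "ClassificationError",
    "filter_min_length",
    "partition_by_exon_count",
    "flag_known_vs_novel",
    "apply_coding_filter",
    "classify_relative_position",
    "build_catalog",
]

logger = logging.getLogger(__name__)


class ClassificationError(ValueError):
    """Raised when a gene cannot be positionally classified."""


class PositionalClass(str, Enum):
    AS = "AS"
    AS_UPSTREAM = "AS_UPSTREAM"
    AS_DOWNSTREAM = "AS_DOWNSTREAM"
    LINCRNA = "LINCRNA"
    EXCLUDED_SAME_STRAND = "EXCLUDED_SAME_STRAND"


@dataclass
class CatalogRecord:
    gene: GeneModel
    positional_class: PositionalClass
    novelty: str  # "known" | "novel"
    nearest_coding_gene_id: str | None = None
    nearest_coding_distance: int | None = None


def filter_min_length(genes: Iterable[GeneModel], min_len: int = 200) -> list[GeneModel]:
    """Keep genes whose summed exon length is at least ``min_len`` (default 200 nt)."""
    return [g for g in genes if g.exonic_length >= min_len]


def partition_by_exon_count(
    genes: Iterable[GeneModel],
) -> tuple[list[GeneModel], list[GeneModel]]:
    """Split into (single-exon, multi-exon) sets on the merged model."""
    single = [g for g in genes if g.n_exons == 1]
    multi = [g for g in genes if g.n_exons >= 2]
    return single, multi


def _exonic_overlap_same_strand(a: GeneModel, b: GeneModel) -> bool:
    if a.chrom != b.chrom or a.strand != b.strand:
        return False
    for ea in a.exons:
        for eb in b.exons:
            if ea.start < eb.end and eb.start < ea.end:
                return True
    return False


def flag_known_vs_novel(
    candidates: Sequence[GeneModel], reference_lncRNAs: Sequence[GeneModel]
) -> dict[str, str]:
    """Label each candidate ``known`` or ``novel``.

    A candidate is *known* iff at least one base of exonic sequence overlaps
    a reference lncRNA exon on the same strand.
    """
    by_chrom: dict[str, list[GeneModel]] = {}
    for r in reference_lncRNAs:
        by_chrom.setdefault(r.chrom, []).append(r)
    labels = {}
    for c in candidates:
        refs = by_chrom.get(c.chrom, [])
        known = any(_exonic_overlap_same_strand(c, r) for r in refs)
        labels[c.gene_id] = "known" if known else "novel"
    return labels


def apply_coding_filter(
    genes: Sequence[GeneModel], coding_table: Mapping[str, str]
) -> list[GeneModel]:
    """Drop genes an external coding-potential call labelled ``coding``.

    Genes missing from the table are retained and logged: the calculator is
    run outside this package and its table may be partial.
    """
    kept = []
    for g in genes:
        label = coding_table.get(g.gene_id)
        if label is None:
            logger.warning(
                "gene %s absent from coding-potential table; retained", g.gene_id
            )
            kept.append(g)
        elif label != "coding":
            kept.append(g)
    return kept


def classify_relative_position(
    lnc: GeneModel,
    coding: Sequence[GeneModel],
    window: int = 5000,
) -> tuple[PositionalClass, str | None, int | None]:
    """Positionally classify one lncRNA against protein-coding gene spans.

    Distances are span gaps (0 when spans overlap).  Decision order:

    1. a same-strand coding gene overlaps or lies within ``window``
       -> ``EXCLUDED_SAME_STRAND``;
    2. an opposite-strand coding gene overlaps the lncRNA span -> ``AS``;
    3. an opposite-strand coding gene lies within ``window``:
       ``AS_UPSTREAM`` when the lncRNA sits on the 5' (TSS) side of that
       coding gene's orientation, ``AS_DOWNSTREAM`` on its 3' side
       (nearest gene wins; on a tie, the upstream call);
    4. otherwise ``LINCRNA``.

    Returns (class, nearest relevant coding gene id, its span gap);
    the id/gap pair is None for lincRNAs with no coding gene on the
    chromosome.
    """
    if lnc.strand not in ("+", "-"):
        raise ClassificationError(f"unstranded lncRNA {lnc.gene_id}")
    span = lnc.span
    same: list[tuple[int, GeneModel]] = []
    opposite: list[tuple[int, GeneModel]] = []
    for cg in coding:
        if cg.strand not in ("+", "-"):
            raise ClassificationError(f"unstranded coding gene {cg.gene_id}")
        gap = span.gap_to(cg.span)
        if gap is None:
            continue
        (same if cg.strand == lnc.strand else opposite).append((gap, cg))

    near_same = [(g, cg) for g, cg in same if g <= window]
    if near_same:
        gap, cg = min(near_same, key=lambda t: (t[0], t[1].span.start, t[1].gene_id))
        return PositionalClass.EXCLUDED_SAME_STRAND, cg.gene_id, gap

    overlapping = [(g, cg) for g, cg in opposite if g == 0 and span.overlaps(cg.span)]
    if overlapping:
        cg = min(overlapping, key=lambda t: (t[1].span.start, t[1].gene_id))[1]
        return PositionalClass.AS, cg.gene_id, 0

    near_opp = [(g, cg) for g, cg in opposite if g <= window]
    if near_opp:
        def side(cg: GeneModel) -> str:
            # upstream/downstream relative to the coding gene's orientation
            lnc_before = span.end <= cg.span.start
            if cg.strand == "+":
                return "up" if lnc_before else "down"
            return "down" if lnc_before else "up"

        gap, cg = min(
            near_opp,
            key=lambda t: (t[0], 0 if side(t[1]) == "up" else 1, t[1].gene_id),
        )
        label = (
            PositionalClass.AS_UPSTREAM if side(cg) == "up" else PositionalClass.AS_DOWNSTREAM
        )
        return label, cg.gene_id, gap

    if not same and not opposite:
        return PositionalClass.LINCRNA, None, None
    gap, cg = min(same + opposite, key=lambda t: (t[0], t[1].span.start, t[1].gene_id))
    return PositionalClass.LINCRNA, cg.gene_id, gap


def build_catalog(
    candidates: Sequence[GeneModel],
    coding: Sequence[GeneModel],
    reference_lncRNAs: Sequence[GeneModel] = (),
    coding_table: Mapping[str, str] | None = None,
    min_len: int = 200,
    window: int = 5000,
) -> list[CatalogRecord]:
    """Run the full identification chain and return one record per survivor.

    Applies the length filter, the coding-potential filter (when a table is
    supplied), novelty flagging and positional classification.  Records
    classified ``EXCLUDED_SAME_STRAND`` are kept in the output so callers can
    report how many candidates the exclusion rule removed.
    """
    genes = filter_min_length(candidates, min_len)
    if coding_table is not None:
        genes = apply_coding_filter(genes, coding_table)
    novelty = flag_known_vs_novel(genes, reference_lncRNAs)
    records = []
    for g in genes:
        label, near_id, near_gap = classify_relative_position(g, coding, window)
        records.append(CatalogRecord(g, label, novelty[g.gene_id], near_id, near_gap))
    return records
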