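"""Chain-file liftover, cross-species synteny and conservation aggregation.

A UCSC chain describes a block-structured pairwise alignment between a
*source* genome (the chain header's first coordinate triple) and a *target*
genome.  Intervals are lifted block by block; an interval maps when at
least ``min_match`` of its bases fall inside aligned blocks.  Synteny pairs
arise when a lifted gene span overlaps a gene of the target catalog by at
least one base (strand-agnostic — orientation is the chain's business).

Sequence-level conservation between a syntenic pair is the fraction of the
query gene covered by ungapped local-alignment hits; positional
conservation over a gene is the mean of a per-base 0-1 score track
(PhastCons-style) across its exonic bases.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .annotation import AnnotationError, GeneModel, GenomicInterval, merge_intervals
from .microdomains import KarlinAltschulParams, local_align_all_pairs

__all__ = [
    "Chain",
    "LiftResult",
    "SyntenyPair",
    "ChainError",
    "read_chain",
    "write_chain",
    "invert_chain",
    "liftover_interval",
    "map_catalog_synteny",
    "pairwise_conservation_pct",
    "read_bedgraph",
    "mean_conservation_score",
]


class ChainError(ValueError):
    pass


@dataclass
class Chain:
    """One UCSC chain: source/target headers plus (size, dt, dq) blocks.

    ``dt``/``dq`` are the unaligned gaps after each block on the source and
    target side; the last block has dt = dq = 0.  Coordinates of a '-'
    strand side are in reverse-strand space, per UCSC convention.
    """

    score: float
    source_chrom: str
    source_size: int
    source_strand: str
    source_start: int
    source_end: int
    target_chrom: str
    target_size: int
    target_strand: str
    target_start: int
    target_end: int
    blocks: list[tuple[int, int, int]]
    chain_id: str = "1"

    def validate(self) -> None:
        if self.source_strand != "+":
            raise ChainError("chain source strand must be '+' (UCSC convention)")
        if self.target_strand not in ("+", "-"):
            raise ChainError(f"invalid target strand {self.target_strand!r}")
        src = sum(size + dt for size, dt, _ in self.blocks)
        tgt = sum(size + dq for size, _, dq in self.blocks)
        if src != self.source_end - self.source_start:
            raise ChainError(
                f"chain {self.chain_id}: blocks cover {src} source bases but "
                f"header claims {self.source_end - self.source_start}"
            )
        if tgt != self.target_end - self.target_start:
            raise ChainError(
                f"chain {self.chain_id}: blocks cover {tgt} target bases but "
                f"header claims {self.target_end - self.target_start}"
            )
        if any(size <= 0 for size, _, _ in self.blocks):
            raise ChainError(f"chain {self.chain_id}: non-positive block size")
        if self.blocks[-1][1] != 0 or self.blocks[-1][2] != 0:
            raise ChainError(f"chain {self.chain_id}: last block must have no gaps")


def read_chain(path: str | Path) -> list[Chain]:
    """Parse a UCSC chain file; block sums are checked against the header."""
    chains: list[Chain] = []
    current: Chain | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("chain"):
                f = line.split()
                if len(f) != 13:
                    raise ChainError(
                        f"{path}: line {lineno}: chain header needs 13 fields, got {len(f)}"
                    )
                try:
                    current = Chain(
                        score=float(f[1]),
                        source_chrom=f[2], source_size=int(f[3]), source_strand=f[4],
                        source_start=int(f[5]), source_end=int(f[6]),
                        target_chrom=f[7], target_size=int(f[8]), target_strand=f[9],
                        target_start=int(f[10]), target_end=int(f[11]),
                        blocks=[], chain_id=f[12],
                    )
                except ValueError:
                    raise ChainError(f"{path}: line {lineno}: malformed header") from None
                chains.append(current)
            else:
                if current is None:
                    raise ChainError(f"{path}: line {lineno}: block before any header")
                f = line.split()
                try:
                    if len(f) == 3:
                        current.blocks.append((int(f[0]), int(f[1]), int(f[2])))
                    elif len(f) == 1:
                        current.blocks.append((int(f[0]), 0, 0))
                    else:
                        raise ValueError
                except ValueError:
                    raise ChainError(f"{path}: line {lineno}: malformed block") from None
    for c in chains:
        if not c.blocks:
            raise ChainError(f"chain {c.chain_id} has no blocks")
        c.validate()
    return chains


def write_chain(chains: Iterable[Chain], path: str | Path) -> None:
    with open(path, "w") as fh:
        for c in chains:
            fh.write(
                f"chain {c.score:g} {c.source_chrom} {c.source_size} {c.source_strand} "
                f"{c.source_start} {c.source_end} {c.target_chrom} {c.target_size} "
                f"{c.target_strand} {c.target_start} {c.target_end} {c.chain_id}\n"
            )
            for size, dt, dq in c.blocks[:-1]:
                fh.write(f"{size} {dt} {dq}\n")
            fh.write(f"{c.blocks[-1][0]}\n\n")


def invert_chain(chain: Chain) -> Chain:
    """Swap the source and target sides of a '+'/'+' chain."""
    if chain.target_strand != "+":
        raise ChainError("only '+'-strand targets can be inverted directly")
    return Chain(
        score=chain.score,
        source_chrom=chain.target_chrom, source_size=chain.target_size,
        source_strand="+", source_start=chain.target_start, source_end=chain.target_end,
        target_chrom=chain.source_chrom, target_size=chain.source_size,
        target_strand="+", target_start=chain.source_start, target_end=chain.source_end,
        blocks=[(size, dq, dt) for size, dt, dq in chain.blocks],
        chain_id=chain.chain_id,
    )


@dataclass
class LiftResult:
    """Lifted pieces on the target genome plus the mapped-base fraction."""

    mapped: list[GenomicInterval]
    mapped_fraction: float

    @property
    def span(self) -> GenomicInterval:
        iv = self.mapped[0]
        return GenomicInterval(
            iv.chrom,
            min(p.start for p in self.mapped),
            max(p.end for p in self.mapped),
            iv.strand,
        )


def _lift_through_chain(
    interval: GenomicInterval, chain: Chain
) -> list[GenomicInterval]:
    """Target-genome pieces of the interval's bases that fall in aligned blocks."""
    pieces: list[tuple[int, int]] = []
    spos, tpos = chain.source_start, chain.target_start
    for size, dt, dq in chain.blocks:
        s0 = max(interval.start, spos)
        s1 = min(interval.end, spos + size)
        if s0 < s1:
            off = s0 - spos
            pieces.append((tpos + off, tpos + off + (s1 - s0)))
        spos += size + dt
        tpos += size + dq
        if spos >= interval.end:
            break
    out = []
    for t0, t1 in pieces:
        if chain.target_strand == "-":
            t0, t1 = chain.target_size - t1, chain.target_size - t0
        out.append(GenomicInterval(chain.target_chrom, t0, t1, "+"))
    return sorted(out, key=lambda iv: iv.start)


def liftover_interval(
    interval: GenomicInterval, chains: Sequence[Chain], min_match: float = 0.95
) -> LiftResult | None:
    """Map an interval onto the target genome through the best chain.

    Among chains on the interval's chromosome the one mapping the most bases
    wins (ties: higher chain score).  Returns None (unmapped) when the
    mapped-base fraction falls below ``min_match``.
    """
    best: tuple[int, float, list[GenomicInterval]] | None = None
    for chain in chains:
        if chain.source_chrom != interval.chrom:
            continue
        pieces = _lift_through_chain(interval, chain)
        mapped_bases = sum(len(p) for p in pieces)
        if mapped_bases == 0:
            continue
        key = (mapped_bases, chain.score)
        if best is None or key > (best[0], best[1]):
            best = (mapped_bases, chain.score, pieces)
    if best is None:
        return None
    fraction = best[0] / len(interval)
    if fraction < min_match:
        return None
    return LiftResult(best[2], fraction)


@dataclass
class SyntenyPair:
    gene_a: str
    gene_b: str
    overlap_bp: int
    conservation_pct: float | None = None


def map_catalog_synteny(
    genes_a: Sequence[GeneModel],
    chains: Sequence[Chain],
    genes_b: Sequence[GeneModel],
    min_match: float = 0.95,
) -> list[SyntenyPair]:
    """Lift each gene of catalog A and pair it with every catalog-B gene its
    lifted span overlaps by at least one base (strand ignored)."""
    pairs: list[SyntenyPair] = []
    for ga in genes_a:
        lifted = liftover_interval(ga.span, chains, min_match)
        if lifted is None:
            continue
        for gb in genes_b:
            if gb.chrom != lifted.mapped[0].chrom:
                continue
            overlap = 0
            for piece in lifted.mapped:
                s = max(piece.start, gb.span.start)
                e = min(piece.end, gb.span.end)
                if s < e:
                    overlap += e - s
            if overlap > 0:
                pairs.append(SyntenyPair(ga.gene_id, gb.gene_id, overlap))
    return pairs


def pairwise_conservation_pct(
    seq_a: str,
    seq_b: str,
    params: KarlinAltschulParams,
    word_size: int = 11,
    evalue_max: float = 10.0,
) -> float:
    """Percent of the query (A) sequence covered by local-alignment hits
    against sequence B."""
    if not seq_a or not seq_b:
        raise ValueError("empty sequence")
    hits = local_align_all_pairs(
        {"a": seq_a, "b": seq_b}, params, word_size=word_size, evalue_max=evalue_max
    )
    ivs = [
        GenomicInterval("a", h.q_start, h.q_end)
        for h in hits
        if h.query_id == "a"
    ]
    covered = sum(len(iv) for iv in merge_intervals(ivs))
    return 100.0 * covered / len(seq_a)


# ---------------------------------------------------------------------------
# Per-base score tracks (bedGraph)
# ---------------------------------------------------------------------------

def read_bedgraph(path: str | Path) -> dict[str, list[tuple[int, int, float]]]:
    """Read a bedGraph into chrom -> sorted (start, end, value) runs."""
    track: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 4:
                raise AnnotationError(
                    f"{path}: line {lineno}: expected 4 bedGraph columns"
                )
            chrom, start, end, value = f[0], int(f[1]), int(f[2]), float(f[3])
            if start < 0 or start >= end:
                raise AnnotationError(f"{path}: line {lineno}: invalid interval")
            track.setdefault(chrom, []).append((start, end, value))
    for runs in track.values():
        runs.sort()
    return track


def mean_conservation_score(
    gene: GeneModel, score_track: Mapping[str, list[tuple[int, int, float]]]
) -> float:
    """Mean per-base conservation score over the gene's exonic positions.

    Bases absent from the track are excluded from numerator and denominator;
    a gene with no covered exonic base has no defined score.
    """
    runs = score_track.get(gene.chrom, [])
    total = 0.0
    covered = 0
    for exon in gene.exons:
        for start, end, value in runs:
            s = max(exon.start, start)
            e = min(exon.end, end)
            if s < e:
                total += value * (e - s)
                covered += e - s
    if covered == 0:
        raise ValueError(
            f"no exonic base of {gene.gene_id} is covered by the score track"
        )
    return total / covered
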