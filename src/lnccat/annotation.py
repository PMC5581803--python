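"""Core genomic domain types and composite gene-model construction.

All coordinates inside the package are 0-based half-open (BED convention).
GTF input/output converts from/to 1-based inclusive at the boundary; no
other code ever sees GTF coordinates.

A "gene model" here is a composite unit: the union of the exons of every
transcript assigned to a gene, with overlapping or book-ended exons merged
into maximal disjoint blocks.  The gene sequence is the concatenation of
merged exon sequences, reverse-complemented for minus-strand genes, so it
reads 5'->3' in transcript orientation.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "GenomicInterval",
    "Transcript",
    "GeneModel",
    "AnnotationError",
    "read_gtf",
    "write_gtf",
    "build_gene_models",
    "merge_intervals",
    "extract_gene_sequence",
    "reverse_complement",
    "write_outputs",
    "read_bed12",
    "read_fasta",
    "write_fasta",
]


class AnnotationError(ValueError):
    """Malformed annotation input or inconsistent gene structure."""


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID_BASES = frozenset("ACGTN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of an upper-case ACGTN nucleotide string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A stranded genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise AnnotationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "need 0 <= start < end"
            )
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def gap_to(self, other: "GenomicInterval") -> int | None:
        """Gap in bases between two intervals on one chromosome.

        0 when they overlap or are book-ended; None on different chromosomes.
        """
        if self.chrom != other.chrom:
            return None
        if self.start < other.end and other.start < self.end:
            return 0
        return max(self.start, other.start) - min(self.end, other.end)


@dataclass
class Transcript:
    """One transcript: an ordered, non-overlapping run of exons."""

    transcript_id: str
    gene_id: str
    exons: list[GenomicInterval]

    def __post_init__(self) -> None:
        if not self.exons:
            raise AnnotationError(f"transcript {self.transcript_id} has no exons")
        chroms = {e.chrom for e in self.exons}
        strands = {e.strand for e in self.exons}
        if len(chroms) > 1 or len(strands) > 1:
            raise AnnotationError(
                f"transcript {self.transcript_id} mixes chromosomes or strands"
            )
        self.exons = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise AnnotationError(
                    f"transcript {self.transcript_id} has overlapping exons"
                )


@dataclass
class GeneModel:
    """A composite gene: merged disjoint exon blocks from all its transcripts."""

    gene_id: str
    chrom: str
    strand: str
    exons: list[GenomicInterval]
    biotype: str = "lncRNA_candidate"

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.exons[0].start, self.exons[-1].end, self.strand
        )

    @property
    def exonic_length(self) -> int:
        return sum(len(e) for e in self.exons)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def tss(self) -> int:
        """Transcription start site: first transcribed base, strand-aware."""
        return self.exons[0].start if self.strand == "+" else self.exons[-1].end - 1


_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_gtf_attributes(text: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(text))


def read_gtf(path: str | Path, feature_filter: str | None = None) -> list[Transcript]:
    """Read exon rows from a GTF file into Transcripts.

    GTF 1-based inclusive coordinates are converted to 0-based half-open.
    ``feature_filter`` keeps only rows whose gene_biotype/gene_type attribute
    matches. Transcripts are returned grouped by transcript_id, in file order
    of first appearance.
    """
    exons: dict[str, tuple[str, list[GenomicInterval]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise AnnotationError(
                    f"{path}: line {lineno}: expected 9 tab-separated columns, "
                    f"got {len(fields)}"
                )
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attrs = (
                fields[:9]
            )
            if feature != "exon":
                continue
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError:
                raise AnnotationError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from None
            start, end = start1 - 1, end1  # 1-based inclusive -> 0-based half-open
            if start < 0 or start >= end:
                raise AnnotationError(
                    f"{path}: line {lineno}: invalid coordinates {start1}..{end1}"
                )
            attr = _parse_gtf_attributes(attrs)
            if "gene_id" not in attr or "transcript_id" not in attr:
                raise AnnotationError(
                    f"{path}: line {lineno}: missing gene_id/transcript_id attribute"
                )
            if feature_filter is not None:
                biotype = attr.get("gene_biotype", attr.get("gene_type", ""))
                if biotype != feature_filter:
                    continue
            tid = attr["transcript_id"]
            exons.setdefault(tid, (attr["gene_id"], []))[1].append(
                GenomicInterval(chrom, start, end, strand)
            )
    return [
        Transcript(tid, gid, ivs) for tid, (gid, ivs) in exons.items()
    ]


def write_gtf(genes: Iterable[GeneModel], path: str | Path, source: str = "lnccat") -> None:
    """Write gene models as single-transcript GTF exon rows (1-based inclusive)."""
    with open(path, "w") as fh:
        for g in genes:
            for iv in g.exons:
                attrs = f'gene_id "{g.gene_id}"; transcript_id "{g.gene_id}.t1";'
                fh.write(
                    f"{g.chrom}\t{source}\texon\t{iv.start + 1}\t{iv.end}\t.\t"
                    f"{g.strand}\t.\t{attrs}\n"
                )


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Union of intervals: overlapping or book-ended runs become one block."""
    ivs = sorted(intervals, key=lambda e: e.start)
    if not ivs:
        return []
    merged = [ivs[0]]
    for iv in ivs[1:]:
        last = merged[-1]
        if iv.start <= last.end:  # book-ended blocks merge too
            if iv.end > last.end:
                merged[-1] = GenomicInterval(last.chrom, last.start, iv.end, last.strand)
        else:
            merged.append(iv)
    return merged


def build_gene_models(
    transcripts: Iterable[Transcript], biotype: str = "lncRNA_candidate"
) -> list[GeneModel]:
    """Collapse transcripts into composite gene models, one per gene_id.

    All exons of all transcripts sharing a gene_id are unioned; overlapping
    or book-ended exons merge into maximal disjoint blocks.  Transcripts of
    one gene must agree on chromosome and strand.
    """
    by_gene: dict[str, list[Transcript]] = {}
    order: list[str] = []
    for t in transcripts:
        if t.gene_id not in by_gene:
            order.append(t.gene_id)
        by_gene.setdefault(t.gene_id, []).append(t)
    models = []
    for gid in order:
        txs = by_gene[gid]
        chroms = {t.exons[0].chrom for t in txs}
        strands = {t.exons[0].strand for t in txs}
        if len(chroms) > 1:
            raise AnnotationError(f"gene {gid}: transcripts on multiple chromosomes")
        if len(strands) > 1:
            raise AnnotationError(f"gene {gid}: transcripts on both strands")
        exons = merge_intervals(e for t in txs for e in t.exons)
        models.append(GeneModel(gid, chroms.pop(), strands.pop(), exons, biotype))
    return models


def extract_gene_sequence(gene: GeneModel, genome: Mapping[str, str]) -> str:
    """Concatenated exonic sequence of a gene, 5'->3' in gene orientation.

    Exon sequences are joined in genomic order; minus-strand genes are
    reverse-complemented after concatenation.  Lower-case genome bases are
    accepted and upper-cased; characters outside ACGTN are rejected.
    """
    if gene.chrom not in genome:
        raise AnnotationError(f"chromosome {gene.chrom!r} absent from genome")
    chrom_seq = genome[gene.chrom]
    if gene.exons[-1].end > len(chrom_seq):
        raise AnnotationError(
            f"gene {gene.gene_id}: exon ends at {gene.exons[-1].end} beyond "
            f"chromosome end {len(chrom_seq)}"
        )
    parts = []
    for iv in gene.exons:
        s = chrom_seq[iv.start : iv.end].upper()
        bad = set(s) - _VALID_BASES
        if bad:
            raise AnnotationError(
                f"gene {gene.gene_id}: invalid bases {sorted(bad)} in genome"
            )
        parts.append(s)
    seq = "".join(parts)
    return reverse_complement(seq) if gene.strand == "-" else seq


# ---------------------------------------------------------------------------
# BED12 / FASTA round-trip output
# ---------------------------------------------------------------------------

def write_outputs(
    genes: Sequence[GeneModel],
    sequences: Mapping[str, str],
    prefix: str | Path,
    fasta_width: int = 60,
) -> tuple[Path, Path]:
    """Write the catalog as ``<prefix>.bed`` (BED12) and ``<prefix>.fa``.

    Blocks of the BED12 record are the merged exons; FASTA headers are gene
    ids.  Reading the BED back with :func:`read_bed12` reproduces the models.
    """
    if not genes:
        raise AnnotationError("refusing to write an empty catalog")
    prefix = Path(prefix)
    bed_path = prefix.with_suffix(".bed")
    fa_path = prefix.with_suffix(".fa")
    with open(bed_path, "w") as fh:
        for g in genes:
            span = g.span
            sizes = ",".join(str(len(e)) for e in g.exons)
            starts = ",".join(str(e.start - span.start) for e in g.exons)
            fh.write(
                f"{g.chrom}\t{span.start}\t{span.end}\t{g.gene_id}\t0\t{g.strand}\t"
                f"{span.start}\t{span.end}\t0\t{g.n_exons}\t{sizes},\t{starts},\n"
            )
    write_fasta({g.gene_id: sequences[g.gene_id] for g in genes}, fa_path, fasta_width)
    return bed_path, fa_path


def read_bed12(path: str | Path, biotype: str = "lncRNA_candidate") -> list[GeneModel]:
    """Read BED12 records back into gene models (blocks become exons)."""
    models = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise AnnotationError(
                    f"{path}: line {lineno}: expected 12 BED columns, got {len(f)}"
                )
            chrom, start, _end, name, _score, strand = f[0], int(f[1]), int(f[2]), f[3], f[4], f[5]
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            if len(sizes) != int(f[9]) or len(sizes) != len(offsets):
                raise AnnotationError(f"{path}: line {lineno}: inconsistent block columns")
            exons = [
                GenomicInterval(chrom, start + off, start + off + sz, strand)
                for off, sz in zip(offsets, sizes)
            ]
            models.append(GeneModel(name, chrom, strand, exons, biotype))
    return models


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an id -> sequence mapping (ids cut at whitespace)."""
    from Bio import SeqIO

    with open(path) as fh:
        return {rec.id: str(rec.seq) for rec in SeqIO.parse(fh, "fasta")}


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
            if not seq:
                fh.write("\n")
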