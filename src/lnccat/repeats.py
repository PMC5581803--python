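"""Repeat annotation intake, exonic repeat-content profiling and hard masking.

Repeat features come from RepeatMasker ``.out`` tables or a 6-column BED
whose name column carries the class/family string.  Class strings collapse
onto the closed set {SINE, LINE, LTR, DNA, other} by the prefix before '/'
("SINE/Alu" -> SINE); anything unrecognized is "other".

Repeat content is measured against EXONIC bases only — the catalog
sequences are merged exons, so intronic repeats are invisible to every
downstream sequence analysis.  When annotations overlap, each base counts
once under a fixed precedence (SINE > LINE > LTR > DNA > other).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .annotation import AnnotationError, GeneModel, GenomicInterval

__all__ = [
    "RepeatFeature",
    "RepeatProfile",
    "REPEAT_CLASSES",
    "normalize_repeat_class",
    "load_repeats",
    "repeat_fraction",
    "mask_repeats",
]

REPEAT_CLASSES = ("SINE", "LINE", "LTR", "DNA", "other")
_PRECEDENCE = {c: i for i, c in enumerate(REPEAT_CLASSES)}


def normalize_repeat_class(raw: str) -> str:
    """Map a RepeatMasker class/family string onto the closed class set."""
    prefix = raw.split("/", 1)[0].strip()
    return prefix if prefix in REPEAT_CLASSES[:-1] else "other"


@dataclass(frozen=True)
class RepeatFeature:
    interval: GenomicInterval  # strand ignored throughout
    repeat_class: str

    def __post_init__(self) -> None:
        if self.repeat_class not in REPEAT_CLASSES:
            raise AnnotationError(f"unknown repeat class {self.repeat_class!r}")


@dataclass
class RepeatProfile:
    """Per-class fractions of a gene's exonic bases, plus the non-repeat rest."""

    fractions: dict[str, float]
    non_repeat: float

    def __post_init__(self) -> None:
        total = sum(self.fractions.values()) + self.non_repeat
        if abs(total - 1.0) > 1e-9:
            raise AnnotationError(f"repeat fractions sum to {total}, not 1")


def load_repeats(path: str | Path, format: str = "rm_out") -> list[RepeatFeature]:
    """Load repeat features from RepeatMasker ``.out`` or BED6.

    ``.out`` coordinates are 1-based inclusive and converted; BED is native.
    """
    if format not in ("rm_out", "bed"):
        raise ValueError(f"unrecognized repeat format {format!r}")
    feats: list[RepeatFeature] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if format == "rm_out":
                f = line.split()
                # two header lines: "SW perc ..." banner and column rule
                if f[0] in ("SW", "score") or not f[0].lstrip("-").isdigit():
                    if lineno <= 3:
                        continue
                    raise AnnotationError(f"{path}: line {lineno}: malformed record")
                if len(f) < 11:
                    raise AnnotationError(
                        f"{path}: line {lineno}: expected >=11 fields, got {len(f)}"
                    )
                chrom, begin, end, klass = f[4], f[5], f[6], f[10]
                try:
                    start = int(begin) - 1  # 1-based inclusive -> 0-based half-open
                    stop = int(end)
                except ValueError:
                    raise AnnotationError(
                        f"{path}: line {lineno}: non-integer coordinates"
                    ) from None
            else:
                if line.startswith(("#", "track", "browser")):
                    continue
                f = line.split("\t")
                if len(f) < 4:
                    raise AnnotationError(
                        f"{path}: line {lineno}: expected >=4 BED columns"
                    )
                chrom, start, stop, klass = f[0], int(f[1]), int(f[2]), f[3]
            if start < 0 or start >= stop:
                raise AnnotationError(f"{path}: line {lineno}: invalid coordinates")
            feats.append(
                RepeatFeature(
                    GenomicInterval(chrom, start, stop), normalize_repeat_class(klass)
                )
            )
    return feats


def _exonic_class_runs(
    gene: GeneModel, repeats: Iterable[RepeatFeature]
) -> list[tuple[GenomicInterval, str]]:
    """(exon-clipped interval, class) pieces, one class per base by precedence."""
    pieces: list[tuple[GenomicInterval, str]] = []
    feats = sorted(
        (r for r in repeats if r.interval.chrom == gene.chrom),
        key=lambda r: _PRECEDENCE[r.repeat_class],
    )
    for exon in gene.exons:
        # per-base class assignment over this exon, first-precedence wins
        claimed: list[tuple[int, int]] = []  # disjoint taken sub-intervals
        for r in feats:
            s = max(exon.start, r.interval.start)
            e = min(exon.end, r.interval.end)
            if s >= e:
                continue
            # subtract already-claimed bases
            segs = [(s, e)]
            for cs, ce in claimed:
                segs = [
                    piece
                    for a, b in segs
                    for piece in ((a, min(b, cs)), (max(a, ce), b))
                    if piece[0] < piece[1]
                ]
            for a, b in segs:
                pieces.append((GenomicInterval(gene.chrom, a, b), r.repeat_class))
                claimed.append((a, b))
    return pieces


def repeat_fraction(gene: GeneModel, repeats: Iterable[RepeatFeature]) -> RepeatProfile:
    """Fraction of the gene's exonic bases covered by each repeat class.

    Overlapping features resolve by precedence SINE > LINE > LTR > DNA >
    other, so every base counts exactly once; ``non_repeat`` is the
    complement.
    """
    length = gene.exonic_length
    covered = {c: 0 for c in REPEAT_CLASSES}
    for iv, klass in _exonic_class_runs(gene, repeats):
        covered[klass] += len(iv)
    fractions = {c: covered[c] / length for c in REPEAT_CLASSES}
    return RepeatProfile(fractions, 1.0 - sum(fractions.values()))


def _genomic_to_transcript(gene: GeneModel, pos: int) -> int:
    """Map a genomic base inside an exon to its transcript-coordinate offset."""
    off = 0
    for exon in gene.exons:
        if exon.start <= pos < exon.end:
            t = off + (pos - exon.start)
            if gene.strand == "-":
                t = gene.exonic_length - 1 - t
            return t
        off += len(exon)
    raise AnnotationError(f"position {pos} not exonic in {gene.gene_id}")


def mask_repeats(
    gene_sequence: str,
    gene: GeneModel,
    repeats: Iterable[RepeatFeature],
    hard: bool = True,
) -> str:
    """Mask repeat-covered transcript positions in the extracted gene sequence.

    Repeat intervals are projected from genomic to transcript coordinates
    (strand-aware).  Hard masking writes 'N'; soft masking lower-cases.
    Sequence length is preserved either way.
    """
    if len(gene_sequence) != gene.exonic_length:
        raise AnnotationError(
            f"sequence length {len(gene_sequence)} != exonic length "
            f"{gene.exonic_length} for {gene.gene_id}"
        )
    out = list(gene_sequence)
    for r in repeats:
        if r.interval.chrom != gene.chrom:
            continue
        for exon in gene.exons:
            s = max(exon.start, r.interval.start)
            e = min(exon.end, r.interval.end)
            for gpos in range(s, e):
                t = _genomic_to_transcript(gene, gpos)
                if not 0 <= t < len(out):
                    raise AnnotationError("repeat projection outside sequence")
                out[t] = "N" if hard else out[t].lower()
    return "".join(out)
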