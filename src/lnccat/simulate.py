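"""Seeded synthetic-data generator with planted ground truth.

Emits every input the pipeline consumes — a two-species toy genome pair,
coding and lncRNA annotation with genes planted in every positional class,
a replicated FPKM matrix with planted fold changes and a planted
lncRNA-mRNA fold-change correlation, its own differential-expression table
(two-sample t-test on log2 FPKM with Benjamini-Hochberg adjustment; the
production DE caller is out of scope, so the generator derives the table
from its own truth), repeat annotation, shared sequence motifs, TSS
coverage bumps with matching peaks, a conservation score track, and a
chain file built exactly from the edit list that produced genome B.

Geometry is slot-based: each chromosome is divided into fixed slots far
enough apart that genes in different slots can never interact under the
5-kb classification window, so every planted positional class is exact by
construction.  A single integer seed drives independent per-stage random
streams, so adding a stage never perturbs earlier outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import (
    GeneModel,
    GenomicInterval,
    Transcript,
    reverse_complement,
    write_fasta,
    write_gtf,
)
from .catalog import PositionalClass
from .repeats import RepeatFeature
from .synteny import Chain, write_chain

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "SimulatedBundle",
    "Edit",
    "simulate_dataset",
    "plant_shared_motif",
    "make_chain_pair",
    "correlated_fold_changes",
]

_SLOT = 25_000
_BASES = np.array(list("ACGT"))
DEFAULT_MOTIF = "ACGTGCATTAGGCCATGCAA"  # 20 nt, GC-balanced, rare in AT-rich noise


class ConfigurationError(ValueError):
    pass


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic bundle.

    Defaults keep the full pipeline in seconds: two chromosomes of 1 Mb per
    species, 60 coding genes, 10 lncRNAs per positional class, AT fraction
    0.58 (the catalog's AT richness), a planted fold change of 2 log2 units,
    a cis fold-change correlation of 0.7 and 3 replicates per condition.
    """

    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 1_000_000
    n_coding: int = 60
    n_lnc_per_class: int = 10
    at_fraction: float = 0.58
    de_log2fc: float = 2.0
    cis_rho: float = 0.7
    n_replicates: int = 3
    cell_types: tuple[str, ...] = ("monocyte", "macrophage", "epithelium", "chondrocyte")
    motif: str = DEFAULT_MOTIF
    n_motif_carriers: int = 12
    repeat_density: float = 0.25
    n_chain_edits: int = 8
    replicate_sigma_log2: float = 0.3
    n_syntenic: int = 10

    def __post_init__(self) -> None:
        if min(self.n_chroms, self.chrom_length, self.n_coding,
               self.n_lnc_per_class, self.n_replicates) <= 0:
            raise ConfigurationError("all counts must be positive")
        if not -1.0 <= self.cis_rho <= 1.0:
            raise ConfigurationError("cis_rho must lie in [-1, 1]")
        if not 0.0 <= self.at_fraction <= 1.0:
            raise ConfigurationError("at_fraction must lie in [0, 1]")
        paired = 4 * self.n_lnc_per_class
        if self.n_coding < paired:
            raise ConfigurationError(
                f"need at least {paired} coding genes to host "
                f"{self.n_lnc_per_class} lncRNAs in each proximal class"
            )
        slots = self.n_chroms * (self.chrom_length // _SLOT)
        needed = self.n_coding + self.n_lnc_per_class + 6  # + decoys/contaminants
        if slots < needed:
            raise ConfigurationError(
                f"{needed} gene slots needed but only {slots} fit: "
                "increase chrom_length or n_chroms, or reduce gene counts"
            )


@dataclass
class GroundTruth:
    """What the generator planted, keyed the way the pipeline reports."""

    classes: dict[str, PositionalClass]
    novelty: dict[str, str]
    short_genes: list[str]
    single_exon_genes: list[str]
    coding_contaminants: list[str]
    expressed: dict[str, set[str]]
    de_lnc: dict[str, set[str]]
    planted_log2fc: dict[tuple[str, str], float]
    nearest_pairs: dict[str, str]
    motif: str
    motif_positions: dict[str, int]
    repeat_features: list[RepeatFeature]
    syntenic: dict[str, str]
    active_genes: set[str]
    inactive_genes: set[str]


@dataclass
class SimulatedBundle:
    out_dir: Path
    genome_a: Path
    genome_b: Path
    lnc_gtf: Path
    coding_gtf: Path
    known_lnc_gtf: Path
    genes_b_gtf: Path
    fpkm: Path
    sample_meta: Path
    de_table: Path
    cpc_table: Path
    repeats_bed: Path
    peaks_bed: Path
    coverage_bedgraph: Path
    score_bedgraph: Path
    chain: Path
    truth: GroundTruth
    config: SyntheticConfig


# ---------------------------------------------------------------------------
# Primitive generators
# ---------------------------------------------------------------------------

def _random_sequence(rng: np.random.Generator, length: int, at_fraction: float) -> np.ndarray:
    probs = [at_fraction / 2, (1 - at_fraction) / 2, (1 - at_fraction) / 2, at_fraction / 2]
    return rng.choice(4, size=length, p=probs)


def correlated_fold_changes(
    n: int, rho: float, seed: int, base_log2fc: float = 2.0
) -> list[tuple[float, float]]:
    """(lncRNA, mRNA) log2 fold-change pairs with planted Pearson correlation.

    lncRNA fold changes are bimodal with magnitude at least ``base_log2fc``
    (sign random); the paired mRNA value is rho times the lncRNA value plus
    Gaussian noise scaled so the population correlation equals rho.
    """
    rng = np.random.default_rng(seed)
    sign = rng.choice([-1.0, 1.0], size=n)
    x = sign * (base_log2fc + 0.5 * np.abs(rng.standard_normal(n)))
    sd_x = float(np.std(x))
    y = rho * x + math.sqrt(max(0.0, 1.0 - rho**2)) * sd_x * rng.standard_normal(n)
    return list(zip(x.tolist(), y.tolist()))


def plant_shared_motif(
    sequences: Mapping[str, str],
    motif: str,
    carriers: Sequence[str],
    seed: int,
    reverse_complement_plant: bool = False,
) -> tuple[dict[str, str], dict[str, int]]:
    """Overwrite a seeded random position of each carrier with the motif.

    Returns (modified sequences, carrier -> plant position).  With
    ``reverse_complement_plant`` the motif is written reverse-complemented,
    so an aligner should report it on the '-' subject strand.
    """
    rng = np.random.default_rng(seed)
    planted = motif if not reverse_complement_plant else reverse_complement(motif)
    out = dict(sequences)
    positions: dict[str, int] = {}
    for cid in carriers:
        seq = out[cid]
        if len(motif) > len(seq):
            raise ValueError(f"motif longer than carrier {cid!r}")
        pos = int(rng.integers(0, len(seq) - len(planted) + 1))
        out[cid] = seq[:pos] + planted + seq[pos + len(planted):]
        positions[cid] = pos
    return out, positions


# ---------------------------------------------------------------------------
# Chain construction from an explicit edit list
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Edit:
    """One rearrangement applied to genome A: kind in
    {deletion, insertion, inversion}, at source position ``pos``, ``size`` bases."""

    kind: str
    pos: int
    size: int

    def __post_init__(self) -> None:
        if self.kind not in ("deletion", "insertion", "inversion"):
            raise ConfigurationError(f"unknown edit kind {self.kind!r}")
        if self.size <= 0 or self.pos < 0:
            raise ConfigurationError("edit needs positive size and position")


def make_chain_pair(
    genome_a: Mapping[str, str],
    edits: Mapping[str, Sequence[Edit]],
    seed: int,
    at_fraction: float = 0.5,
) -> tuple[dict[str, str], list[Chain], dict[str, "_CoordMap"]]:
    """Apply edits to genome A; return genome B, the exact chain, and per-
    chromosome coordinate maps from A to B.

    Deletions drop A bases (a source-side gap), insertions add random B
    bases (a target-side gap), inversions reverse-complement a segment and
    emit a separate '-' strand chain covering it.  Edits must not overlap.
    """
    rng = np.random.default_rng(seed)
    genome_b: dict[str, str] = {}
    chains: list[Chain] = []
    maps: dict[str, _CoordMap] = {}
    chain_no = 0
    for chrom, a_seq in genome_a.items():
        chrom_edits = sorted(edits.get(chrom, ()), key=lambda e: e.pos)
        for e1, e2 in zip(chrom_edits, chrom_edits[1:]):
            end1 = e1.pos + (0 if e1.kind == "insertion" else e1.size)
            if e2.pos < end1:
                raise ConfigurationError(f"overlapping edits on {chrom}")
        if chrom_edits and chrom_edits[-1].pos + (
            0 if chrom_edits[-1].kind == "insertion" else chrom_edits[-1].size
        ) > len(a_seq):
            raise ConfigurationError(f"edit beyond end of {chrom}")

        b_parts: list[str] = []
        blocks: list[tuple[int, int, int]] = []
        inversions: list[tuple[int, int, int]] = []  # (a_pos, b_pos, size)
        a_pos = 0
        b_pos = 0
        for e in chrom_edits:
            keep = e.pos - a_pos
            if e.kind == "deletion":
                blocks.append((keep, e.size, 0))
                b_parts.append(a_seq[a_pos:e.pos])
                a_pos = e.pos + e.size
                b_pos += keep
            elif e.kind == "insertion":
                ins = "".join(_BASES[_random_sequence(rng, e.size, at_fraction)])
                blocks.append((keep, 0, e.size))
                b_parts.append(a_seq[a_pos:e.pos] + ins)
                a_pos = e.pos
                b_pos += keep + e.size
            else:  # inversion: unaligned in the '+' chain, own '-' chain below
                blocks.append((keep, e.size, e.size))
                seg = a_seq[e.pos : e.pos + e.size]
                b_parts.append(a_seq[a_pos:e.pos] + reverse_complement(seg))
                inversions.append((e.pos, b_pos + keep, e.size))
                a_pos = e.pos + e.size
                b_pos += keep + e.size
        tail = len(a_seq) - a_pos
        b_parts.append(a_seq[a_pos:])
        b_seq = "".join(b_parts)
        genome_b[chrom] = b_seq

        # fold zero-size blocks (edits at a shared boundary) into gaps;
        # gaps before the first aligned block shift the chain start instead
        clean: list[tuple[int, int, int]] = []
        lead_dt = lead_dq = 0
        pending_dt = pending_dq = 0
        for size, dt, dq in blocks + [(tail, 0, 0)]:
            if size == 0:
                pending_dt += dt
                pending_dq += dq
                continue
            if pending_dt or pending_dq:
                if clean:
                    s, pdt, pdq = clean[-1]
                    clean[-1] = (s, pdt + pending_dt, pdq + pending_dq)
                else:
                    lead_dt += pending_dt
                    lead_dq += pending_dq
                pending_dt = pending_dq = 0
            clean.append((size, dt, dq))
        if not clean:
            raise ConfigurationError(f"no aligned bases left on {chrom}")
        s, dt, dq = clean[-1]
        clean[-1] = (s, 0, 0)
        src_span = sum(sz + d for sz, d, _ in clean)
        tgt_span = sum(sz + d for sz, _, d in clean)
        chain_no += 1
        chains.append(
            Chain(
                score=1000.0,
                source_chrom=chrom, source_size=len(a_seq), source_strand="+",
                source_start=lead_dt, source_end=lead_dt + src_span,
                target_chrom=chrom, target_size=len(b_seq), target_strand="+",
                target_start=lead_dq, target_end=lead_dq + tgt_span,
                blocks=clean, chain_id=str(chain_no),
            )
        )
        for a0, b0, size in inversions:
            chain_no += 1
            chains.append(
                Chain(
                    score=500.0,
                    source_chrom=chrom, source_size=len(a_seq), source_strand="+",
                    source_start=a0, source_end=a0 + size,
                    target_chrom=chrom, target_size=len(b_seq), target_strand="-",
                    target_start=len(b_seq) - (b0 + size),
                    target_end=len(b_seq) - b0,
                    blocks=[(size, 0, 0)], chain_id=str(chain_no),
                )
            )
        maps[chrom] = _CoordMap(chrom_edits)
    for c in chains:
        c.validate()
    return genome_b, chains, maps


class _CoordMap:
    """A -> B coordinate shift for positions outside every edit."""

    def __init__(self, edits: Sequence[Edit]):
        self._edits = sorted(edits, key=lambda e: e.pos)

    def lift(self, pos: int) -> int:
        shift = 0
        for e in self._edits:
            if e.pos > pos:
                break
            if e.kind == "deletion":
                if pos < e.pos + e.size:
                    raise ConfigurationError(f"position {pos} deleted")
                shift -= e.size
            elif e.kind == "insertion":
                shift += e.size
            else:
                if pos < e.pos + e.size:
                    raise ConfigurationError(f"position {pos} inverted")
        return pos + shift


# ---------------------------------------------------------------------------
# Gene layout
# ---------------------------------------------------------------------------

@dataclass
class _PlannedGene:
    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    role: str  # coding | lnc | short | single_exon | contaminant
    planted_class: PositionalClass | None = None
    partner: str | None = None  # slot coding gene for proximal lnc classes

    def model(self, biotype: str) -> GeneModel:
        return GeneModel(
            self.gene_id, self.chrom, self.strand,
            [GenomicInterval(self.chrom, s, e, self.strand) for s, e in self.exons],
            biotype,
        )


def _split_exons(start: int, end: int, n_exons: int, rng: np.random.Generator) -> list[tuple[int, int]]:
    """Cut [start, end) into n_exons exons separated by introns (>=60 bp)."""
    length = end - start
    if n_exons == 1:
        return [(start, end)]
    intron = max(60, length // (4 * n_exons))
    exon = (length - intron * (n_exons - 1)) // n_exons
    out = []
    pos = start
    for i in range(n_exons):
        e = end if i == n_exons - 1 else pos + exon
        out.append((pos, e))
        pos = e + intron
    return out


def _plan_genes(cfg: SyntheticConfig, rng: np.random.Generator) -> list[_PlannedGene]:
    chroms = [f"chr{i + 1}" for i in range(cfg.n_chroms)]
    slots = [
        (c, s)
        for c in chroms
        for s in range(0, cfg.chrom_length - _SLOT + 1, _SLOT)
    ]
    rng.shuffle(slots)
    proximal = ["AS", "ASU", "ASD", "EXC"]
    plans: list[_PlannedGene] = []
    slot_iter = iter(slots)

    def take() -> tuple[str, int]:
        try:
            return next(slot_iter)
        except StopIteration:  # pragma: no cover - guarded by config validation
            raise ConfigurationError("ran out of gene slots")

    def opposite(strand: str) -> str:
        return "-" if strand == "+" else "+"

    n_paired = 4 * cfg.n_lnc_per_class
    coding_plans: list[_PlannedGene] = []
    for i in range(cfg.n_coding):
        chrom, S = take()
        strand = "+" if rng.random() < 0.5 else "-"
        c_start = S + 12_000
        c_len = int(rng.integers(3000, 5001))
        gid = f"COD{i + 1:04d}"
        coding_plans.append(
            _PlannedGene(
                gid, chrom, strand,
                _split_exons(c_start, c_start + c_len, 3, rng), "coding",
            )
        )
        if i >= n_paired:
            continue
        klass = proximal[i % 4]
        j = i // 4 + 1
        c_end = c_start + c_len
        lnc_len = int(rng.integers(1200, 2001))
        if klass == "AS":
            l_start = c_start + 500
            l_end = min(l_start + lnc_len, c_end + 800)
            lid, lstrand, pclass = f"LNC_AS{j:03d}", opposite(strand), PositionalClass.AS
        else:
            gap = int(rng.integers(500, 4001 if klass != "EXC" else 3001))
            tss_side_left = strand == "+"  # coding TSS side is its 5' side
            if klass == "ASD":
                on_left = not tss_side_left
            elif klass == "ASU":
                on_left = tss_side_left
            else:  # EXC: same strand, either side works; use left
                on_left = True
            if on_left:
                l_end = c_start - gap
                l_start = l_end - lnc_len
            else:
                l_start = c_end + gap
                l_end = l_start + lnc_len
            lstrand = strand if klass == "EXC" else opposite(strand)
            pclass = {
                "ASU": PositionalClass.AS_UPSTREAM,
                "ASD": PositionalClass.AS_DOWNSTREAM,
                "EXC": PositionalClass.EXCLUDED_SAME_STRAND,
            }[klass]
            lid = f"LNC_{klass}{j:03d}"
        plans.append(
            _PlannedGene(
                lid, chrom, lstrand, _split_exons(l_start, l_end, 2, rng),
                "lnc", pclass, partner=gid,
            )
        )
    plans = coding_plans + plans

    for j in range(cfg.n_lnc_per_class):
        chrom, S = take()
        strand = "+" if rng.random() < 0.5 else "-"
        l_start = S + 12_000
        l_len = int(rng.integers(1500, 2501))
        plans.append(
            _PlannedGene(
                f"LNC_LIN{j + 1:03d}", chrom, strand,
                _split_exons(l_start, l_start + l_len, 2, rng),
                "lnc", PositionalClass.LINCRNA,
            )
        )

    # decoys exercising the identification filters
    for j in range(2):
        chrom, S = take()
        start = S + 12_000
        plans.append(
            _PlannedGene(
                f"LNC_SHORT{j + 1:02d}", chrom, "+",
                [(start, start + 80), (start + 200, start + 270)], "short",
            )
        )
    for j in range(2):
        chrom, S = take()
        start = S + 12_000
        plans.append(
            _PlannedGene(
                f"LNC_SE{j + 1:02d}", chrom, "-",
                [(start, start + 900)], "single_exon",
                PositionalClass.LINCRNA,
            )
        )
    for j in range(2):
        chrom, S = take()
        start = S + 12_000
        plans.append(
            _PlannedGene(
                f"LNC_CPC{j + 1:02d}", chrom, "+",
                _split_exons(start, start + 1500, 2, rng), "contaminant",
                PositionalClass.LINCRNA,
            )
        )
    return plans


# ---------------------------------------------------------------------------
# Track painting (disjoint bedGraph runs from possibly-overlapping features)
# ---------------------------------------------------------------------------

def _paint_runs(
    length: int, features: Iterable[tuple[int, int, float]]
) -> list[tuple[int, int, float]]:
    """Paint (start, end, value) features onto a zero array (max wins on
    overlap) and return the disjoint non-zero runs."""
    arr = np.zeros(length)
    for s, e, v in features:
        s, e = max(0, s), min(length, e)
        if s < e:
            arr[s:e] = np.maximum(arr[s:e], v)
    runs: list[tuple[int, int, float]] = []
    changes = np.flatnonzero(np.diff(arr) != 0) + 1
    bounds = np.concatenate(([0], changes, [length]))
    for s, e in zip(bounds[:-1], bounds[1:]):
        v = arr[s]
        if v > 0:
            runs.append((int(s), int(e), float(v)))
    return runs


def _write_bedgraph(
    runs_by_chrom: Mapping[str, list[tuple[int, int, float]]], path: Path
) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(runs_by_chrom):
            for s, e, v in runs_by_chrom[chrom]:
                fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")


# ---------------------------------------------------------------------------
# The bundle
# ---------------------------------------------------------------------------

def simulate_dataset(config: SyntheticConfig, out_dir: str | Path) -> SimulatedBundle:
    """Generate the full synthetic input bundle plus its ground truth.

    Deterministic given ``config.seed``; every stage draws from its own
    spawned random stream.
    """
    cfg = config
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    streams = np.random.SeedSequence(cfg.seed).spawn(8)
    rng_genome, rng_layout, rng_expr, rng_rep, rng_motif, rng_chain, rng_epi, rng_tx = (
        np.random.default_rng(s) for s in streams
    )

    chroms = [f"chr{i + 1}" for i in range(cfg.n_chroms)]
    genome_arr = {
        c: _random_sequence(rng_genome, cfg.chrom_length, cfg.at_fraction)
        for c in chroms
    }

    plans = _plan_genes(cfg, rng_layout)
    by_id = {p.gene_id: p for p in plans}
    coding = [p for p in plans if p.role == "coding"]
    lnc_like = [p for p in plans if p.role != "coding"]
    classed_lnc = [p for p in lnc_like if p.role in ("lnc", "single_exon")]

    # --- motif planting (into the genome, transcript orientation) ----------
    carriers = [
        p.gene_id
        for p in classed_lnc
        if p.planted_class is not PositionalClass.EXCLUDED_SAME_STRAND
        and p.role == "lnc"
    ][: cfg.n_motif_carriers]
    motif_sites: dict[str, tuple[str, int]] = {}  # gene -> (chrom, genomic pos)
    for gid in carriers:
        p = by_id[gid]
        s, e = p.exons[0]
        lo, hi = s + 50, e - 50 - len(cfg.motif)
        gpos = int(rng_motif.integers(lo, hi + 1))
        written = cfg.motif if p.strand == "+" else reverse_complement(cfg.motif)
        idx = np.array([_BASES.tolist().index(b) for b in written])
        genome_arr[p.chrom][gpos : gpos + len(idx)] = idx
        motif_sites[gid] = (p.chrom, gpos)

    genome_a = {c: "".join(_BASES[genome_arr[c]]) for c in chroms}

    # --- repeats ------------------------------------------------------------
    repeat_feats: list[RepeatFeature] = []
    class_choices = ["SINE", "LINE", "LTR", "DNA"]
    class_probs = [0.35, 0.30, 0.20, 0.15]
    names = {"SINE": "SINE/Alu", "LINE": "LINE/L1", "LTR": "LTR/ERVL", "DNA": "DNA/hAT"}
    for p in classed_lnc:
        for s, e in p.exons:
            if rng_rep.random() >= cfg.repeat_density:
                continue
            site = motif_sites.get(p.gene_id)
            rep_len = int(rng_rep.integers(80, min(301, e - s)))
            r_start = int(rng_rep.integers(s, e - rep_len + 1))
            if site and site[1] - rep_len < r_start < site[1] + len(cfg.motif):
                continue  # never mask the planted motif
            klass = class_choices[rng_rep.choice(4, p=class_probs)]
            repeat_feats.append(
                RepeatFeature(GenomicInterval(p.chrom, r_start, r_start + rep_len), klass)
            )

    # --- expression + DE ----------------------------------------------------
    all_gene_ids = [p.gene_id for p in plans]
    mult_probs = [0.60, 0.25, 0.10, 0.05][: len(cfg.cell_types)]
    mult_probs = [x / sum(mult_probs) for x in mult_probs]
    expressed: dict[str, set[str]] = {ct: set() for ct in cfg.cell_types}
    base_fpkm: dict[tuple[str, str], float] = {}
    for p in plans:
        k = 1 + rng_expr.choice(len(mult_probs), p=mult_probs)
        on_types = list(rng_expr.choice(len(cfg.cell_types), size=k, replace=False))
        hi = p.role == "coding"
        for i, ct in enumerate(cfg.cell_types):
            if i in on_types:
                mu = 3.2 if hi else 1.6
                base_fpkm[(p.gene_id, ct)] = float(np.exp(mu + 0.6 * rng_expr.standard_normal()))
                expressed[ct].add(p.gene_id)
            else:
                base_fpkm[(p.gene_id, ct)] = float(0.15 * np.exp(0.3 * rng_expr.standard_normal()))

    nearest_pairs: dict[str, str] = {}
    for p in classed_lnc:
        if p.partner is not None:
            nearest_pairs[p.gene_id] = p.partner
        else:  # lincRNA/single-exon: nearest coding gene by span gap
            span_s, span_e = p.exons[0][0], p.exons[-1][1]
            best = None
            for cg in coding:
                if cg.chrom != p.chrom:
                    continue
                cs, ce = cg.exons[0][0], cg.exons[-1][1]
                gap = 0 if span_s < ce and cs < span_e else max(span_s, cs) - min(span_e, ce)
                if best is None or gap < best[0]:
                    best = (gap, cg.gene_id)
            if best is not None:
                nearest_pairs[p.gene_id] = best[1]

    planted_fc: dict[tuple[str, str], float] = {}
    de_lnc: dict[str, set[str]] = {ct: set() for ct in cfg.cell_types}
    sq = math.sqrt(max(0.0, 1.0 - cfg.cis_rho**2))
    for ct in cfg.cell_types:
        eligible = [
            p.gene_id for p in classed_lnc
            if p.gene_id in expressed[ct] and p.gene_id in nearest_pairs
        ]
        chosen = [g for g in eligible if rng_expr.random() < 0.5]
        fcs = {}
        for g in chosen:
            sign = -1.0 if rng_expr.random() < 0.5 else 1.0
            fcs[g] = sign * (cfg.de_log2fc + 0.5 * abs(rng_expr.standard_normal()))
        sd_l = float(np.std(list(fcs.values()))) if len(fcs) > 1 else cfg.de_log2fc
        for g, fc_l in fcs.items():
            planted_fc[(g, ct)] = fc_l
            de_lnc[ct].add(g)
            partner = nearest_pairs[g]
            if (partner, ct) not in planted_fc:
                planted_fc[(partner, ct)] = (
                    cfg.cis_rho * fc_l + sq * sd_l * rng_expr.standard_normal()
                )

    samples = []
    for ct in cfg.cell_types:
        for cond in ("control", "stimulated"):
            for r in range(1, cfg.n_replicates + 1):
                samples.append((f"{ct}_{cond}_{r}", ct, cond))
    fpkm = np.zeros((len(all_gene_ids), len(samples)))
    for gi, gid in enumerate(all_gene_ids):
        for si, (_name, ct, cond) in enumerate(samples):
            level = base_fpkm[(gid, ct)]
            fc = planted_fc.get((gid, ct), 0.0)
            if cond == "stimulated":
                level *= 2.0 ** fc
            fpkm[gi, si] = level * 2.0 ** (
                cfg.replicate_sigma_log2 * rng_expr.standard_normal()
            )
    fpkm_df = pd.DataFrame(
        fpkm, index=pd.Index(all_gene_ids, name="gene_id"),
        columns=[s[0] for s in samples],
    )
    meta_df = pd.DataFrame(
        {"cell_type": [s[1] for s in samples], "condition": [s[2] for s in samples]},
        index=pd.Index([s[0] for s in samples], name="sample"),
    )

    # DE table from the generator's own test: t-test on log2 FPKM, BH per cell type
    de_rows = []
    logf = np.log2(fpkm + 0.05)
    for ct in cfg.cell_types:
        ctrl_idx = [i for i, s in enumerate(samples) if s[1] == ct and s[2] == "control"]
        stim_idx = [i for i, s in enumerate(samples) if s[1] == ct and s[2] == "stimulated"]
        tres = stats.ttest_ind(logf[:, stim_idx], logf[:, ctrl_idx], axis=1)
        pvals = np.where(np.isnan(tres.pvalue), 1.0, tres.pvalue)
        qvals = stats.false_discovery_control(pvals, method="bh")
        est_fc = logf[:, stim_idx].mean(axis=1) - logf[:, ctrl_idx].mean(axis=1)
        for gid, fc, q in zip(all_gene_ids, est_fc, qvals):
            de_rows.append((gid, ct, float(fc), float(q)))
    de_df = pd.DataFrame(de_rows, columns=["gene_id", "cell_type", "log2fc", "q_value"])

    # --- species B: edits, chain, syntenic partners -------------------------
    margin_starts = {
        c: [
            S + _SLOT - 1500
            for S in range(0, cfg.chrom_length - _SLOT + 1, _SLOT)
        ]
        for c in chroms
    }
    edits: dict[str, list[Edit]] = {c: [] for c in chroms}
    kinds = ["deletion", "insertion"]
    for i in range(cfg.n_chain_edits):
        c = chroms[i % len(chroms)]
        pool = margin_starts[c]
        pos = pool[int(rng_chain.integers(0, len(pool)))]
        if any(abs(pos - e.pos) < 2000 for e in edits[c]):
            continue
        edits[c].append(Edit(kinds[i % 2], pos, int(rng_chain.integers(200, 1201))))
    genome_b, chains, coord_maps = make_chain_pair(
        genome_a, edits, seed=int(rng_chain.integers(0, 2**31 - 1)),
        at_fraction=cfg.at_fraction,
    )

    syn_candidates = [
        p for p in classed_lnc
        if p.role == "lnc" and p.planted_class is not PositionalClass.EXCLUDED_SAME_STRAND
    ]
    syntenic: dict[str, str] = {}
    genes_b: list[GeneModel] = []
    for p in syn_candidates[: cfg.n_syntenic]:
        m = coord_maps[p.chrom]
        b_id = "m" + p.gene_id
        b_exons = [
            GenomicInterval(p.chrom, m.lift(s), m.lift(s) + (e - s), p.strand)
            for s, e in p.exons
        ]
        genes_b.append(GeneModel(b_id, p.chrom, p.strand, b_exons, "lncRNA_candidate"))
        syntenic[p.gene_id] = b_id

    # --- epigenome: TSS bumps + peaks for active genes ----------------------
    de_ct0 = de_lnc[cfg.cell_types[0]]
    active = set(de_ct0) | {nearest_pairs[g] for g in de_ct0 if g in nearest_pairs}
    classifiable = {p.gene_id for p in classed_lnc} | {p.gene_id for p in coding}
    inactive = classifiable - active
    cov_feats: dict[str, list[tuple[int, int, float]]] = {c: [] for c in chroms}
    peaks: list[tuple[str, int, int]] = []
    for gid in sorted(active):
        p = by_id[gid]
        tss = p.exons[0][0] if p.strand == "+" else p.exons[-1][1] - 1
        height = float(6.0 + 4.0 * rng_epi.random())
        for step in range(9):  # stepped triangular bump over TSS +- 900
            frac = 1.0 - step / 9.0
            half = 100 + step * 100
            cov_feats[p.chrom].append((tss - half, tss + half, height * frac))
        peaks.append((p.chrom, max(0, tss - 400), tss + 400))
    coverage_runs = {
        c: _paint_runs(cfg.chrom_length, cov_feats[c]) for c in chroms
    }

    # --- conservation score track -------------------------------------------
    score_feats: dict[str, list[tuple[int, int, float]]] = {c: [] for c in chroms}
    for p in plans:
        v = 0.8 if p.gene_id in syntenic else 0.25
        for s, e in p.exons:
            score_feats[p.chrom].append((s, e, v))
    score_runs = {c: _paint_runs(cfg.chrom_length, score_feats[c]) for c in chroms}

    # --- write the bundle ----------------------------------------------------
    paths = {
        "genome_a": out / "genome_a.fa",
        "genome_b": out / "genome_b.fa",
        "lnc_gtf": out / "lnc_candidates.gtf",
        "coding_gtf": out / "coding.gtf",
        "known_lnc_gtf": out / "known_lnc.gtf",
        "genes_b_gtf": out / "lnc_species_b.gtf",
        "fpkm": out / "fpkm.tsv",
        "sample_meta": out / "samples.tsv",
        "de_table": out / "de.tsv",
        "cpc_table": out / "coding_potential.tsv",
        "repeats_bed": out / "repeats.bed",
        "peaks_bed": out / "peaks.bed",
        "coverage_bedgraph": out / "coverage.bedgraph",
        "score_bedgraph": out / "conservation.bedgraph",
        "chain": out / "a_to_b.chain",
    }
    write_fasta(genome_a, paths["genome_a"])
    write_fasta(genome_b, paths["genome_b"])

    def as_models(plist: Sequence[_PlannedGene], biotype: str) -> list[GeneModel]:
        return [p.model(biotype) for p in plist]

    # candidates GTF: some genes get a second transcript (an exon subset) to
    # exercise transcript merging; the merged model is unchanged by design
    with open(paths["lnc_gtf"], "w") as fh:
        for p in lnc_like:
            for s, e in p.exons:
                fh.write(
                    f"{p.chrom}\tlnccat_sim\texon\t{s + 1}\t{e}\t.\t{p.strand}\t.\t"
                    f'gene_id "{p.gene_id}"; transcript_id "{p.gene_id}.t1";\n'
                )
            if len(p.exons) > 1 and rng_tx.random() < 0.3:
                s, e = p.exons[0]
                fh.write(
                    f"{p.chrom}\tlnccat_sim\texon\t{s + 1}\t{e}\t.\t{p.strand}\t.\t"
                    f'gene_id "{p.gene_id}"; transcript_id "{p.gene_id}.t2";\n'
                )
    write_gtf(as_models(coding, "coding"), paths["coding_gtf"], source="lnccat_sim")

    known_ids = {
        p.gene_id for i, p in enumerate(classed_lnc) if p.role == "lnc" and i % 2 == 0
    }
    known_models = [
        GeneModel(
            "REF_" + p.gene_id, p.chrom, p.strand,
            [GenomicInterval(p.chrom, s, e, p.strand) for s, e in p.exons],
            "lncRNA",
        )
        for p in classed_lnc
        if p.gene_id in known_ids
    ]
    write_gtf(known_models, paths["known_lnc_gtf"], source="lnccat_sim")
    write_gtf(genes_b, paths["genes_b_gtf"], source="lnccat_sim")

    fpkm_df.round(4).to_csv(paths["fpkm"], sep="\t")
    meta_df.to_csv(paths["sample_meta"], sep="\t")
    de_df.to_csv(paths["de_table"], sep="\t", index=False, float_format="%.6g")
    with open(paths["cpc_table"], "w") as fh:
        fh.write("gene_id\tlabel\n")
        for p in lnc_like:
            label = "coding" if p.role == "contaminant" else "noncoding"
            fh.write(f"{p.gene_id}\t{label}\n")
    with open(paths["repeats_bed"], "w") as fh:
        for r in sorted(repeat_feats, key=lambda r: (r.interval.chrom, r.interval.start)):
            fh.write(
                f"{r.interval.chrom}\t{r.interval.start}\t{r.interval.end}\t"
                f"{names[r.repeat_class]}\t0\t+\n"
            )
    with open(paths["peaks_bed"], "w") as fh:
        for chrom, s, e in sorted(peaks):
            fh.write(f"{chrom}\t{s}\t{e}\tpeak\t100\t.\n")
    _write_bedgraph(coverage_runs, paths["coverage_bedgraph"])
    _write_bedgraph(score_runs, paths["score_bedgraph"])
    write_chain(chains, paths["chain"])

    # motif transcript positions, recorded by searching the extracted sequence
    from .annotation import extract_gene_sequence

    motif_positions: dict[str, int] = {}
    for gid in carriers:
        seq = extract_gene_sequence(by_id[gid].model("lncRNA_candidate"), genome_a)
        pos = seq.find(cfg.motif)
        assert pos >= 0, f"planted motif lost in {gid}"
        motif_positions[gid] = pos

    truth = GroundTruth(
        classes={
            p.gene_id: p.planted_class for p in classed_lnc if p.planted_class
        },
        novelty={
            p.gene_id: ("known" if p.gene_id in known_ids else "novel")
            for p in classed_lnc
        },
        short_genes=[p.gene_id for p in lnc_like if p.role == "short"],
        single_exon_genes=[p.gene_id for p in lnc_like if p.role == "single_exon"],
        coding_contaminants=[p.gene_id for p in lnc_like if p.role == "contaminant"],
        expressed=expressed,
        de_lnc=de_lnc,
        planted_log2fc=planted_fc,
        nearest_pairs=nearest_pairs,
        motif=cfg.motif,
        motif_positions=motif_positions,
        repeat_features=repeat_feats,
        syntenic=syntenic,
        active_genes=active,
        inactive_genes=inactive,
    )
    return SimulatedBundle(out_dir=out, truth=truth, config=cfg, **paths)
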