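"""Conserved-microdomain discovery by all-vs-all ungapped local alignment.

Short (12-50 nt) near-exact segments shared between lncRNAs are candidate
functional microdomains.  They are found by a seed-and-extend search: exact
``word_size``-mer seeds between each sequence pair (both subject strands)
are extended without gaps under an X-drop rule, trimmed to their
maximal-scoring segment, and scored.  Significance uses Karlin-Altschul
statistics, E = K * m * n * exp(-lambda * S): lambda is the positive root of
the score-generating equation for the background base composition, and K is
calibrated by a seeded Monte-Carlo fit of the Gumbel location of maximal
segment scores on random sequence pairs.

The null model for hit counts is a set of random sequences matched to the
catalog in length and AT composition, mirroring how shared-segment
enrichment is judged against matched random controls.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import optimize, stats

from .annotation import reverse_complement, write_fasta

__all__ = [
    "KarlinAltschulParams",
    "AlignmentHit",
    "karlin_altschul_params",
    "calibrate_k",
    "generate_matched_controls",
    "local_align_all_pairs",
    "hit_length_stats",
    "compare_hit_counts",
    "export_hits_fasta",
    "write_hit_table",
]

_EULER_GAMMA = 0.5772156649015329
_BASES = "ACGT"


@dataclass(frozen=True)
class KarlinAltschulParams:
    """Ungapped local-alignment significance parameters.

    lambda_ and k_const parameterize the extreme-value tail of maximal
    segment scores; base_probs is the background composition (A, C, G, T)
    the scores are judged against.
    """

    lambda_: float
    k_const: float
    base_probs: tuple[float, float, float, float]
    match_score: int
    mismatch_score: int

    def evalue(self, score: float, m: int, n: int) -> float:
        return self.k_const * m * n * math.exp(-self.lambda_ * score)


@dataclass
class AlignmentHit:
    """One ungapped local alignment between two catalog sequences."""

    query_id: str
    subject_id: str
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    subject_strand: str
    length: int
    n_ident: int
    score: int
    evalue: float

    @property
    def pident(self) -> float:
        return 100.0 * self.n_ident / self.length


def _expected_score(
    base_probs: Sequence[float], match: int, mismatch: int
) -> float:
    p = np.asarray(base_probs, float)
    p_match = float(np.sum(p * p))
    return p_match * match + (1.0 - p_match) * mismatch


def karlin_altschul_params(
    base_probs: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
    match: int = 2,
    mismatch: int = -3,
    k_const: float | None = None,
    calibration_seed: int = 20170828,
    calibration_length: int = 300,
    calibration_sims: int = 40,
) -> KarlinAltschulParams:
    """Solve for lambda and (optionally) calibrate K.

    lambda is the unique positive root of
    ``sum_ij p_i p_j exp(lambda * s(i, j)) = 1`` with s(i,j) = match on the
    diagonal and mismatch off it, found to |f| < 1e-10.  K defaults to a
    seeded Monte-Carlo calibration (:func:`calibrate_k`); pass ``k_const``
    to override with a fixed constant.
    """
    p = np.asarray(base_probs, float)
    if p.shape != (4,) or (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("base_probs must be 4 non-negative values summing to 1")
    if match <= 0 or mismatch >= 0:
        raise ValueError("need match > 0 and mismatch < 0")
    if _expected_score(p, match, mismatch) >= 0:
        raise ValueError("expected pairwise score must be negative")

    p_match = float(np.sum(p * p))

    def f(lam: float) -> float:
        return p_match * math.exp(lam * match) + (1 - p_match) * math.exp(lam * mismatch) - 1.0

    hi = 1.0
    while f(hi) < 0:
        hi *= 2.0
    lam = optimize.brentq(f, 1e-12, hi, xtol=1e-14, rtol=8.9e-16)
    assert abs(f(lam)) < 1e-10
    params = KarlinAltschulParams(lam, 0.1, tuple(p), match, mismatch)
    if k_const is None:
        k_const = calibrate_k(
            params,
            seed=calibration_seed,
            length=calibration_length,
            n_sims=calibration_sims,
        )
    return KarlinAltschulParams(lam, k_const, tuple(p), match, mismatch)


def _max_segment_score(a: np.ndarray, b: np.ndarray, match: int, mismatch: int) -> int:
    """Maximal ungapped local-alignment score between two base arrays.

    Exact by exhaustion: per diagonal, the best contiguous-subarray sum of
    the per-position match/mismatch scores (prefix-sum minus running
    minimum).
    """
    n, m = len(a), len(b)
    best = 0
    for d in range(-(n - 1), m):
        if d >= 0:
            ai, bi = a[: min(n, m - d)], b[d : d + min(n, m - d)]
        else:
            ai, bi = a[-d : -d + min(n + d, m)], b[: min(n + d, m)]
        s = np.where(ai == bi, match, mismatch).astype(np.int64)
        cs = np.cumsum(s)
        run_min = np.minimum.accumulate(np.concatenate(([0], cs[:-1])))
        best = max(best, int(np.max(cs - run_min)))
    return best


def calibrate_k(
    params: KarlinAltschulParams,
    seed: int = 20170828,
    length: int = 300,
    n_sims: int = 40,
) -> float:
    """Monte-Carlo estimate of the Karlin-Altschul K constant.

    Maximal segment scores of random sequence pairs follow a Gumbel law with
    location ln(K m n) / lambda, so E[S_max] = (ln(K m n) + gamma) / lambda.
    K is recovered from the mean maximal score over ``n_sims`` seeded random
    pairs drawn from ``base_probs``.
    """
    rng = np.random.default_rng(seed)
    p = np.asarray(params.base_probs, float)
    scores = []
    for _ in range(n_sims):
        a = rng.choice(4, size=length, p=p)
        b = rng.choice(4, size=length, p=p)
        scores.append(
            _max_segment_score(a, b, params.match_score, params.mismatch_score)
        )
    mean_smax = float(np.mean(scores))
    k = math.exp(params.lambda_ * mean_smax - _EULER_GAMMA) / (length * length)
    return float(np.clip(k, 1e-6, 10.0))


def generate_matched_controls(
    lengths: Sequence[int], at_fraction: float, seed: int
) -> list[str]:
    """Random null sequences matched in length and AT composition.

    One i.i.d. sequence per requested length with P(A) = P(T) =
    at_fraction / 2 and P(G) = P(C) = (1 - at_fraction) / 2; reproducible
    from ``seed``.
    """
    if not 0.0 <= at_fraction <= 1.0:
        raise ValueError(f"at_fraction {at_fraction} outside [0, 1]")
    if any(L <= 0 for L in lengths):
        raise ValueError("lengths must be positive")
    rng = np.random.default_rng(seed)
    probs = [at_fraction / 2, (1 - at_fraction) / 2, (1 - at_fraction) / 2, at_fraction / 2]
    return [
        "".join(np.array(list("ACGT"))[rng.choice(4, size=L, p=probs)])
        for L in lengths
    ]


def apply_mask_template(control: str, template: str) -> str:
    """Copy a template sequence's N-mask onto a control of equal length.

    A null for a masked catalog must carry the catalog's masks, otherwise
    the controls hold more seedable words per base than the sequences they
    calibrate.
    """
    if len(control) != len(template):
        raise ValueError("control and template lengths differ")
    return "".join("N" if t == "N" else c for c, t in zip(control, template))


# ---------------------------------------------------------------------------
# Seed-and-extend aligner
# ---------------------------------------------------------------------------

def _word_index(seq: str, word_size: int) -> dict[str, list[int]]:
    """Positions of every exact word; words containing N never seed."""
    idx: dict[str, list[int]] = {}
    for i in range(len(seq) - word_size + 1):
        w = seq[i : i + word_size]
        if "N" in w:
            continue
        idx.setdefault(w, []).append(i)
    return idx


def _extend_seed(
    q: str,
    s: str,
    q_pos: int,
    s_pos: int,
    word_size: int,
    match: int,
    mismatch: int,
    x_drop: int,
) -> tuple[int, int, int, int]:
    """Ungapped two-sided X-drop extension trimmed to the maximal segment.

    Returns (q_start, q_end, score, n_ident) of the best-scoring segment
    containing the seed word; subject coordinates follow from the diagonal.
    """

    def step(i: int, j: int) -> int:
        return match if q[i] == s[j] and q[i] != "N" and s[j] != "N" else mismatch

    seed_score = word_size * match

    # rightward from the seed's end
    best_right, best_right_end = 0, q_pos + word_size
    run = 0
    i, j = q_pos + word_size, s_pos + word_size
    while i < len(q) and j < len(s):
        run += step(i, j)
        if run > best_right:
            best_right, best_right_end = run, i + 1
        if best_right - run >= x_drop:
            break
        i += 1
        j += 1

    # leftward from the seed's start
    best_left, best_left_start = 0, q_pos
    run = 0
    i, j = q_pos - 1, s_pos - 1
    while i >= 0 and j >= 0:
        run += step(i, j)
        if run > best_left:
            best_left, best_left_start = run, i
        if best_left - run >= x_drop:
            break
        i -= 1
        j -= 1

    q_start, q_end = best_left_start, best_right_end
    score = seed_score + best_left + best_right
    d = s_pos - q_pos
    n_ident = sum(
        1 for k in range(q_start, q_end) if q[k] == s[k + d] and q[k] != "N"
    )
    return q_start, q_end, score, n_ident


def _align_pair_one_strand(
    qid: str,
    sid: str,
    q: str,
    s_oriented: str,
    strand: str,
    s_len: int,
    q_index: Mapping[str, list[int]],
    params: KarlinAltschulParams,
    word_size: int,
    x_drop: int,
) -> list[AlignmentHit]:
    hits: list[AlignmentHit] = []
    covered: dict[int, list[tuple[int, int]]] = {}  # diagonal -> q-intervals done
    for j in range(len(s_oriented) - word_size + 1):
        w = s_oriented[j : j + word_size]
        if "N" in w:
            continue
        for i in q_index.get(w, ()):
            d = j - i
            if any(a <= i < b for a, b in covered.get(d, ())):
                continue
            q0, q1, score, n_ident = _extend_seed(
                q, s_oriented, i, j, word_size,
                params.match_score, params.mismatch_score, x_drop,
            )
            covered.setdefault(d, []).append((q0, q1))
            so0, so1 = q0 + d, q1 + d  # oriented-subject coordinates
            if strand == "-":
                s0, s1 = s_len - so1, s_len - so0
            else:
                s0, s1 = so0, so1
            hits.append(
                AlignmentHit(
                    qid, sid, q0, q1, s0, s1, strand,
                    q1 - q0, n_ident, score,
                    params.evalue(score, len(q), s_len),
                )
            )
    # merge overlapping same-diagonal hits: keep the best-scoring one
    hits.sort(key=lambda h: (h.s_start - h.q_start, h.q_start))
    kept: list[AlignmentHit] = []
    for h in hits:
        if kept:
            last = kept[-1]
            if (
                last.s_start - last.q_start == h.s_start - h.q_start
                and h.q_start < last.q_end
            ):
                if h.score > last.score:
                    kept[-1] = h
                continue
        kept.append(h)
    return kept


def local_align_all_pairs(
    sequences: Mapping[str, str],
    params: KarlinAltschulParams,
    word_size: int = 11,
    evalue_max: float = 10.0,
    x_drop: int = 20,
) -> list[AlignmentHit]:
    """All-vs-all ungapped local alignment over a sequence catalog.

    Every unordered pair is searched once (no self-pairs, no reciprocal
    duplicates) on both subject strands.  Exact ``word_size``-mer seeds are
    extended without gaps under an X-drop of ``x_drop`` score units and
    trimmed to maximal-scoring segments; hits with
    E = K * m * n * exp(-lambda * S) at most ``evalue_max`` are reported.
    Masked (N) bases never seed and never count as identities.
    """
    items = [(k, v.upper()) for k, v in sequences.items()]
    nonempty = []
    for k, v in items:
        if not v:
            warnings.warn(f"skipping empty sequence {k!r}")
        else:
            nonempty.append((k, v))
    if len(nonempty) < 2:
        raise ValueError("need at least 2 non-empty sequences")
    indices = {k: _word_index(v, word_size) for k, v in nonempty}
    out: list[AlignmentHit] = []
    for a in range(len(nonempty)):
        qid, q = nonempty[a]
        for b in range(a + 1, len(nonempty)):
            sid, s = nonempty[b]
            for strand, s_oriented in (("+", s), ("-", reverse_complement(s))):
                for h in _align_pair_one_strand(
                    qid, sid, q, s_oriented, strand, len(s),
                    indices[qid], params, word_size, x_drop,
                ):
                    if h.evalue <= evalue_max:
                        out.append(h)
    return out


def hit_length_stats(
    hits: Iterable[AlignmentHit], min_len: int = 12, max_len: int = 50
) -> tuple[dict[int, int], int]:
    """Per-length histogram of hits inside the closed [min_len, max_len]
    window, plus the total; hits outside the window are not counted."""
    hist = {L: 0 for L in range(min_len, max_len + 1)}
    for h in hits:
        if min_len <= h.length <= max_len:
            hist[h.length] += 1
    return hist, sum(hist.values())


def compare_hit_counts(*histograms: Mapping[int, int]) -> tuple[float, float]:
    """One-way ANOVA across hit-length histograms (per-length-bin counts as
    observations).  Returns (F, p)."""
    if len(histograms) < 2:
        raise ValueError("need at least 2 groups")
    bins = set(histograms[0])
    if any(set(h) != bins for h in histograms):
        raise ValueError("histograms must share the same length bins")
    groups = [np.array([h[L] for L in sorted(bins)], float) for h in histograms]
    if all(np.array_equal(g, groups[0]) for g in groups[1:]):
        return 0.0, 1.0
    f, p = stats.f_oneway(*groups)
    return float(f), float(p)


def export_hits_fasta(
    hits: Sequence[AlignmentHit], sequences: Mapping[str, str], path: str | Path
) -> None:
    """Write hit subsequences (taken from the query) as FASTA for external
    motif discovery.  Headers encode query/subject ids and coordinates."""
    records: dict[str, str] = {}
    for idx, h in enumerate(hits):
        q = sequences[h.query_id]
        if not (0 <= h.q_start < h.q_end <= len(q)):
            raise ValueError(f"hit coordinates outside query {h.query_id}")
        name = (
            f"hit{idx}|{h.query_id}:{h.q_start}-{h.q_end}|"
            f"{h.subject_id}:{h.s_start}-{h.s_end}({h.subject_strand})"
        )
        records[name] = q[h.q_start : h.q_end]
    write_fasta(records, path)


def write_hit_table(hits: Sequence[AlignmentHit], sequences: Mapping[str, str], path: str | Path) -> None:
    """Tab-delimited hit table: qacc, sacc, sseq, pident, qlen, length, evalue."""
    with open(path, "w") as fh:
        fh.write("qacc\tsacc\tsseq\tpident\tqlen\tlength\tevalue\n")
        for h in hits:
            sseq = sequences[h.query_id][h.q_start : h.q_end]
            fh.write(
                f"{h.query_id}\t{h.subject_id}\t{sseq}\t{h.pident:.2f}\t"
                f"{len(sequences[h.query_id])}\t{h.length}\t{h.evalue:.3g}\n"
            )
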