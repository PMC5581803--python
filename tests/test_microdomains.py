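"""Karlin-Altschul statistics and the seed-and-extend microdomain search."""

import math

import numpy as np
import pytest

from lnccat.annotation import read_fasta, reverse_complement
from lnccat.microdomains import (
    compare_hit_counts,
    export_hits_fasta,
    generate_matched_controls,
    hit_length_stats,
    karlin_altschul_params,
    local_align_all_pairs,
)


@pytest.fixture(scope="module")
def params():
    # fixed K keeps unit tests independent of the Monte-Carlo calibration
    return karlin_altschul_params(match=2, mismatch=-3, k_const=0.3)


def random_seq(rng, n, at=0.5):
    probs = [at / 2, (1 - at) / 2, (1 - at) / 2, at / 2]
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=n, p=probs)])


# ---------------------------------------------------------------------------
# Independent oracle: maximal exact shared substrings by diagonal run-lengths
# ---------------------------------------------------------------------------

def maximal_shared_substrings(a: str, b: str, min_len: int):
    """All maximal exact shared substrings of length >= min_len, as
    (a_start, b_start, length), by exhaustive diagonal scanning."""
    A = np.frombuffer(a.encode(), dtype=np.uint8)
    B = np.frombuffer(b.encode(), dtype=np.uint8)
    out = []
    for d in range(-(len(A) - 1), len(B)):
        if d >= 0:
            ai, bi = 0, d
        else:
            ai, bi = -d, 0
        L = min(len(A) - ai, len(B) - bi)
        eq = A[ai : ai + L] == B[bi : bi + L]
        run = 0
        for k in range(L + 1):
            if k < L and eq[k]:
                run += 1
            else:
                if run >= min_len:
                    out.append((ai + k - run, bi + k - run, run))
                run = 0
    return out


class TestLambda:
    def test_uniform_plus1_minus1_closed_form(self):
        p = karlin_altschul_params(match=1, mismatch=-1, k_const=0.1)
        assert p.lambda_ == pytest.approx(math.log(3), abs=1e-8)

    def test_plus2_minus3_matches_bisection_oracle(self):
        p = karlin_altschul_params(match=2, mismatch=-3, k_const=0.1)

        def f(lam):
            return 0.25 * math.exp(2 * lam) + 0.75 * math.exp(-3 * lam) - 1.0

        lo, hi = 1e-9, 4.0
        for _ in range(80):  # plain bisection, independent of brentq
            mid = (lo + hi) / 2
            if f(mid) < 0:
                lo = mid
            else:
                hi = mid
        assert p.lambda_ == pytest.approx((lo + hi) / 2, abs=1e-6)

    def test_invalid_scoring_rejected(self):
        with pytest.raises(ValueError):
            karlin_altschul_params(match=0, mismatch=-1)
        with pytest.raises(ValueError):
            karlin_altschul_params(match=5, mismatch=-1)  # positive expectation

    def test_skewed_composition_shifts_lambda(self):
        uni = karlin_altschul_params(match=1, mismatch=-1, k_const=0.1)
        at_rich = karlin_altschul_params(
            base_probs=(0.35, 0.15, 0.15, 0.35), match=1, mismatch=-1, k_const=0.1
        )
        # more self-matching composition -> smaller lambda
        assert at_rich.lambda_ < uni.lambda_


class TestMatchedControls:
    def test_lengths_reproduced_exactly(self):
        lens = [5, 17, 200]
        assert [len(s) for s in generate_matched_controls(lens, 0.5, 3)] == lens

    def test_pure_at(self):
        (s,) = generate_matched_controls([500], 1.0, 7)
        assert set(s) <= {"A", "T"}

    def test_at_fraction_concentrates(self):
        seqs = generate_matched_controls([250_000] * 4, 0.58, 11)
        joined = "".join(seqs)
        at = (joined.count("A") + joined.count("T")) / len(joined)
        assert abs(at - 0.58) < 0.005

    def test_reproducible_and_seed_sensitive(self):
        a = generate_matched_controls([100], 0.5, 42)
        b = generate_matched_controls([100], 0.5, 42)
        c = generate_matched_controls([100], 0.5, 43)
        assert a == b and a != c

    def test_bad_at_fraction_rejected(self):
        with pytest.raises(ValueError):
            generate_matched_controls([10], 1.5, 0)


class TestAligner:
    def test_identical_sequences_single_full_hit(self, params):
        s = "ACGTGCATTAGGCCATGCAAGTCAGTCACGTGGATCCAGTCAGGTACGATCGATTGCAAG"
        hits = local_align_all_pairs({"a": s, "b": s}, params)
        plus = [h for h in hits if h.subject_strand == "+"]
        best = max(plus, key=lambda h: h.score)
        assert best.length == 60 and best.pident == 100.0
        assert (best.q_start, best.q_end) == (0, 60)

    def test_planted_block_recovered(self, params):
        rng = np.random.default_rng(5)
        block = random_seq(rng, 25)
        s1 = random_seq(rng, 150) + block + random_seq(rng, 150)
        s2 = random_seq(rng, 80) + block + random_seq(rng, 200)
        hits = local_align_all_pairs({"a": s1, "b": s2}, params)
        # oracle: the longest exact shared substring must sit inside a hit
        shared = maximal_shared_substrings(s1, s2, 25)
        qa, qb, L = max(shared, key=lambda t: t[2])
        assert any(
            h.q_start <= qa and h.q_end >= qa + L and h.subject_strand == "+"
            for h in hits
        )

    def test_reverse_complement_plant_found_on_minus(self, params):
        rng = np.random.default_rng(6)
        block = random_seq(rng, 30)
        s1 = random_seq(rng, 100) + block + random_seq(rng, 100)
        s2 = random_seq(rng, 60) + reverse_complement(block) + random_seq(rng, 90)
        hits = local_align_all_pairs({"a": s1, "b": s2}, params)
        minus = [h for h in hits if h.subject_strand == "-" and h.length >= 30]
        assert minus
        h = max(minus, key=lambda x: x.score)
        # subject coordinates are on the original (forward) subject
        assert s2[h.s_start : h.s_end] == reverse_complement(s1[h.q_start : h.q_end])

    def test_no_shared_word_no_hits(self, params):
        hits = local_align_all_pairs({"a": "ACGT" * 20, "b": "AACC" * 20}, params)
        assert hits == []

    def test_masked_bases_never_seed(self, params):
        s = "ACGTGCATTAGGCCATGCAAGTCAGTCACG"
        masked = "N" * len(s)
        hits = local_align_all_pairs({"a": s, "b": masked}, params)
        assert hits == []

    def test_evalue_monotone_in_score(self, params):
        rng = np.random.default_rng(9)
        seqs = {f"s{i}": random_seq(rng, 400) for i in range(4)}
        seqs["s0"] = seqs["s1"][:150] + random_seq(rng, 250)
        hits = local_align_all_pairs(seqs, params, evalue_max=1e9)
        pairs = {}
        for h in hits:
            pairs.setdefault((h.query_id, h.subject_id), []).append(h)
        for hs in pairs.values():
            by_score = sorted(hs, key=lambda h: -h.score)
            by_e = sorted(hs, key=lambda h: h.evalue)
            assert [h.score for h in by_score] == [h.score for h in by_e]

    def test_oracle_equivalence_on_random_catalog(self, params):
        """Every maximal exact shared substring >= word_size lies inside a
        reported hit (both orientations), vs exhaustive enumeration."""
        rng = np.random.default_rng(17)
        seqs = {f"s{i}": random_seq(rng, 300, at=0.58) for i in range(8)}
        # plant some structure so the check is not vacuous
        motif = random_seq(rng, 18)
        seqs["s1"] = seqs["s1"][:50] + motif + seqs["s1"][68:]
        seqs["s4"] = seqs["s4"][:200] + motif + seqs["s4"][218:]
        seqs["s5"] = seqs["s5"][:10] + reverse_complement(motif) + seqs["s5"][28:]
        hits = local_align_all_pairs(seqs, params, word_size=11)
        names = list(seqs)
        n_checked = 0
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                q, s = seqs[names[i]], seqs[names[j]]
                for strand in "+-":
                    target = s if strand == "+" else reverse_complement(s)
                    for qa, sa, L in maximal_shared_substrings(q, target, 11):
                        n_checked += 1
                        matching = [
                            h
                            for h in hits
                            if h.query_id == names[i]
                            and h.subject_id == names[j]
                            and h.subject_strand == strand
                            and h.q_start <= qa
                            and h.q_end >= qa + L
                        ]
                        assert matching, (names[i], names[j], strand, qa, L)
        assert n_checked >= 3  # the planted motifs guarantee real work


class TestHitStats:
    def make_hit(self, length, params):
        from lnccat.microdomains import AlignmentHit

        return AlignmentHit("a", "b", 0, length, 0, length, "+", length, length,
                            2 * length, 1e-5)

    def test_closed_interval_boundaries(self, params):
        hits = [self.make_hit(L, params) for L in (11, 12, 50, 51)]
        hist, total = hit_length_stats(hits)
        assert total == 2
        assert hist[12] == 1 and hist[50] == 1
        assert 51 not in hist and 11 not in hist

    def test_histogram_sums_to_total(self, params):
        hits = [self.make_hit(L, params) for L in (12, 12, 20, 49)]
        hist, total = hit_length_stats(hits)
        assert sum(hist.values()) == total == 4

    def test_empty(self, params):
        hist, total = hit_length_stats([])
        assert total == 0 and all(v == 0 for v in hist.values())


class TestCompareHitCounts:
    def test_identical_groups_f_zero_p_one(self):
        h = {12: 5, 13: 3, 14: 1}
        assert compare_hit_counts(h, dict(h), dict(h)) == (0.0, 1.0)

    def test_matches_textbook_decomposition(self):
        g1, g2, g3 = {1: 1, 2: 2, 3: 3}, {1: 2, 2: 3, 3: 4}, {1: 6, 2: 7, 3: 11}
        f, p = compare_hit_counts(g1, g2, g3)
        # hand-computed one-way ANOVA sums of squares
        groups = [[1, 2, 3], [2, 3, 4], [6, 7, 11]]
        grand = np.mean([x for g in groups for x in g])
        ss_between = sum(len(g) * (np.mean(g) - grand) ** 2 for g in groups)
        ss_within = sum((x - np.mean(g)) ** 2 for g in groups for x in g)
        f_oracle = (ss_between / 2) / (ss_within / 6)
        assert f == pytest.approx(f_oracle, rel=1e-12)

    def test_bin_order_irrelevant(self):
        g1, g2 = {12: 5, 13: 1, 14: 9}, {12: 2, 13: 2, 14: 2}
        f1, _ = compare_hit_counts(g1, g2)
        g1r = {14: 9, 12: 5, 13: 1}
        f2, _ = compare_hit_counts(g1r, g2)
        assert f1 == pytest.approx(f2)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            compare_hit_counts({12: 1})


class TestExportHits:
    def test_zero_hits_empty_file(self, tmp_path, params):
        export_hits_fasta([], {}, tmp_path / "h.fa")
        assert read_fasta(tmp_path / "h.fa") == {}

    def test_record_equals_query_slice(self, tmp_path, params):
        rng = np.random.default_rng(3)
        block = random_seq(rng, 40)
        seqs = {
            "q": random_seq(rng, 60) + block + random_seq(rng, 60),
            "s": random_seq(rng, 30) + block + random_seq(rng, 30),
        }
        hits = local_align_all_pairs(seqs, params)
        export_hits_fasta(hits, seqs, tmp_path / "h.fa")
        recs = read_fasta(tmp_path / "h.fa")
        assert len(recs) == len(hits)
        for h in hits:
            sub = seqs[h.query_id][h.q_start : h.q_end]
            assert sub in recs.values()

    def test_exported_hit_realigns_to_source(self, tmp_path, params):
        rng = np.random.default_rng(4)
        block = random_seq(rng, 30)
        seqs = {
            "q": random_seq(rng, 50) + block + random_seq(rng, 50),
            "s": random_seq(rng, 80) + block + random_seq(rng, 20),
        }
        hits = local_align_all_pairs(seqs, params)
        h = max(hits, key=lambda x: x.score)
        fragment = seqs["q"][h.q_start : h.q_end]
        re_hits = local_align_all_pairs({"frag": fragment, "q": seqs["q"]}, params)
        best = max(re_hits, key=lambda x: x.score)
        assert (best.s_start, best.s_end) == (h.q_start, h.q_end) or (
            best.q_start,
            best.q_end,
        ) == (h.q_start, h.q_end)
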