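"""Expression thresholds, DE intake, specificity spectra and cis correlation."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from lnccat.catalog import PositionalClass
from lnccat.expression import (
    DERecord,
    ExpressionError,
    ExpressionMatrix,
    class_distribution,
    de_filter,
    expressed_genes,
    expression_stats,
    fold_change_correlation,
    genes_within_window,
    multiplicity_summary,
    nearest_coding_gene,
    round_half_up,
)
from .conftest import mk_gene, spectrum_sets


def matrix(values: dict[str, list[float]], samples):
    df = pd.DataFrame(values, index=[s[0] for s in samples]).T
    meta = pd.DataFrame(
        {"cell_type": [s[1] for s in samples], "condition": [s[2] for s in samples]},
        index=[s[0] for s in samples],
    )
    return ExpressionMatrix(df, meta)


SAMPLES = [
    ("m_c1", "mono", "control"),
    ("m_c2", "mono", "control"),
    ("m_s1", "mono", "stimulated"),
    ("m_s2", "mono", "stimulated"),
]


class TestExpressedGenes:
    def test_threshold_is_strict(self):
        m = matrix({"g": [1.0, 1.0, 1.0, 1.0]}, SAMPLES)
        assert expressed_genes(m)["mono"] == set()

    def test_either_condition_suffices(self):
        m = matrix({"g": [0.5, 0.5, 1.5, 1.5]}, SAMPLES)
        assert expressed_genes(m)["mono"] == {"g"}

    def test_all_zero_matrix_gives_empty_sets(self):
        m = matrix({"g": [0, 0, 0, 0], "h": [0, 0, 0, 0]}, SAMPLES)
        assert expressed_genes(m) == {"mono": set()}

    def test_mean_over_replicates_not_any_sample(self):
        # one replicate above 1, mean below: not expressed
        m = matrix({"g": [1.8, 0.1, 0.2, 0.2]}, SAMPLES)
        assert expressed_genes(m)["mono"] == set()


class TestMultiplicity:
    def test_reported_spectrum_161_33_8_2(self):
        # the four-cell-type DE spectrum: 161/33/8/2 over a union of 204
        ms = multiplicity_summary(spectrum_sets({1: 161, 2: 33, 3: 8, 4: 2}))
        assert ms.union_size == 204
        assert [ms.counts[k] for k in (1, 2, 3, 4)] == [161, 33, 8, 2]
        assert [ms.rounded[k] for k in (1, 2, 3, 4)] == [79, 16, 4, 1]

    def test_disjoint_sets_all_multiplicity_one(self):
        sets = {c: {f"{c}{i}" for i in range(5)} for c in "abcd"}
        ms = multiplicity_summary(sets)
        assert ms.rounded[1] == 100 and ms.counts[2] == 0

    def test_identical_sets_all_top_multiplicity(self):
        s = {"x", "y", "z"}
        ms = multiplicity_summary({c: set(s) for c in "abcd"})
        assert ms.counts[4] == 3 and ms.rounded[4] == 100

    def test_counts_sum_to_union(self):
        sets = {"a": {"1", "2", "3"}, "b": {"2", "4"}, "c": {"2", "3", "5"}}
        ms = multiplicity_summary(sets)
        assert sum(ms.counts.values()) == ms.union_size == 5
        assert math.isclose(sum(ms.percentages.values()), 100.0)


class TestClassDistribution:
    def test_reported_distribution_127_45_17_15(self):
        labels = (
            [PositionalClass.LINCRNA] * 127
            + [PositionalClass.AS] * 45
            + [PositionalClass.AS_DOWNSTREAM] * 17
            + [PositionalClass.AS_UPSTREAM] * 15
        )
        dist = class_distribution(labels)
        assert dist.total == 204
        assert dist.percentages[PositionalClass.LINCRNA] == pytest.approx(62.25, abs=0.005)
        assert dist.percentages[PositionalClass.AS] == pytest.approx(22.06, abs=0.005)
        assert dist.percentages[PositionalClass.AS_DOWNSTREAM] == pytest.approx(8.33, abs=0.005)
        assert dist.percentages[PositionalClass.AS_UPSTREAM] == pytest.approx(7.35, abs=0.005)
        # half-up integer display; 7.35 rounds to 7 (the source table printed 8)
        assert [dist.rounded[k] for k in (
            PositionalClass.LINCRNA, PositionalClass.AS,
            PositionalClass.AS_DOWNSTREAM, PositionalClass.AS_UPSTREAM,
        )] == [62, 22, 8, 7]

    def test_excluded_not_in_denominator(self):
        labels = [PositionalClass.LINCRNA] * 3 + [PositionalClass.EXCLUDED_SAME_STRAND] * 7
        dist = class_distribution(labels)
        assert dist.total == 3
        assert dist.rounded[PositionalClass.LINCRNA] == 100

    def test_equal_counts_quarter_each(self):
        labels = [
            PositionalClass.LINCRNA, PositionalClass.AS,
            PositionalClass.AS_UPSTREAM, PositionalClass.AS_DOWNSTREAM,
        ] * 5
        dist = class_distribution(labels)
        assert all(v == 25 for v in dist.rounded.values())


class TestDEFilter:
    def test_q_threshold_is_strict(self):
        recs = [
            DERecord("a", "mono", 1.0, 0.05),
            DERecord("b", "mono", 1.0, 0.049),
        ]
        sets, union = de_filter(recs)
        assert sets["mono"] == {"b"} and union == {"b"}

    def test_union_by_inclusion_exclusion(self):
        recs = [DERecord(f"g{i}", "a", 1.0, 0.01) for i in range(6)] + [
            DERecord(f"g{i}", "b", 1.0, 0.01) for i in range(4, 9)
        ]
        sets, union = de_filter(recs)
        assert len(union) == len(sets["a"]) + len(sets["b"]) - len(sets["a"] & sets["b"])

    @given(st.floats(0.0, 0.5), st.floats(0.0, 0.5))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_monotone_in_alpha(self, a1, a2):
        recs = [DERecord(f"g{i}", "x", 0.0, q) for i, q in enumerate(np.linspace(0, 1, 21))]
        lo, hi = sorted([a1, a2])
        s_lo, _ = de_filter(recs, lo)
        s_hi, _ = de_filter(recs, hi)
        assert s_lo["x"] <= s_hi["x"]


class TestExpressionStats:
    def test_single_gene(self):
        m = matrix({"g": [10, 10, 10, 10]}, SAMPLES)
        assert expression_stats(["g"], m) == (10.0, 0.0)

    def test_mean_and_sem_hand_computed(self):
        m = matrix({"a": [1] * 4, "b": [2] * 4, "c": [3] * 4}, SAMPLES)
        mean, sem = expression_stats(["a", "b", "c"], m)
        assert mean == pytest.approx(2.0)
        assert sem == pytest.approx(1 / math.sqrt(3), abs=1e-12)

    def test_linearity_under_scaling(self):
        m1 = matrix({"a": [1, 1, 3, 3], "b": [2, 2, 5, 5]}, SAMPLES)
        m2 = matrix({"a": [2, 2, 6, 6], "b": [4, 4, 10, 10]}, SAMPLES)
        mean1, sem1 = expression_stats(["a", "b"], m1)
        mean2, sem2 = expression_stats(["a", "b"], m2)
        assert mean2 == pytest.approx(2 * mean1) and sem2 == pytest.approx(2 * sem1)

    def test_empty_set_rejected(self):
        m = matrix({"g": [1, 1, 1, 1]}, SAMPLES)
        with pytest.raises(ExpressionError):
            expression_stats([], m)


class TestNearestCoding:
    lnc = mk_gene("l", "c", "+", [(10_000, 12_000)])
    coding = [
        mk_gene("far", "c", "+", [(13_000, 14_000)], "coding"),     # gap 1000
        mk_gene("near", "c", "-", [(12_100, 12_500)], "coding"),    # gap 100
        mk_gene("overlap", "c", "-", [(11_000, 11_500)], "coding"), # gap 0
        mk_gene("other", "d", "+", [(10_000, 12_000)], "coding"),
    ]

    def test_overlapping_gene_wins_at_distance_zero(self):
        assert nearest_coding_gene(self.lnc, self.coding) == ("overlap", 0)

    def test_minimal_gap_selected(self):
        coding = [c for c in self.coding if c.gene_id != "overlap"]
        assert nearest_coding_gene(self.lnc, coding) == ("near", 100)

    def test_none_beyond_max_dist(self):
        assert nearest_coding_gene(self.lnc, self.coding, max_dist=0) == ("overlap", 0)
        far_only = [self.coding[0]]
        assert nearest_coding_gene(self.lnc, far_only, max_dist=999) is None

    def test_tie_breaks_by_start_then_id(self):
        a = mk_gene("b_gene", "c", "+", [(13_000, 13_500)], "coding")
        b = mk_gene("a_gene", "c", "+", [(13_000, 13_500)], "coding")
        assert nearest_coding_gene(self.lnc, [a, b])[0] == "a_gene"

    def test_window_listing_sorted_by_gap(self):
        hits = genes_within_window(self.lnc, self.coding, max_dist=1_000_000)
        assert [h[0] for h in hits] == ["overlap", "near", "far"]


class TestFoldChangeCorrelation:
    def test_perfect_correlation_both_signs(self):
        xs = [(-1.0, -1.0), (0.0, 0.0), (2.0, 2.0)]
        assert fold_change_correlation(xs).r == pytest.approx(1.0)
        ys = [(x, -y) for x, y in xs]
        assert fold_change_correlation(ys).r == pytest.approx(-1.0)

    def test_matches_direct_product_moment_formula(self):
        pairs = [(0.3, 1.1), (-1.2, -0.4), (2.5, 1.9), (0.0, 0.3), (-0.7, -1.5)]
        x = np.array([p[0] for p in pairs])
        y = np.array([p[1] for p in pairs])
        # textbook formula, evaluated independently of scipy
        r_oracle = float(
            np.sum((x - x.mean()) * (y - y.mean()))
            / math.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
        )
        n = len(pairs)
        t = r_oracle * math.sqrt((n - 2) / (1 - r_oracle**2))
        from scipy import stats as ss

        p_oracle = 2 * ss.t.sf(abs(t), n - 2)
        res = fold_change_correlation(pairs)
        assert res.r == pytest.approx(r_oracle, abs=1e-12)
        assert res.p_value == pytest.approx(p_oracle, rel=1e-9)
        assert res.n == 5

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ExpressionError):
            fold_change_correlation([(1.0, 2.0), (2.0, 3.0)])
        with pytest.raises(ExpressionError):
            fold_change_correlation([(1.0, 2.0), (1.0, 3.0), (1.0, 4.0)])


def test_round_half_up_display_rule():
    assert [round_half_up(x) for x in (7.35, 7.5, 78.9, 0.49)] == [7, 8, 79, 0]
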