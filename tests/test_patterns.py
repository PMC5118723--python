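import itertools

import numpy as np
import pandas as pd
import pytest

from polyploid_eld import destats, patterns, simdata
from polyploid_eld.errors import ConsistencyError, DomainError
from polyploid_eld.patterns import (
    classify_pattern,
    midparent,
    nonadditive_test,
    pattern_calls,
    summarize_pattern_counts,
    summarize_patterns,
)
from polyploid_eld.tables_io import ExpressionTable


def oracle_classify(d_ab: str, d_ca: str, d_cb: str) -> str:
    """Independent aggregate-class oracle via explicit ordering search.

    A triple is coherent iff some integer valuation (a, b, c) in {0,1,2}^3
    satisfies all three pairwise relations; the aggregate follows from C's
    place among the parents in that valuation.
    """
    rel = {"less": -1, "equal": 0, "greater": 1}
    for a, b, c in itertools.product(range(3), repeat=3):
        if (
            np.sign(a - b) == rel[d_ab]
            and np.sign(c - a) == rel[d_ca]
            and np.sign(c - b) == rel[d_cb]
        ):
            if a == b == c:
                return "no_change"
            if c > max(a, b):
                return "transgressive_up"
            if c < min(a, b):
                return "transgressive_down"
            if c == a:
                return "ELD_a_up" if c > b else "ELD_a_down"
            if c == b:
                return "ELD_b_up" if c > a else "ELD_b_down"
            return "additive"
    return "conflicting"


class TestClassify:
    def test_all_equal_is_no_change(self):
        cat = classify_pattern("equal", "equal", "equal")
        assert cat.label == "no_change"

    def test_pattern_ii_is_maternal_dominant_up(self):
        # C = A (mother), both above B: the up-biased maternal-dominance class
        cat = classify_pattern("greater", "equal", "greater")
        assert cat.label == "II"
        assert cat.aggregate == "ELD_a_up"

    def test_exhaustive_27_triples_match_ordering_oracle(self):
        counts = {}
        for triple in itertools.product(("less", "equal", "greater"), repeat=3):
            got = classify_pattern(*triple)
            assert got.aggregate == oracle_classify(*triple), triple
            counts[got.aggregate] = counts.get(got.aggregate, 0) + 1
        assert counts["conflicting"] == 14
        assert counts["additive"] == 2
        assert counts["ELD_a_up"] + counts["ELD_a_down"] == 2
        assert counts["ELD_b_up"] + counts["ELD_b_down"] == 2
        assert counts["transgressive_up"] == 3
        assert counts["transgressive_down"] == 3
        assert counts["no_change"] == 1

    def test_twelve_distinct_roman_labels(self):
        labels = {
            classify_pattern(*t).label
            for t in itertools.product(("less", "equal", "greater"), repeat=3)
        }
        romans = labels - {"no_change", "conflicting"}
        assert romans == {"I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X",
                          "XI", "XII"}

    def test_invalid_direction_rejected(self):
        with pytest.raises(DomainError):
            classify_pattern("equal", "equal", "sideways")


class TestMidparent:
    def test_identity_zero_and_mean(self):
        assert midparent(5.0, 5.0) == 5.0
        assert midparent(0.0, 0.0) == 0.0
        assert midparent(10.0, 30.0) == 20.0

    def test_negative_rejected(self):
        with pytest.raises(DomainError):
            midparent(-1.0, 2.0)


def _table(rows: dict, lib: int = 10**6) -> ExpressionTable:
    df = pd.DataFrame(rows, dtype=np.int64).T
    df.columns = ["A", "B", "C"]
    df.index.name = "feature_id"
    return ExpressionTable(df, library_sizes=pd.Series({"A": lib, "B": lib, "C": lib}))


class TestNonadditive:
    def test_c_equal_to_parents_not_flagged(self):
        table = _table({"g1": [100, 100, 100], "g2": [30, 30, 30]})
        res = nonadditive_test(table)
        assert not res["nonadditive"].any()

    def test_strong_deviation_flagged_up(self):
        # C = 400 vs parents 100/100: fold change vs MPV = 4, exact p tiny
        table = _table({"g1": [100, 100, 400]})
        res = nonadditive_test(table)
        assert bool(res.loc["g1", "nonadditive"])
        assert res.loc["g1", "direction"] == "up"
        assert res.loc["g1", "log2fc_vs_mpv"] == pytest.approx(2.0, abs=0.02)

    def test_fold_criterion_alone_fails(self):
        # ~1.9-fold deviation: significant but below the two-fold requirement
        table = _table({"g1": [10000, 10000, 19000]})
        res = nonadditive_test(table)
        assert res.loc["g1", "p"] < 0.001
        assert abs(res.loc["g1", "log2fc_vs_mpv"]) < 1.0
        assert not bool(res.loc["g1", "nonadditive"])

    def test_direction_none_iff_not_flagged(self, small_exp):
        res = nonadditive_test(small_exp.gene_counts)
        assert ((res["direction"] == "none") == ~res["nonadditive"]).all()

    def test_truth_recovery_on_synthetic(self, small_exp):
        res = nonadditive_test(small_exp.gene_counts)
        truth = small_exp.truth_nonadditive
        agree = (res["nonadditive"] == truth).mean()
        assert agree >= 0.95


class TestPatternCalls:
    def test_aggregate_counts_partition_features(self, small_exp):
        calls = pattern_calls(small_exp.gene_counts)
        summary = summarize_patterns(calls, deg_total=len(calls))
        assert sum(summary["counts"].values()) == len(calls)

    def test_category_recovery_small_fixture(self, small_exp):
        calls = pattern_calls(small_exp.gene_counts)
        truth = small_exp.truth_gene_class
        for cls in ("ELD_a_up", "ELD_b_down", "transgressive_up", "additive"):
            mask = truth == cls
            assert mask.sum() > 0
            assert (calls.loc[mask, "aggregate"] == cls).mean() >= 0.8, cls

    def test_parent_swap_maps_eld_a_to_eld_b(self, small_exp):
        table = small_exp.gene_counts
        swapped = ExpressionTable(
            table.counts.rename(columns={"A": "B", "B": "A"})[["A", "B", "C"]],
            library_sizes=pd.Series(
                {
                    "A": table.library_sizes["B"],
                    "B": table.library_sizes["A"],
                    "C": table.library_sizes["C"],
                }
            ),
        )
        orig = pattern_calls(table)["aggregate"].value_counts()
        swap = pattern_calls(swapped)["aggregate"].value_counts()
        for a, b in [("ELD_a_up", "ELD_b_up"), ("ELD_a_down", "ELD_b_down")]:
            assert orig.get(a, 0) == swap.get(b, 0)
            assert orig.get(b, 0) == swap.get(a, 0)
        for same in ("additive", "no_change", "transgressive_up", "transgressive_down",
                     "conflicting"):
            assert orig.get(same, 0) == swap.get(same, 0)


class TestSummaries:
    def test_published_style_totals(self):
        # feeding printed per-class tallies reproduces the printed totals
        summary = summarize_pattern_counts(
            {
                "ELD_a_up": 3583,
                "ELD_a_down": 884,
                "ELD_b_up": 1905,
                "ELD_b_down": 1261,
            },
            deg_total=9209,
        )
        assert summary["eld_a_total"] == 4467
        assert summary["eld_b_total"] == 3166
        assert summary["eld_total"] == 7633
        # 4467/9209 = 48.5069%: half-up display rounding gives 48.51
        assert summary["eld_a_share_of_degs"] == 48.51
        assert summary["maternal_bias_ratio"] == pytest.approx(4467 / 3166)

    def test_empty_calls_all_zero(self):
        empty = pd.DataFrame(columns=["aggregate", "nonadditive", "nonadditive_direction"])
        summary = summarize_patterns(empty)
        assert all(v == 0 for v in summary["counts"].values())
        assert summary["eld_total"] == 0

    def test_zero_deg_with_eld_is_inconsistent(self):
        with pytest.raises(ConsistencyError):
            summarize_pattern_counts({"ELD_a_up": 5}, deg_total=0)
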