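"""Chi-square machinery, counting, and descriptive summaries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dreamincorp.errors import DegenerateInputError, ValidationError
from dreamincorp.similarity import SimilarityRecord
from dreamincorp.stats import (
    CountTable,
    allocation_test,
    chisq_gof,
    chisq_pairwise,
    criterion_counts,
    normalize_counts,
    recall_summary,
    score_variability,
    threshold_sweep,
    word_count_summary,
)
from dreamincorp.similarity import Allocation
from dreamincorp.types import ExecutionStatus


def pearson_oracle(counts):
    """Independent textbook summation of the Pearson statistic."""
    counts = list(counts)
    expected = sum(counts) / len(counts)
    return sum((o - expected) ** 2 / expected for o in counts)


class TestChiSquare:
    @pytest.mark.parametrize(
        "counts, printed",
        [
            ((24, 31, 5), 18.10),
            ((29, 24, 20), 1.67),
            ((46, 27, 25), 8.22),
        ],
    )
    def test_recovers_printed_statistics(self, counts, printed):
        res = chisq_gof(counts)
        assert round(res.statistic, 2) == printed
        assert res.df == 2

    def test_equal_counts_give_zero_statistic_p_one(self):
        res = chisq_gof((10, 10, 10))
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_upper_tail_p_monotone_in_statistic(self):
        stats = [chisq_gof(c).statistic for c in [(10, 10, 12), (10, 10, 20), (5, 10, 30)]]
        ps = [chisq_gof(c).p_value for c in [(10, 10, 12), (10, 10, 20), (5, 10, 30)]]
        assert stats == sorted(stats)
        assert ps == sorted(ps, reverse=True)

    def test_zero_total_rejected(self):
        with pytest.raises(DegenerateInputError):
            chisq_gof((0, 0, 0))

    @given(
        st.lists(st.integers(min_value=0, max_value=200), min_size=2, max_size=6)
    )
    @settings(max_examples=300, deadline=None)
    def test_matches_summation_oracle(self, counts):
        if sum(counts) == 0:
            return
        res = chisq_gof(counts)
        assert res.statistic == pytest.approx(pearson_oracle(counts), abs=1e-12)
        assert res.df == len(counts) - 1


class TestPairwise:
    def test_closed_form_for_two_cells(self):
        # for a 2-cell uniform null the statistic is (a-b)^2/(a+b)
        for a, b in [(24, 5), (10, 10), (3, 17)]:
            res = chisq_gof((a, b))
            assert res.statistic == pytest.approx((a - b) ** 2 / (a + b), abs=1e-12)

    def test_three_pairs_with_largest_gap_most_extreme(self):
        table = CountTable(labels=["c", "u", "i"], counts=[24, 31, 5])
        results = chisq_pairwise(table)
        assert len(results) == 3
        by_pair = {r.labels: r.statistic for r in results}
        assert max(by_pair, key=by_pair.get) == ("u", "i")

    def test_equal_pair_statistic_zero(self):
        table = CountTable(labels=["a", "b", "c"], counts=[10, 10, 20])
        results = chisq_pairwise(table)
        assert {r.labels: r.statistic for r in results}[("a", "b")] == 0.0

    def test_bonferroni_scales_p(self):
        table = CountTable(labels=["a", "b", "c"], counts=[24, 31, 5])
        raw = chisq_pairwise(table)
        adj = chisq_pairwise(table, bonferroni=True)
        for r, a in zip(raw, adj):
            assert a.p_value == pytest.approx(min(1.0, r.p_value * 3), abs=1e-12)


def _rec(report_id, plan_id, score):
    return SimilarityRecord(
        report_id=report_id,
        plan_id=plan_id,
        subtask_scores=[score, score - 0.2, -0.5, -0.5, -0.5],
        max_score=score,
    )


STATUSES = {
    ("r1", "pa"): ExecutionStatus.COMPLETED,
    ("r1", "pb"): ExecutionStatus.UNCOMPLETED,
    ("r1", "pc"): ExecutionStatus.INTERRUPTED,
    ("r2", "pa"): ExecutionStatus.COMPLETED,
    ("r2", "pb"): ExecutionStatus.UNCOMPLETED,
    ("r2", "pc"): ExecutionStatus.INTERRUPTED,
}

RECORDS = [
    _rec("r1", "pa", 0.9),
    _rec("r1", "pb", 0.8),
    _rec("r1", "pc", 0.85),
    _rec("r2", "pa", 0.3),
    _rec("r2", "pb", 0.86),
    _rec("r2", "pc", 0.1),
]


class TestCriterionCounts:
    def test_inclusive_boundary(self):
        table = criterion_counts(RECORDS, 0.85, STATUSES)
        assert dict(zip(table.labels, table.counts)) == {
            "completed": 1,
            "uncompleted": 1,
            "interrupted": 1,
        }

    def test_threshold_one_counts_nothing_above(self):
        table = criterion_counts(RECORDS, 1.0, STATUSES)
        assert sum(table.counts) == 0

    def test_tiny_threshold_counts_totals(self):
        table = criterion_counts(RECORDS, 1e-9, STATUSES)
        # scores below the threshold (0.1, 0.3) still count only if >=
        assert table.totals == [2, 2, 2]

    def test_group_by_plan_and_status(self):
        table = criterion_counts(RECORDS, 0.85, STATUSES, group_by="status_x_plan")
        got = dict(zip(table.labels, table.counts))
        assert got["pa|completed"] == 1
        assert got["pb|uncompleted"] == 1

    def test_empty_records_rejected(self):
        with pytest.raises(DegenerateInputError):
            criterion_counts([], 0.85, STATUSES)

    def test_sweep_monotone_and_consistent(self):
        sweep = threshold_sweep(RECORDS, [0.75, 0.80, 0.85], STATUSES)
        counts = [sweep[t].counts for t in (0.75, 0.80, 0.85)]
        for lo, hi in zip(counts, counts[1:]):
            assert all(h <= l for l, h in zip(lo, hi))
        single = criterion_counts(RECORDS, 0.85, STATUSES)
        assert sweep[0.85].counts == single.counts

    def test_unsorted_sweep_rejected(self):
        with pytest.raises(ValidationError):
            threshold_sweep(RECORDS, [0.85, 0.75], STATUSES)


class TestNormalization:
    def test_direct_division(self):
        table = CountTable(labels=["a", "b"], counts=[2, 4], totals=[4, 8])
        assert normalize_counts(table) == [0.5, 0.5]

    def test_printed_proportions(self):
        table = CountTable(
            labels=["c", "u", "i"], counts=[20, 28, 38], totals=[86, 86, 86]
        )
        props = normalize_counts(table)
        assert [round(p, 4) for p in props] == [0.2326, 0.3256, 0.4419]

    def test_zero_total_names_cell(self):
        table = CountTable(labels=["a", "b"], counts=[0, 1], totals=[0, 2])
        with pytest.raises(DegenerateInputError, match="'a'"):
            normalize_counts(table)


class TestAllocationTest:
    def test_statistic_from_allocation_counts(self):
        allocations = (
            [Allocation("r%d" % i, ExecutionStatus.COMPLETED, 0.9, False) for i in range(20)]
            + [Allocation("s%d" % i, ExecutionStatus.UNCOMPLETED, 0.9, False) for i in range(28)]
            + [Allocation("t%d" % i, ExecutionStatus.INTERRUPTED, 0.9, False) for i in range(38)]
        )
        res, table = allocation_test(allocations)
        assert res.statistic == pytest.approx(5.674418604651162, abs=1e-9)
        assert res.df == 2
        assert table.counts == [20, 28, 38]
        assert table.total == 86

    def test_total_concentration_statistic_2n(self):
        allocations = [
            Allocation("r%d" % i, ExecutionStatus.INTERRUPTED, 0.9, False)
            for i in range(30)
        ]
        res, _ = allocation_test(allocations)
        assert res.statistic == pytest.approx(60.0, abs=1e-12)

    def test_uniform_allocations_statistic_zero(self):
        allocations = [
            Allocation(f"r{i}{s.value}", s, 0.9, False)
            for i in range(7)
            for s in ExecutionStatus
        ]
        res, _ = allocation_test(allocations)
        assert res.statistic == 0.0

    def test_empty_rejected(self):
        with pytest.raises(DegenerateInputError):
            allocation_test([])


class TestRecallSummary:
    def test_reported_rates(self):
        summary = recall_summary(
            {"REM": 51, "N2": 35}, {"REM": 59, "N2": 58}
        )
        assert round(100 * summary.recall_rate, 1) == 73.5
        assert round(100 * summary.report_share_by_stage["REM"], 1) == 59.3

    def test_zero_reports(self):
        summary = recall_summary({"REM": 0, "N2": 0}, {"REM": 10, "N2": 10})
        assert summary.recall_rate == 0.0

    def test_more_reports_than_awakenings_rejected(self):
        with pytest.raises(ValidationError):
            recall_summary({"REM": 11}, {"REM": 10})


class TestWordCounts:
    def test_identical_groups_f_zero(self):
        res = word_count_summary({"a": [5, 5], "b": [5, 5], "c": [5, 5]})
        assert res.f_statistic == 0.0

    def test_matches_textbook_anova(self):
        rng = np.random.default_rng(1)
        groups = {k: list(rng.integers(50, 200, size=9)) for k in "abc"}
        res = word_count_summary(groups)
        # direct formula: F = MSbetween / MSwithin
        all_vals = np.concatenate([np.array(v, float) for v in groups.values()])
        grand = all_vals.mean()
        k, n = len(groups), len(all_vals)
        ssb = sum(len(v) * (np.mean(v) - grand) ** 2 for v in groups.values())
        ssw = sum(((np.array(v) - np.mean(v)) ** 2).sum() for v in groups.values())
        f_expected = (ssb / (k - 1)) / (ssw / (n - k))
        assert res.f_statistic == pytest.approx(f_expected, abs=1e-10)

    def test_single_group_rejected(self):
        with pytest.raises(DegenerateInputError):
            word_count_summary({"a": [1, 2]})


class TestScoreVariability:
    def test_all_equal_both_zero(self):
        records = [_rec(r, p, 0.5) for r in ("r1", "r2") for p in ("pa", "pb", "pc")]
        v = score_variability(records)
        assert v.within_report_variance == 0.0
        assert v.between_report_variance == 0.0

    def test_within_zero_between_positive(self):
        records = [_rec("r1", p, 0.4) for p in ("pa", "pb", "pc")] + [
            _rec("r2", p, 0.8) for p in ("pa", "pb", "pc")
        ]
        v = score_variability(records)
        assert v.within_report_variance == pytest.approx(0.0, abs=1e-15)
        assert v.between_report_variance > 0.0

    def test_matches_variance_formula(self):
        rng = np.random.default_rng(4)
        scores = {f"r{i}": rng.uniform(0, 1, size=3) for i in range(10)}
        records = [
            _rec(r, p, s)
            for r, vals in scores.items()
            for p, s in zip(("pa", "pb", "pc"), vals)
        ]
        v = score_variability(records)
        within = np.mean([np.var(vals, ddof=1) for vals in scores.values()])
        between = np.var([np.mean(vals) for vals in scores.values()], ddof=1)
        assert v.within_report_variance == pytest.approx(within, abs=1e-12)
        assert v.between_report_variance == pytest.approx(between, abs=1e-12)

    def test_single_report_rejected(self):
        with pytest.raises(DegenerateInputError):
            score_variability([_rec("r1", "pa", 0.5)])
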