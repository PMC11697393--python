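"""Count-based inference on incorporation scores.

The analysis counts, per execution status (and optionally per plan), the
reports whose maximum similarity score meets an inclusive criterion
threshold (default >= 0.85), and tests the resulting count vectors with
Pearson chi-square goodness-of-fit statistics against a uniform null
(df = k-1, upper-tail p, no continuity correction). Tests always run on
raw counts; per-cell normalization by the number of reports available in
each cell is provided for reporting and plotting only, since a
chi-square on proportions is not well-defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .errors import DegenerateInputError, ValidationError
from .similarity import Allocation, SentenceSimilarityRecord, SimilarityRecord
from .types import STATUS_ORDER, Corpus, ExecutionStatus, SleepStage


@dataclass
class CountTable:
    """Labelled non-negative integer counts, with optional per-cell
    denominators (the number of reports available in each cell)."""

    labels: list[str]
    counts: list[int]
    totals: list[int] | None = None
    name: str = "counts"

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.counts):
            raise ValidationError("labels and counts must have equal length")
        if any((int(c) != c or c < 0) for c in self.counts):
            raise ValidationError("counts must be non-negative integers")
        self.counts = [int(c) for c in self.counts]
        if self.totals is not None:
            if len(self.totals) != len(self.counts):
                raise ValidationError("totals must match counts in length")
            if any((int(t) != t or t < 0) for t in self.totals):
                raise ValidationError("totals must be non-negative integers")
            self.totals = [int(t) for t in self.totals]

    @property
    def total(self) -> int:
        return sum(self.counts)


@dataclass
class ChiSquareResult:
    """Pearson goodness-of-fit result (upper-tail p, df = k-1)."""

    statistic: float
    df: int
    p_value: float
    tail: str = "upper"
    labels: tuple[str, ...] = field(default_factory=tuple)


def chisq_gof(
    counts: CountTable | Sequence[int], null: str = "uniform"
) -> ChiSquareResult:
    """Pearson chi-square of observed counts against equal expected counts."""
    if null != "uniform":
        raise ValidationError(f"unsupported null {null!r}")
    if isinstance(counts, CountTable):
        labels = tuple(counts.labels)
        obs = np.asarray(counts.counts, dtype=float)
    else:
        obs = np.asarray(list(counts), dtype=float)
        labels = tuple(str(i) for i in range(len(obs)))
    if obs.size < 2:
        raise DegenerateInputError("need at least 2 categories")
    if obs.sum() <= 0:
        raise DegenerateInputError("total count is zero")
    stat, p = sps.chisquare(obs)
    return ChiSquareResult(
        statistic=float(stat), df=int(obs.size - 1), p_value=float(p), labels=labels
    )


def chisq_pairwise(
    counts: CountTable, bonferroni: bool = False
) -> list[ChiSquareResult]:
    """Each category pair as a 2-cell goodness-of-fit vs uniform.

    No multiplicity correction by default; ``bonferroni=True`` scales the
    p-values by the number of pairs (capped at 1).
    """
    k = len(counts.counts)
    if k < 3:
        raise DegenerateInputError("pairwise comparisons need >= 3 categories")
    pairs = [(i, j) for i in range(k) for j in range(i + 1, k)]
    results = []
    for i, j in pairs:
        r = chisq_gof([counts.counts[i], counts.counts[j]])
        p = min(1.0, r.p_value * len(pairs)) if bonferroni else r.p_value
        results.append(
            ChiSquareResult(
                statistic=r.statistic,
                df=r.df,
                p_value=p,
                labels=(counts.labels[i], counts.labels[j]),
            )
        )
    return results


AnyRecord = SimilarityRecord | SentenceSimilarityRecord
StatusIndex = Mapping[tuple[str, str], ExecutionStatus]


def criterion_counts(
    records: Iterable[AnyRecord],
    threshold: float,
    statuses: StatusIndex,
    group_by: str = "status",
    name: str | None = None,
    unit: str = "report",
) -> CountTable:
    """Count units with max_score >= threshold (inclusive) per group.

    ``statuses`` maps (report_id, plan_id) to the execution status of
    that plan for the report's participant (see
    :meth:`Corpus.status_index`). ``group_by`` is ``"status"`` or
    ``"status_x_plan"``. Totals carry the per-group unit counts used
    for normalization.

    ``unit="report"`` counts records whose overall maximum meets the
    criterion; ``unit="sentence"`` (sentence-wise records only) counts
    individual sentences whose best subtask score meets it, with
    sentence totals as denominators.
    """
    if not 0 < threshold <= 1:
        raise ValidationError("threshold must be in (0, 1]")
    records = list(records)
    if not records:
        raise DegenerateInputError("no similarity records to count")
    if group_by not in ("status", "status_x_plan"):
        raise ValidationError(f"unknown group_by {group_by!r}")
    if unit not in ("report", "sentence"):
        raise ValidationError(f"unknown counting unit {unit!r}")
    if unit == "sentence" and not all(
        isinstance(r, SentenceSimilarityRecord) for r in records
    ):
        raise ValidationError("sentence-unit counting needs sentence-wise records")

    def key(rec: AnyRecord):
        status = statuses[(rec.report_id, rec.plan_id)]
        if group_by == "status":
            return status.value
        return f"{rec.plan_id}|{status.value}"

    groups: dict[str, list[AnyRecord]] = {}
    for rec in records:
        groups.setdefault(key(rec), []).append(rec)

    if group_by == "status":
        labels = [s.value for s in STATUS_ORDER if s.value in groups]
    else:
        labels = sorted(groups)
    if unit == "report":
        counts = [sum(r.max_score >= threshold for r in groups[g]) for g in labels]
        totals = [len(groups[g]) for g in labels]
    else:
        counts = [
            int(sum((r.matrix.max(axis=1) >= threshold).sum() for r in groups[g]))
            for g in labels
        ]
        totals = [
            int(sum(r.matrix.shape[0] for r in groups[g])) for g in labels
        ]
    return CountTable(
        labels=labels,
        counts=counts,
        totals=totals,
        name=name or f"criterion_counts(threshold={threshold})",
    )


def normalize_counts(table: CountTable) -> list[float]:
    """Per-cell proportion count/total, for reporting only."""
    if table.totals is None:
        raise ValidationError("normalization requires per-cell totals")
    props = []
    for label, count, total in zip(table.labels, table.counts, table.totals):
        if total <= 0:
            raise DegenerateInputError(
                f"cell {label!r}: proportion undefined with zero total"
            )
        props.append(count / total)
    return props


def threshold_sweep(
    records: Iterable[AnyRecord],
    thresholds: Sequence[float],
    statuses: StatusIndex,
    group_by: str = "status",
    unit: str = "report",
) -> dict[float, CountTable]:
    """criterion_counts at each threshold of an ascending sweep."""
    thresholds = list(thresholds)
    if sorted(thresholds) != thresholds:
        raise ValidationError("thresholds must be sorted ascending")
    records = list(records)
    return {
        t: criterion_counts(records, t, statuses, group_by=group_by, unit=unit)
        for t in thresholds
    }


def allocation_test(
    allocations: Sequence[Allocation],
) -> tuple[ChiSquareResult, CountTable]:
    """Counts of forced-choice allocations per status + GOF vs uniform."""
    if not allocations:
        raise DegenerateInputError("no allocations to test")
    counts = {s: 0 for s in STATUS_ORDER}
    for a in allocations:
        counts[a.chosen_status] += 1
    table = CountTable(
        labels=[s.value for s in STATUS_ORDER],
        counts=[counts[s] for s in STATUS_ORDER],
        name="forced_choice_allocations",
    )
    return chisq_gof(table), table


@dataclass
class RecallSummary:
    """Dream-recall bookkeeping across awakenings and sleep stages."""

    n_awakenings: int
    n_reports: int
    recall_rate: float  # fraction of awakenings with recall
    recall_rate_by_stage: dict[str, float]
    report_share_by_stage: dict[str, float]  # fraction of reports per stage


def recall_summary(
    reports_by_stage: Mapping[str, int] | Corpus,
    awakenings_by_stage: Mapping[str, int],
) -> RecallSummary:
    """Recall rate overall and per stage, and each stage's report share."""
    if isinstance(reports_by_stage, Corpus):
        tallies: dict[str, int] = {s.value: 0 for s in SleepStage}
        for r in reports_by_stage.reports:
            tallies[r.sleep_stage.value] += 1
        reports_by_stage = tallies
    reports = {str(k): int(v) for k, v in reports_by_stage.items()}
    awakenings = {str(k): int(v) for k, v in awakenings_by_stage.items()}
    for stage, n in reports.items():
        if n > awakenings.get(stage, 0):
            raise ValidationError(
                f"stage {stage}: {n} reports exceed "
                f"{awakenings.get(stage, 0)} awakenings"
            )
    n_awake = sum(awakenings.values())
    n_rep = sum(reports.values())
    if n_awake <= 0:
        raise ValidationError("no awakenings recorded")
    return RecallSummary(
        n_awakenings=n_awake,
        n_reports=n_rep,
        recall_rate=n_rep / n_awake,
        recall_rate_by_stage={
            s: (reports.get(s, 0) / a if a else 0.0) for s, a in awakenings.items()
        },
        report_share_by_stage={
            s: (n / n_rep if n_rep else 0.0) for s, n in reports.items()
        },
    )


@dataclass
class WordCountSummary:
    group_means: dict[str, float]
    f_statistic: float
    p_value: float


def word_count_summary(
    word_counts_by_group: Mapping[str, Sequence[int]],
) -> WordCountSummary:
    """Descriptive group means plus a one-way ANOVA (delegated to scipy)."""
    groups = {str(k): list(v) for k, v in word_counts_by_group.items()}
    if len(groups) < 2:
        raise DegenerateInputError("ANOVA needs at least 2 groups")
    if any(len(v) == 0 for v in groups.values()):
        raise DegenerateInputError("empty group in word-count summary")
    arrays = [np.asarray(v, dtype=float) for v in groups.values()]
    if np.ptp(np.concatenate(arrays)) == 0:
        f, p = 0.0, 1.0  # zero variance everywhere: F defined as 0
    else:
        f, p = sps.f_oneway(*arrays)
    return WordCountSummary(
        group_means={k: float(np.mean(v)) for k, v in groups.items()},
        f_statistic=float(f),
        p_value=float(p),
    )


@dataclass
class ScoreVariability:
    """Within-report (across the 3 plans) vs between-report score spread."""

    within_report_variance: float
    between_report_variance: float
    ratio: float  # within / between


def score_variability(records: Iterable[AnyRecord]) -> ScoreVariability:
    """Mean within-report variance of the 3 plan scores vs variance of
    plan-averaged scores across reports (sample variances, ddof=1)."""
    by_report: dict[str, list[float]] = {}
    for rec in records:
        by_report.setdefault(rec.report_id, []).append(rec.max_score)
    if len(by_report) < 2:
        raise DegenerateInputError("variance comparison needs >= 2 reports")
    within = float(
        np.mean([np.var(v, ddof=1) for v in by_report.values() if len(v) > 1])
    )
    means = np.array([np.mean(v) for v in by_report.values()])
    between = float(np.var(means, ddof=1))
    ratio = within / between if between > 0 else float("inf") if within > 0 else 0.0
    return ScoreVariability(
        within_report_variance=within,
        between_report_variance=between,
        ratio=ratio,
    )
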