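"""Cosine-similarity scoring of dream reports against task plans.

Two analysis branches mirror the study design:

* whole-text: the (optionally summarized) report is embedded once and
  compared with each of a plan's five subtask embeddings; the per-plan
  score is the maximum over subtasks.
* sentence-wise: every report sentence is compared with every subtask
  (no summarization); the per-plan score is the maximum over the
  sentence x subtask matrix. Forced-choice allocation then assigns the
  report to the execution status whose plan wins.

This module emits raw scores only; all criterion thresholding lives in
:mod:`dreamincorp.stats`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .embed import (
    EmbedderSpec,
    EmbeddingVector,
    HashedBowEmbedder,
    SummarizerSpec,
    make_embedder,
    summarize,
)
from .errors import DegenerateInputError, UndefinedSimilarityError
from .textprep import plan_to_sentences, split_sentences
from .types import (
    TIE_PRIORITY,
    DreamReport,
    ExecutionStatus,
    StatusAssignment,
    TaskPlan,
)

#: Two scores closer than this are an exact tie for forced choice.
TIE_TOLERANCE = 1e-12


def cosine(a: EmbeddingVector | np.ndarray, b: EmbeddingVector | np.ndarray) -> float:
    """Cosine of the angle between two vectors, in [-1, 1]."""
    va = a.values if isinstance(a, EmbeddingVector) else np.asarray(a, dtype=float)
    vb = b.values if isinstance(b, EmbeddingVector) else np.asarray(b, dtype=float)
    if va.shape != vb.shape:
        raise UndefinedSimilarityError(
            f"dimension mismatch: {va.shape} vs {vb.shape}"
        )
    na = np.linalg.norm(va)
    nb = np.linalg.norm(vb)
    if na == 0.0 or nb == 0.0:
        raise UndefinedSimilarityError("cosine undefined for the zero vector")
    return float(np.clip(np.dot(va, vb) / (na * nb), -1.0, 1.0))


@dataclass
class SimilarityRecord:
    """Whole-text scores of one report against one plan's five subtasks."""

    report_id: str
    plan_id: str
    subtask_scores: list[float]
    max_score: float

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.subtask_scores)):
            raise UndefinedSimilarityError(
                f"non-finite score for report {self.report_id}, plan {self.plan_id}"
            )
        expected = float(max(self.subtask_scores))
        if abs(self.max_score - expected) > 0:
            raise UndefinedSimilarityError(
                "max_score must equal the maximum subtask score"
            )


@dataclass
class SentenceSimilarityRecord:
    """Sentence x subtask score matrix of one report against one plan."""

    report_id: str
    plan_id: str
    matrix: np.ndarray  # (n_sentences, 5)
    max_score: float

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if not np.all(np.isfinite(self.matrix)):
            raise UndefinedSimilarityError(
                f"non-finite score for report {self.report_id}, plan {self.plan_id}"
            )
        if abs(self.max_score - float(self.matrix.max())) > 0:
            raise UndefinedSimilarityError(
                "max_score must equal the global matrix maximum"
            )


@dataclass
class Allocation:
    """Forced-choice outcome for one report."""

    report_id: str
    chosen_status: ExecutionStatus
    winning_score: float
    tie_flag: bool


def _resolve_embedder(embedder):
    if embedder is None or isinstance(embedder, EmbedderSpec):
        return make_embedder(embedder)
    return embedder


def score_report_whole(
    report: DreamReport,
    plans: list[TaskPlan],
    embedder: EmbedderSpec | HashedBowEmbedder | None = None,
    summarizer: SummarizerSpec | None = None,
) -> list[SimilarityRecord]:
    """Whole-text branch: summarize (optional), embed the report once,
    score it against each subtask of each plan, take per-plan maxima."""
    emb = _resolve_embedder(embedder)
    text = summarize(report.text, summarizer)
    report_vec = emb.embed(text)
    records = []
    for plan in plans:
        rendered = plan_to_sentences(plan)
        scores = [cosine(report_vec, emb.embed(s)) for s in rendered.sentences]
        records.append(
            SimilarityRecord(
                report_id=report.report_id,
                plan_id=plan.plan_id,
                subtask_scores=scores,
                max_score=float(max(scores)),
            )
        )
    return records


def score_report_sentences(
    report: DreamReport,
    plans: list[TaskPlan],
    embedder: EmbedderSpec | HashedBowEmbedder | None = None,
) -> list[SentenceSimilarityRecord]:
    """Sentence-wise branch: every report sentence against every subtask,
    no summarization."""
    emb = _resolve_embedder(embedder)
    sentences = report.sentences
    if not sentences:
        sentences = split_sentences(report.text)
    sent_vecs = [emb.embed(s) for s in sentences]
    records = []
    for plan in plans:
        rendered = plan_to_sentences(plan)
        sub_vecs = [emb.embed(s) for s in rendered.sentences]
        matrix = np.array(
            [[cosine(sv, pv) for pv in sub_vecs] for sv in sent_vecs]
        )
        records.append(
            SentenceSimilarityRecord(
                report_id=report.report_id,
                plan_id=plan.plan_id,
                matrix=matrix,
                max_score=float(matrix.max()),
            )
        )
    return records


def allocate_forced_choice(
    records: list[SentenceSimilarityRecord] | list[SimilarityRecord],
    assignment: StatusAssignment,
) -> Allocation:
    """Assign the report to the status whose plan scores highest.

    Ties (scores within :data:`TIE_TOLERANCE`) are flagged and resolved
    by a fixed priority in which the completed condition wins, so a tie
    never manufactures evidence for preferential incorporation of
    uncompleted/interrupted plans.
    """
    if len(records) != 3:
        raise DegenerateInputError(
            f"forced choice needs the participant's 3 plan records, got "
            f"{len(records)}"
        )
    report_ids = {r.report_id for r in records}
    if len(report_ids) != 1:
        raise DegenerateInputError("records must belong to a single report")
    by_status: dict[ExecutionStatus, float] = {}
    for rec in records:
        by_status[assignment.status_of(rec.plan_id)] = rec.max_score
    if len(by_status) != 3:
        raise DegenerateInputError(
            "records must cover the participant's three statuses"
        )
    best = max(by_status.values())
    candidates = [s for s, v in by_status.items() if best - v < TIE_TOLERANCE]
    tie = len(candidates) > 1
    chosen = next(s for s in TIE_PRIORITY if s in candidates)
    return Allocation(
        report_id=next(iter(report_ids)),
        chosen_status=chosen,
        winning_score=best,
        tie_flag=tie,
    )
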