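"""Synthetic corpora with planted incorporation structure.

The generator emulates the statistical skeleton of the study: ~19
participants each learn 3 task plans assigned (balanced across
participants) to the completed / uncompleted / interrupted statuses,
sleep through 4-6 awakenings, and recall a dream on ~73.5% of them.
Each report sentence independently "incorporates" a plan with a
status-dependent rate (defaults 0.10 completed, 0.30 uncompleted and
interrupted — the hypothesized direction), replacing a fraction of its
tokens with tokens from that plan's vocabulary.

Text is token-level, not grammatical: plan vocabularies are pairwise
disjoint by default (an ``plan_vocab_overlap`` knob can blur them to
reproduce the real materials' too-similar-plans failure mode), and
sentences are strings of synthetic tokens. That is sufficient for the
bag-of-words test embedder and exercises every pipeline contract;
it does not emulate narrative structure, grammar, or REM/N2 content
differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations

import numpy as np

from .errors import BackendError, ValidationError
from .embed import EmbedderSpec
from .types import (
    STATUS_ORDER,
    Corpus,
    DreamReport,
    ExecutionStatus,
    SleepStage,
    StatusAssignment,
    TaskPlan,
)

PLAN_IDS = ("plan_a", "plan_b", "plan_c")
PLAN_TITLES = ("Sorting the workshop", "Packing for a trip", "Preparing a meal")


def _default_rates() -> dict[ExecutionStatus, float]:
    return {
        ExecutionStatus.COMPLETED: 0.10,
        ExecutionStatus.UNCOMPLETED: 0.30,
        ExecutionStatus.INTERRUPTED: 0.30,
    }


@dataclass
class GeneratorConfig:
    """Study-condition parameters of the synthetic corpus.

    Defaults reflect the emulated study: 19 participants, 4-6
    awakenings each, 73.5% recall, awakenings split evenly between REM
    and N2, reports of 3-10 sentences, and incorporation rates of 0.10
    for the completed plan vs 0.30 for the uncompleted and interrupted
    plans. ``mixing_rate`` is the fraction of tokens an incorporating
    sentence borrows from the plan vocabulary.
    """

    n_participants: int = 19
    awakenings_per_participant: tuple[int, int] = (4, 6)
    recall_probability: float = 0.735
    rem_fraction: float = 0.5
    sentences_per_report: tuple[int, int] = (3, 10)
    incorporation_rates: dict[ExecutionStatus, float] = field(
        default_factory=_default_rates
    )
    mixing_rate: float = 0.5
    vocab_size_per_plan: int = 40
    background_vocab_size: int = 400
    tokens_per_sentence: tuple[int, int] = (6, 12)
    plan_vocab_overlap: float = 0.0
    filler_probability: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        self.incorporation_rates = {
            ExecutionStatus(k): float(v) for k, v in self.incorporation_rates.items()
        }
        probs = [
            self.recall_probability,
            self.rem_fraction,
            self.mixing_rate,
            self.plan_vocab_overlap,
            self.filler_probability,
            *self.incorporation_rates.values(),
        ]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValidationError("probabilities must lie in [0, 1]")
        if self.mixing_rate <= 0.0:
            raise ValidationError("mixing_rate must be in (0, 1]")
        if self.n_participants < 1:
            raise ValidationError("n_participants must be positive")
        for lo, hi in (
            self.awakenings_per_participant,
            self.sentences_per_report,
            self.tokens_per_sentence,
        ):
            if lo < 1 or hi < lo:
                raise ValidationError(f"invalid range ({lo}, {hi})")
        if self.vocab_size_per_plan < 1 or self.background_vocab_size < 1:
            raise ValidationError("vocabulary sizes must be positive")
        if set(self.incorporation_rates) != set(ExecutionStatus):
            raise ValidationError("incorporation_rates must cover all 3 statuses")


@dataclass
class GroundTruth:
    """Which sentences of which reports incorporate which plan."""

    # report_id -> list of (sentence_index, plan_id)
    incorporations: dict[str, list[tuple[int, str]]]
    assignments: list[StatusAssignment]
    # every performed awakening, recalled or not, per sleep stage
    awakenings_by_stage: dict[str, int] = field(
        default_factory=lambda: {s.value: 0 for s in SleepStage}
    )


_FILLERS = ("ähm", "äh", "halt", "mhm")


def _plan_vocabularies(config: GeneratorConfig, rng: np.random.Generator):
    vocabs = {}
    for k, pid in enumerate(PLAN_IDS):
        vocabs[pid] = [f"{pid}tok{i}" for i in range(config.vocab_size_per_plan)]
    if config.plan_vocab_overlap > 0:
        # blur plan vocabularies: each plan replaces a fraction of its
        # tokens with tokens shared across all plans
        n_shared = int(round(config.plan_vocab_overlap * config.vocab_size_per_plan))
        shared = [f"sharedtok{i}" for i in range(n_shared)]
        for pid in PLAN_IDS:
            for i in range(n_shared):
                vocabs[pid][i] = shared[i]
    background = [f"szene{i}" for i in range(config.background_vocab_size)]
    return vocabs, background


def _make_plans(vocabs: dict[str, list[str]], rng: np.random.Generator) -> list[TaskPlan]:
    plans = []
    for pid, title in zip(PLAN_IDS, PLAN_TITLES):
        subtasks = []
        for _ in range(5):
            toks = rng.choice(vocabs[pid], size=6, replace=False)
            subtasks.append(" ".join(toks).capitalize() + ".")
        plans.append(TaskPlan(plan_id=pid, title=title, subtasks=subtasks))
    return plans


def generate_corpus(config: GeneratorConfig) -> tuple[Corpus, GroundTruth]:
    """Draw a corpus; byte-identical for identical config and seed."""
    rng = np.random.default_rng(config.seed)
    vocabs, background = _plan_vocabularies(config, rng)
    plans = _make_plans(vocabs, rng)

    # balanced plan->status assignment: cycle through the 6 bijections
    perms = list(permutations(STATUS_ORDER))
    assignments = []
    for p in range(config.n_participants):
        mapping = dict(zip(PLAN_IDS, perms[p % len(perms)]))
        assignments.append(
            StatusAssignment(participant_id=f"p{p:03d}", mapping=mapping)
        )

    reports: list[DreamReport] = []
    incorporations: dict[str, list[tuple[int, str]]] = {}
    awakening_log = {s.value: 0 for s in SleepStage}
    lo_a, hi_a = config.awakenings_per_participant
    lo_s, hi_s = config.sentences_per_report
    lo_t, hi_t = config.tokens_per_sentence
    for assignment in assignments:
        n_awakenings = int(rng.integers(lo_a, hi_a + 1))
        for awakening in range(1, n_awakenings + 1):
            stage = (
                SleepStage.REM
                if rng.random() < config.rem_fraction
                else SleepStage.N2
            )
            awakening_log[stage.value] += 1
            if rng.random() >= config.recall_probability:
                continue  # awakening without dream recall
            report_id = f"{assignment.participant_id}_a{awakening}"
            n_sentences = int(rng.integers(lo_s, hi_s + 1))
            sentences = []
            marks: list[tuple[int, str]] = []
            for s in range(n_sentences):
                n_tokens = int(rng.integers(lo_t, hi_t + 1))
                tokens = list(rng.choice(background, size=n_tokens, replace=True))
                # each plan may independently fire; one incorporation per
                # sentence, chosen uniformly among those that fired
                fired = [
                    pid
                    for pid in PLAN_IDS
                    if rng.random()
                    < config.incorporation_rates[assignment.status_of(pid)]
                ]
                if fired:
                    pid = fired[int(rng.integers(len(fired)))] if len(fired) > 1 else fired[0]
                    n_borrow = max(1, int(round(config.mixing_rate * n_tokens)))
                    positions = rng.choice(n_tokens, size=n_borrow, replace=False)
                    borrowed = rng.choice(vocabs[pid], size=n_borrow, replace=True)
                    for pos, tok in zip(positions, borrowed):
                        tokens[pos] = tok
                    marks.append((s, pid))
                if rng.random() < config.filler_probability:
                    tokens.insert(0, _FILLERS[int(rng.integers(len(_FILLERS)))])
                sentences.append(" ".join(tokens).capitalize() + ".")
            reports.append(
                DreamReport(
                    report_id=report_id,
                    participant_id=assignment.participant_id,
                    awakening_index=awakening,
                    sleep_stage=stage,
                    raw_text=" ".join(sentences),
                )
            )
            incorporations[report_id] = marks

    corpus = Corpus(reports=reports, plans=plans, assignments=assignments)
    truth = GroundTruth(
        incorporations=incorporations,
        assignments=assignments,
        awakenings_by_stage=awakening_log,
    )
    return corpus, truth


@dataclass
class PredictedOrdering:
    """Statuses grouped by predicted mean max-score, descending; a single
    group of all three statuses means no predicted ordering."""

    groups: list[list[ExecutionStatus]]


def expected_separation(
    config: GeneratorConfig, embedder: EmbedderSpec
) -> PredictedOrdering:
    """Analytic direction of the planted effect under the test backend.

    A higher per-sentence incorporation rate yields stochastically more
    incorporating sentences, hence a stochastically larger maximum
    cosine against the corresponding plan; the predicted ordering of
    mean max-scores is therefore the ordering of the rates.
    """
    if embedder.backend != "hashed_bow_test":
        raise BackendError(
            "expected_separation is an oracle for the hashed_bow_test backend"
        )
    rates = config.incorporation_rates
    groups: list[list[ExecutionStatus]] = []
    for rate in sorted({float(r) for r in rates.values()}, reverse=True):
        groups.append(
            [s for s in STATUS_ORDER if float(rates[s]) == rate]
        )
    return PredictedOrdering(groups=groups)


def corpus_from_count_matrix(
    matrix: dict[str, dict[ExecutionStatus, int]],
    plans: list[TaskPlan] | None = None,
) -> Corpus:
    """Build a corpus whose per-(plan, status) report counts reproduce a
    printed count matrix.

    Works whenever the matrix has equal row and column sums (each report
    appears once per plan row, under the status its participant's
    bijection assigns): the matrix then decomposes into permutation
    matrices (integral Birkhoff-von Neumann), each giving a batch of
    single-report participants sharing one plan->status bijection.
    """
    plan_ids = list(matrix)
    if len(plan_ids) != 3:
        raise ValidationError("count matrix must cover exactly 3 plans")
    remaining = {
        p: {ExecutionStatus(s): int(c) for s, c in row.items()}
        for p, row in matrix.items()
    }
    row_sums = {p: sum(row.values()) for p, row in remaining.items()}
    col_sums = {
        s: sum(remaining[p][s] for p in plan_ids) for s in ExecutionStatus
    }
    n = next(iter(row_sums.values()))
    if set(row_sums.values()) != {n} or set(col_sums.values()) != {n}:
        raise ValidationError(
            "count matrix must have equal row and column sums (each report "
            "contributes one cell per plan)"
        )
    if plans is None:
        plans = [
            TaskPlan(
                plan_id=p,
                title=p,
                subtasks=[f"{p} step {i}." for i in range(1, 6)],
            )
            for p in plan_ids
        ]

    assignments: list[StatusAssignment] = []
    reports: list[DreamReport] = []
    batch = 0
    while any(remaining[p][s] for p in plan_ids for s in ExecutionStatus):
        perm = next(
            (
                perm
                for perm in permutations(ExecutionStatus)
                if all(remaining[p][s] > 0 for p, s in zip(plan_ids, perm))
            ),
            None,
        )
        if perm is None:  # cannot happen for a doubly balanced matrix
            raise ValidationError("count matrix is not decomposable")
        take = min(remaining[p][s] for p, s in zip(plan_ids, perm))
        for i in range(take):
            pid = f"fx{batch:02d}_{i:03d}"
            assignments.append(
                StatusAssignment(
                    participant_id=pid, mapping=dict(zip(plan_ids, perm))
                )
            )
            reports.append(
                DreamReport(
                    report_id=f"r_{pid}",
                    participant_id=pid,
                    awakening_index=1,
                    sleep_stage=SleepStage.REM,
                    raw_text="Platzhaltertraum ohne Inhalt.",
                )
            )
        for p, s in zip(plan_ids, perm):
            remaining[p][s] -= take
        batch += 1
    return Corpus(reports=reports, plans=plans, assignments=assignments)
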