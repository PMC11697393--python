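"""Cosine scoring, maxima, and forced-choice allocation."""

import math

import numpy as np
import pytest

from dreamincorp.embed import EmbedderSpec, make_embedder
from dreamincorp.errors import DegenerateInputError, UndefinedSimilarityError
from dreamincorp.similarity import (
    SentenceSimilarityRecord,
    allocate_forced_choice,
    cosine,
    score_report_sentences,
    score_report_whole,
)
from dreamincorp.types import DreamReport, ExecutionStatus, SleepStage


class TestCosine:
    def test_self_similarity_is_one(self):
        v = np.array([0.3, -1.2, 4.0])
        assert cosine(v, v) == pytest.approx(1.0, abs=1e-15)

    def test_orthogonal_is_zero(self):
        assert cosine(np.array([1.0, 0.0]), np.array([0.0, 1.0])) == 0.0

    def test_formula_oracle(self):
        assert cosine(np.array([1.0, 0.0]), np.array([1.0, 1.0])) == pytest.approx(
            1 / math.sqrt(2), abs=1e-12
        )

    def test_scale_invariant_and_symmetric(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(size=8), rng.normal(size=8)
        assert cosine(a, b) == pytest.approx(cosine(b, a), abs=1e-15)
        assert cosine(3.7 * a, b) == pytest.approx(cosine(a, b), abs=1e-12)

    def test_zero_vector_rejected(self):
        with pytest.raises(UndefinedSimilarityError):
            cosine(np.zeros(3), np.ones(3))

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(UndefinedSimilarityError):
            cosine(np.ones(3), np.ones(4))


class TestWholeTextScoring:
    def test_report_equal_to_subtask_scores_one(self, plans, embedder_spec):
        report = DreamReport(
            report_id="r",
            participant_id="p1",
            awakening_index=1,
            sleep_stage=SleepStage.REM,
            raw_text=plans[1].subtasks[2],
        )
        records = score_report_whole(report, plans, embedder_spec)
        by_plan = {r.plan_id: r for r in records}
        assert by_plan["plan_b"].max_score == pytest.approx(1.0, abs=1e-12)
        assert by_plan["plan_b"].subtask_scores[2] == pytest.approx(1.0, abs=1e-12)

    def test_one_record_per_plan_with_five_scores(self, plans, embedder_spec):
        report = DreamReport(
            report_id="r",
            participant_id="p1",
            awakening_index=1,
            sleep_stage=SleepStage.REM,
            raw_text="Ein ganz anderer Traum von etwas Fremdem.",
        )
        records = score_report_whole(report, plans, embedder_spec)
        assert [r.plan_id for r in records] == [p.plan_id for p in plans]
        assert all(len(r.subtask_scores) == 5 for r in records)
        assert all(r.max_score == max(r.subtask_scores) for r in records)

    def test_unrelated_report_scores_near_zero(self, plans):
        report = DreamReport(
            report_id="r",
            participant_id="p1",
            awakening_index=1,
            sleep_stage=SleepStage.REM,
            raw_text=" ".join(f"fremdwort{i}" for i in range(30)),
        )
        sims = []
        for seed in range(50):
            spec = EmbedderSpec(dimension=2048, seed=seed)
            records = score_report_whole(report, plans, spec)
            sims.extend(s for r in records for s in r.subtask_scores)
        assert abs(np.mean(sims)) < 0.02


class TestSentenceScoring:
    def test_matrix_shape_and_max(self, plans, embedder_spec):
        report = DreamReport(
            report_id="r",
            participant_id="p1",
            awakening_index=1,
            sleep_stage=SleepStage.REM,
            raw_text="Erster Satz vom Traum. " + plans[1].subtasks[1] + " Noch ein Satz dazu.",
        )
        records = score_report_sentences(report, plans, embedder_spec)
        by_plan = {r.plan_id: r for r in records}
        assert by_plan["plan_b"].matrix.shape == (3, 5)
        assert by_plan["plan_b"].matrix[1, 1] == pytest.approx(1.0, abs=1e-12)
        assert by_plan["plan_b"].max_score == pytest.approx(1.0, abs=1e-12)

    def test_single_sentence_report_degenerates_to_whole_text(
        self, plans, embedder_spec
    ):
        report = DreamReport(
            report_id="r",
            participant_id="p1",
            awakening_index=1,
            sleep_stage=SleepStage.REM,
            raw_text="Nur ein einziger Satz im Traum.",
        )
        sent = score_report_sentences(report, plans, embedder_spec)
        whole = score_report_whole(report, plans, embedder_spec)
        for s, w in zip(sent, whole):
            assert s.matrix.shape == (1, 5)
            np.testing.assert_allclose(s.matrix[0], w.subtask_scores, atol=1e-12)

    def test_max_matches_brute_force_over_all_pairs(self, plans, embedder_spec):
        rng = np.random.default_rng(5)
        emb = make_embedder(embedder_spec)
        from dreamincorp.textprep import plan_to_sentences

        vocab = [f"w{i}" for i in range(40)] + [
            t for p in plans for s in p.subtasks for t in s.lower().split()
        ]
        for trial in range(20):
            n_sent = int(rng.integers(1, 8))
            sentences = [
                " ".join(rng.choice(vocab, size=rng.integers(3, 9)))
                for _ in range(n_sent)
            ]
            report = DreamReport(
                report_id=f"r{trial}",
                participant_id="p1",
                awakening_index=1,
                sleep_stage=SleepStage.REM,
                raw_text=" ".join(s + "." for s in sentences),
                cleaned_text=" ".join(s + "." for s in sentences),
                sentences=[s + "." for s in sentences],
            )
            records = score_report_sentences(report, plans, emb)
            for rec, plan in zip(records, plans):
                subs = plan_to_sentences(plan).sentences
                brute = max(
                    cosine(emb.embed(s), emb.embed(t))
                    for s in report.sentences
                    for t in subs
                )
                assert rec.max_score == pytest.approx(brute, abs=1e-12)

    def test_subtask_permutation_only_moves_argmax(self, plans, embedder_spec):
        report = DreamReport(
            report_id="r",
            participant_id="p1",
            awakening_index=1,
            sleep_stage=SleepStage.REM,
            raw_text=plans[0].subtasks[0] + " Und etwas anderes danach.",
        )
        base = score_report_sentences(report, plans, embedder_spec)[0]
        shuffled = plans[0].subtasks[::-1]
        from dreamincorp.types import TaskPlan

        plan_rev = TaskPlan(plan_id="plan_a", title=plans[0].title, subtasks=shuffled)
        rev = score_report_sentences(report, [plan_rev], embedder_spec)[0]
        assert rev.max_score == pytest.approx(base.max_score, abs=1e-12)
        np.testing.assert_allclose(
            np.sort(rev.matrix, axis=1), np.sort(base.matrix, axis=1), atol=1e-12
        )


def _simple_record(report_id, plan_id, score):
    m = np.full((1, 5), -1.0)
    m[0, 0] = score
    return SentenceSimilarityRecord(
        report_id=report_id, plan_id=plan_id, matrix=m, max_score=score
    )


class TestForcedChoice:
    def test_argmax_wins(self, assignment):
        records = [
            _simple_record("r", "plan_a", 0.9),  # completed
            _simple_record("r", "plan_b", 0.8),  # uncompleted
            _simple_record("r", "plan_c", 0.7),  # interrupted
        ]
        alloc = allocate_forced_choice(records, assignment)
        assert alloc.chosen_status == ExecutionStatus.COMPLETED
        assert alloc.winning_score == pytest.approx(0.9)
        assert not alloc.tie_flag

    def test_tie_resolves_to_completed_and_is_flagged(self, assignment):
        records = [
            _simple_record("r", "plan_a", 0.8),  # completed
            _simple_record("r", "plan_b", 0.8),  # uncompleted
            _simple_record("r", "plan_c", 0.5),  # interrupted
        ]
        alloc = allocate_forced_choice(records, assignment)
        assert alloc.chosen_status == ExecutionStatus.COMPLETED
        assert alloc.tie_flag

    def test_uncompleted_interrupted_tie_resolves_to_interrupted(self, assignment):
        records = [
            _simple_record("r", "plan_a", 0.2),  # completed
            _simple_record("r", "plan_b", 0.8),  # uncompleted
            _simple_record("r", "plan_c", 0.8),  # interrupted
        ]
        alloc = allocate_forced_choice(records, assignment)
        assert alloc.chosen_status == ExecutionStatus.INTERRUPTED
        assert alloc.tie_flag

    def test_incomplete_record_set_rejected(self, assignment):
        with pytest.raises(DegenerateInputError):
            allocate_forced_choice(
                [_simple_record("r", "plan_a", 0.5)], assignment
            )

    def test_allocations_partition_synthetic_corpus(self, synthetic_corpus):
        from dreamincorp.pipeline import RunConfig, analyze_corpus

        corpus, _ = synthetic_corpus
        result = analyze_corpus(corpus, RunConfig())
        assert len(result.allocations) == len(corpus.reports)
        assert result.allocation_counts.total == len(corpus.reports)
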