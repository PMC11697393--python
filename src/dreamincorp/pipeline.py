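"""End-to-end orchestration: prepare -> embed -> score -> count -> test.

`analyze_corpus` is the in-memory workhorse; `run_pipeline` wraps it
with file I/O, a plain-text run log, and a JSON manifest so every
reported statistic can be re-derived from the written score tables.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as corpus_io
from .embed import EmbedderSpec, SummarizerSpec, make_embedder, tokenize
from .errors import DegenerateInputError, ValidationError
from .similarity import (
    Allocation,
    SentenceSimilarityRecord,
    SimilarityRecord,
    allocate_forced_choice,
    score_report_sentences,
    score_report_whole,
)
from .stats import (
    ChiSquareResult,
    CountTable,
    allocation_test,
    chisq_gof,
    chisq_pairwise,
    criterion_counts,
    normalize_counts,
    score_variability,
    threshold_sweep,
    word_count_summary,
)
from .textprep import CleaningConfig, clean_transcript, split_sentences
from .types import Corpus

DEFAULT_THRESHOLD = 0.85
DEFAULT_SWEEP = (0.75, 0.80, 0.85)


@dataclass
class RunConfig:
    """Everything a pipeline run depends on, schema-validated up front."""

    corpus_path: str | None = None
    corpus_format: str = "json_lines"
    cleaning: CleaningConfig = field(default_factory=CleaningConfig)
    embedder: EmbedderSpec = field(default_factory=EmbedderSpec)
    summarizer: SummarizerSpec = field(default_factory=SummarizerSpec)
    threshold: float = DEFAULT_THRESHOLD
    sweep: tuple[float, ...] = DEFAULT_SWEEP
    counting_unit: str = "report"
    output_dir: str = "results"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.threshold <= 1:
            raise ValidationError("threshold must be in (0, 1]")
        if list(self.sweep) != sorted(self.sweep):
            raise ValidationError("threshold sweep must be ascending")
        if self.counting_unit not in ("report", "sentence"):
            raise ValidationError(f"unknown counting unit {self.counting_unit!r}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text("utf-8")) or {}
        raw.update(overrides)
        if "cleaning" in raw and isinstance(raw["cleaning"], dict):
            c = dict(raw["cleaning"])
            if "filler_lexicon" in c:
                c["filler_lexicon"] = frozenset(c["filler_lexicon"])
            raw["cleaning"] = CleaningConfig(**c)
        if "embedder" in raw and isinstance(raw["embedder"], dict):
            raw["embedder"] = EmbedderSpec(**raw["embedder"])
        if "summarizer" in raw and isinstance(raw["summarizer"], dict):
            raw["summarizer"] = SummarizerSpec(**raw["summarizer"])
        if "sweep" in raw:
            raw["sweep"] = tuple(float(t) for t in raw["sweep"])
        return cls(**raw)

    def digest(self) -> str:
        blob = repr(self).encode("utf-8")
        return hashlib.sha256(blob).hexdigest()[:16]


def prepare_corpus(corpus: Corpus, cleaning: CleaningConfig | None = None) -> Corpus:
    """Fill cleaned_text and sentences on every report (in place)."""
    cleaning = cleaning or CleaningConfig()
    for r in corpus.reports:
        r.cleaned_text = clean_transcript(r.raw_text, cleaning)
        r.sentences = split_sentences(r.cleaned_text)
    return corpus


@dataclass
class AnalysisResult:
    """Full audit trail of one pipeline run."""

    whole_records: list[SimilarityRecord]
    sentence_records: list[SentenceSimilarityRecord]
    criterion_table: CountTable | None
    criterion_by_plan: CountTable | None
    criterion_proportions: list[float] | None
    chisq_overall: ChiSquareResult | None
    chisq_pairwise: list[ChiSquareResult] | None
    chisq_per_plan: dict[str, ChiSquareResult]
    allocations: list[Allocation]
    allocation_counts: CountTable | None
    allocation_chisq: ChiSquareResult | None
    sweep_tables: dict[float, CountTable]
    n_ties: int
    variability: object | None
    word_counts: object | None
    warnings: list[str]


def analyze_corpus(corpus: Corpus, config: RunConfig | None = None) -> AnalysisResult:
    """Run both analysis branches on a prepared (or raw) corpus.

    Degenerate statistical stages (too few reports, empty cells) are
    reported as warnings in the result rather than raised, so a run on
    a tiny corpus still produces its score tables.
    """
    config = config or RunConfig()
    if not corpus.reports:
        raise DegenerateInputError("corpus has no reports")
    if any(r.cleaned_text is None for r in corpus.reports):
        prepare_corpus(corpus, config.cleaning)

    embedder = make_embedder(config.embedder)
    warnings: list[str] = []
    statuses = corpus.status_index()

    whole_records: list[SimilarityRecord] = []
    sentence_records: list[SentenceSimilarityRecord] = []
    allocations: list[Allocation] = []
    for report in corpus.reports:
        whole_records.extend(
            score_report_whole(report, corpus.plans, embedder, config.summarizer)
        )
        sent_recs = score_report_sentences(report, corpus.plans, embedder)
        sentence_records.extend(sent_recs)
        allocations.append(
            allocate_forced_choice(
                sent_recs, corpus.assignment_for(report.participant_id)
            )
        )

    counting_records = (
        sentence_records if config.counting_unit == "sentence" else whole_records
    )

    def guarded(stage, fn):
        try:
            return fn()
        except DegenerateInputError as exc:
            warnings.append(f"{stage}: {exc}")
            return None

    criterion_table = guarded(
        "criterion_counts",
        lambda: criterion_counts(
            counting_records, config.threshold, statuses,
            group_by="status", unit=config.counting_unit,
        ),
    )
    criterion_by_plan = guarded(
        "criterion_counts_by_plan",
        lambda: criterion_counts(
            counting_records, config.threshold, statuses,
            group_by="status_x_plan", unit=config.counting_unit,
        ),
    )
    proportions = None
    chisq_overall = None
    pairwise = None
    if criterion_table is not None:
        proportions = guarded(
            "normalize_counts", lambda: normalize_counts(criterion_table)
        )
        chisq_overall = guarded("chisq_overall", lambda: chisq_gof(criterion_table))
        pairwise = guarded("chisq_pairwise", lambda: chisq_pairwise(criterion_table))

    chisq_per_plan: dict[str, ChiSquareResult] = {}
    if criterion_by_plan is not None:
        per_plan: dict[str, CountTable] = {}
        for label, count, total in zip(
            criterion_by_plan.labels,
            criterion_by_plan.counts,
            criterion_by_plan.totals or [0] * len(criterion_by_plan.labels),
        ):
            plan_id, status = label.split("|", 1)
            t = per_plan.setdefault(
                plan_id, CountTable(labels=[], counts=[], totals=[], name=plan_id)
            )
            t.labels.append(status)
            t.counts.append(count)
            t.totals.append(total)
        for plan_id, table in per_plan.items():
            res = guarded(f"chisq_plan[{plan_id}]", lambda t=table: chisq_gof(t))
            if res is not None:
                chisq_per_plan[plan_id] = res

    alloc_out = guarded("allocation_test", lambda: allocation_test(allocations))
    allocation_chisq, allocation_counts = alloc_out if alloc_out else (None, None)

    sweep_tables = guarded(
        "threshold_sweep",
        lambda: threshold_sweep(
            counting_records, list(config.sweep), statuses, unit=config.counting_unit
        ),
    ) or {}

    variability = guarded(
        "score_variability", lambda: score_variability(whole_records)
    )
    by_status: dict[str, list[int]] = {}
    for report, alloc in zip(corpus.reports, allocations):
        by_status.setdefault(alloc.chosen_status.value, []).append(
            len(tokenize(report.text))
        )
    word_counts = guarded(
        "word_count_summary", lambda: word_count_summary(by_status)
    )

    n_ties = sum(a.tie_flag for a in allocations)
    if n_ties:
        warnings.append(f"forced choice: {n_ties} tie(s) resolved conservatively")

    return AnalysisResult(
        whole_records=whole_records,
        sentence_records=sentence_records,
        criterion_table=criterion_table,
        criterion_by_plan=criterion_by_plan,
        criterion_proportions=proportions,
        chisq_overall=chisq_overall,
        chisq_pairwise=pairwise,
        chisq_per_plan=chisq_per_plan,
        allocations=allocations,
        allocation_counts=allocation_counts,
        allocation_chisq=allocation_chisq,
        sweep_tables=sweep_tables,
        n_ties=n_ties,
        variability=variability,
        word_counts=word_counts,
        warnings=warnings,
    )


def whole_scores_frame(records: list[SimilarityRecord]) -> pd.DataFrame:
    rows = [
        {
            "report_id": r.report_id,
            "plan_id": r.plan_id,
            "subtask_index": i,
            "score": s,
        }
        for r in records
        for i, s in enumerate(r.subtask_scores)
    ]
    return pd.DataFrame(rows)


def sentence_scores_frame(records: list[SentenceSimilarityRecord]) -> pd.DataFrame:
    rows = [
        {
            "report_id": r.report_id,
            "plan_id": r.plan_id,
            "sentence_index": si,
            "subtask_index": ti,
            "score": float(r.matrix[si, ti]),
        }
        for r in records
        for si in range(r.matrix.shape[0])
        for ti in range(r.matrix.shape[1])
    ]
    return pd.DataFrame(rows)


def chisq_frame(results: dict[str, ChiSquareResult | None]) -> pd.DataFrame:
    rows = []
    for name, res in results.items():
        if res is None:
            continue
        rows.append(
            {
                "test": name,
                "labels": "/".join(res.labels),
                "statistic": res.statistic,
                "df": res.df,
                "p_value": res.p_value,
                "tail": res.tail,
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig, corpus: Corpus | None = None) -> AnalysisResult:
    """File-level entry point: read corpus, analyze, write the bundle."""
    if corpus is None:
        if not config.corpus_path:
            raise ValidationError("run_pipeline needs corpus_path or a Corpus")
        corpus = corpus_io.read_corpus(config.corpus_path, config.corpus_format)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    result = analyze_corpus(corpus, config)

    tests: dict[str, ChiSquareResult | None] = {
        "criterion_overall": result.chisq_overall,
        "allocation": result.allocation_chisq,
    }
    for plan_id, res in result.chisq_per_plan.items():
        tests[f"criterion_plan_{plan_id}"] = res
    if result.chisq_pairwise:
        for res in result.chisq_pairwise:
            tests[f"criterion_pair_{'_vs_'.join(res.labels)}"] = res

    tables: list = [
        ("scores_whole", whole_scores_frame(result.whole_records)),
        ("scores_sentence", sentence_scores_frame(result.sentence_records)),
        ("chisq_results", chisq_frame(tests)),
    ]
    if result.criterion_table is not None:
        result.criterion_table.name = "criterion_counts"
        tables.append(result.criterion_table)
    if result.criterion_by_plan is not None:
        result.criterion_by_plan.name = "criterion_counts_by_plan"
        tables.append(result.criterion_by_plan)
    if result.allocation_counts is not None:
        tables.append(result.allocation_counts)
    for thr, table in result.sweep_tables.items():
        table.name = f"sweep_{thr:.2f}"
        tables.append(table)

    manifest = {
        "config": {
            "threshold": config.threshold,
            "sweep": list(config.sweep),
            "counting_unit": config.counting_unit,
            "embedder": config.embedder.backend_id,
            "summarizer": config.summarizer.mode,
            "seed": config.seed,
        },
        "config_digest": config.digest(),
        "n_reports": len(corpus.reports),
        "n_ties": result.n_ties,
        "warnings": result.warnings,
    }
    corpus_io.write_results(tables, out, manifest)
    log_lines = [f"reports: {len(corpus.reports)}"]
    log_lines += [f"warning: {w}" for w in result.warnings]
    for name, res in tests.items():
        if res is not None:
            log_lines.append(
                f"{name}: chi2={res.statistic:.4f} df={res.df} p={res.p_value:.4f}"
            )
    (out / "run.log").write_text("\n".join(log_lines) + "\n", "utf-8")
    return result


def run_printed_counts(counts_path: str | Path) -> dict[str, ChiSquareResult]:
    """Goodness-of-fit tests straight from a printed counts CSV, with no
    text processing: overall plus all pairwise comparisons."""
    table = corpus_io.read_count_table(counts_path)
    results = {"overall": chisq_gof(table)}
    if len(table.counts) >= 3:
        for res in chisq_pairwise(table):
            results["pair_" + "_vs_".join(res.labels)] = res
    return results
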