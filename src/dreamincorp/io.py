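"""Reading and writing corpora and result tables.

Interchange formats are deliberately plain text:

* ``json_lines`` — one UTF-8 JSON object per line in a single file,
  tagged with ``kind`` (plan / assignment / report); diffable and
  streamable.
* ``directory_of_text`` — one ``.txt`` transcript per report plus a
  ``metadata.csv`` (report_id, participant_id, awakening_index,
  sleep_stage), a ``plans.txt`` (blank-line-separated blocks of
  ``plan_id: title`` followed by 5 subtask lines) and an
  ``assignments.csv`` (participant_id, plan_id, status).

Result tables are comma-separated; counts are serialized as integers,
scores with 6 fractional digits (enough to distinguish every printed
value); each run also writes a JSON manifest echoing its configuration.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Iterable, Mapping

import pandas as pd

from .errors import ValidationError
from .stats import CountTable
from .types import Corpus, DreamReport, StatusAssignment, TaskPlan

SCORE_DIGITS = 6

_REPORT_FIELDS = ("report_id", "participant_id", "awakening_index", "sleep_stage")


def _report_from_record(rec: Mapping[str, Any]) -> DreamReport:
    missing = [f for f in (*_REPORT_FIELDS, "raw_text") if f not in rec]
    if missing:
        raise ValidationError(
            f"report record {rec.get('report_id', '?')!r} missing metadata "
            f"fields {missing}"
        )
    return DreamReport(
        report_id=str(rec["report_id"]),
        participant_id=str(rec["participant_id"]),
        awakening_index=int(rec["awakening_index"]),
        sleep_stage=rec["sleep_stage"],
        raw_text=str(rec["raw_text"]),
        cleaned_text=rec.get("cleaned_text"),
        sentences=rec.get("sentences"),
    )


def read_corpus(path: str | Path, format: str = "json_lines") -> Corpus:
    """Read and validate a corpus; malformed input raises a named error."""
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"corpus path {path} does not exist")
    if format == "json_lines":
        return _read_jsonl(path)
    if format == "directory_of_text":
        return _read_directory(path)
    raise ValidationError(f"unknown corpus format {format!r}")


def _read_jsonl(path: Path) -> Corpus:
    reports, plans, assignments = [], [], []
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ValidationError(f"{path}:{lineno}: invalid JSON: {exc}") from None
            kind = rec.get("kind")
            if kind == "report":
                reports.append(_report_from_record(rec))
            elif kind == "plan":
                plans.append(
                    TaskPlan(
                        plan_id=str(rec["plan_id"]),
                        title=str(rec["title"]),
                        subtasks=list(rec["subtasks"]),
                    )
                )
            elif kind == "assignment":
                assignments.append(
                    StatusAssignment(
                        participant_id=str(rec["participant_id"]),
                        mapping=dict(rec["mapping"]),
                    )
                )
            else:
                raise ValidationError(f"{path}:{lineno}: unknown record kind {kind!r}")
    return Corpus(reports=reports, plans=plans, assignments=assignments)


def _read_directory(path: Path) -> Corpus:
    meta_path = path / "metadata.csv"
    if not meta_path.exists():
        raise ValidationError(f"missing {meta_path}")
    meta = pd.read_csv(meta_path, dtype=str)
    reports = []
    for rec in meta.to_dict("records"):
        txt_path = path / f"{rec['report_id']}.txt"
        if not txt_path.exists():
            raise ValidationError(
                f"report {rec['report_id']}: transcript file {txt_path} missing"
            )
        rec = dict(rec)
        if any(pd.isna(v) for v in rec.values()):
            raise ValidationError(
                f"report {rec.get('report_id', '?')}: incomplete metadata row"
            )
        rec["raw_text"] = txt_path.read_text("utf-8").strip()
        reports.append(_report_from_record(rec))
    plans = _read_plans_txt(path / "plans.txt")
    assign = pd.read_csv(path / "assignments.csv", dtype=str)
    assignments = [
        StatusAssignment(
            participant_id=pid, mapping=dict(zip(grp["plan_id"], grp["status"]))
        )
        for pid, grp in assign.groupby("participant_id", sort=False)
    ]
    return Corpus(reports=reports, plans=plans, assignments=assignments)


def _read_plans_txt(path: Path) -> list[TaskPlan]:
    if not path.exists():
        raise ValidationError(f"missing {path}")
    plans = []
    blocks = [b for b in path.read_text("utf-8").split("\n\n") if b.strip()]
    for block in blocks:
        lines = [ln.strip() for ln in block.splitlines() if ln.strip()]
        head, *subtasks = lines
        if ":" not in head:
            raise ValidationError(f"{path}: plan header {head!r} needs 'plan_id: title'")
        plan_id, title = (part.strip() for part in head.split(":", 1))
        plans.append(TaskPlan(plan_id=plan_id, title=title, subtasks=subtasks))
    return plans


def write_corpus(corpus: Corpus, path: str | Path, format: str = "json_lines") -> None:
    path = Path(path)
    if format == "json_lines":
        path.parent.mkdir(parents=True, exist_ok=True)
        with path.open("w", encoding="utf-8") as fh:
            for p in corpus.plans:
                fh.write(
                    json.dumps(
                        {"kind": "plan", "plan_id": p.plan_id, "title": p.title,
                         "subtasks": p.subtasks},
                        ensure_ascii=False,
                    )
                    + "\n"
                )
            for a in corpus.assignments:
                fh.write(
                    json.dumps(
                        {
                            "kind": "assignment",
                            "participant_id": a.participant_id,
                            "mapping": {k: v.value for k, v in a.mapping.items()},
                        },
                        ensure_ascii=False,
                    )
                    + "\n"
                )
            for r in corpus.reports:
                rec = {
                    "kind": "report",
                    "report_id": r.report_id,
                    "participant_id": r.participant_id,
                    "awakening_index": r.awakening_index,
                    "sleep_stage": r.sleep_stage.value,
                    "raw_text": r.raw_text,
                }
                if r.cleaned_text is not None:
                    rec["cleaned_text"] = r.cleaned_text
                if r.sentences is not None:
                    rec["sentences"] = r.sentences
                fh.write(json.dumps(rec, ensure_ascii=False) + "\n")
    elif format == "directory_of_text":
        path.mkdir(parents=True, exist_ok=True)
        rows = []
        for r in corpus.reports:
            (path / f"{r.report_id}.txt").write_text(r.raw_text + "\n", "utf-8")
            rows.append(
                {
                    "report_id": r.report_id,
                    "participant_id": r.participant_id,
                    "awakening_index": r.awakening_index,
                    "sleep_stage": r.sleep_stage.value,
                }
            )
        pd.DataFrame(rows).to_csv(path / "metadata.csv", index=False)
        with (path / "plans.txt").open("w", encoding="utf-8") as fh:
            fh.write(
                "\n\n".join(
                    f"{p.plan_id}: {p.title}\n" + "\n".join(p.subtasks)
                    for p in corpus.plans
                )
                + "\n"
            )
        pd.DataFrame(
            [
                {"participant_id": a.participant_id, "plan_id": pid,
                 "status": status.value}
                for a in corpus.assignments
                for pid, status in a.mapping.items()
            ]
        ).to_csv(path / "assignments.csv", index=False)
    else:
        raise ValidationError(f"unknown corpus format {format!r}")


def count_table_to_frame(table: CountTable) -> pd.DataFrame:
    data: dict[str, Any] = {"label": table.labels, "count": table.counts}
    if table.totals is not None:
        data["total"] = table.totals
    return pd.DataFrame(data)


def read_count_table(path: str | Path, name: str | None = None) -> CountTable:
    df = pd.read_csv(path)
    if "count" not in df.columns:
        raise ValidationError(f"{path}: counts file needs a 'count' column")
    labels = (
        [str(x) for x in df["label"]]
        if "label" in df.columns
        else [str(i) for i in range(len(df))]
    )
    totals = [int(t) for t in df["total"]] if "total" in df.columns else None
    return CountTable(
        labels=labels,
        counts=[int(c) for c in df["count"]],
        totals=totals,
        name=name or Path(path).stem,
    )


def write_results(
    tables: Iterable[CountTable | tuple[str, pd.DataFrame]],
    path: str | Path,
    manifest: Mapping[str, Any] | None = None,
) -> None:
    """Write each table as CSV plus a JSON run manifest.

    ``tables`` mixes :class:`CountTable` objects (named by their ``name``
    field) and ``(name, DataFrame)`` pairs for score tables; scores are
    rounded to 6 fractional digits. Re-reading the CSVs yields identical
    values.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    written = []
    for item in tables:
        if isinstance(item, CountTable):
            name, frame = item.name, count_table_to_frame(item)
        else:
            name, frame = item
            frame = frame.round(SCORE_DIGITS)
        out = path / f"{name}.csv"
        frame.to_csv(out, index=False, float_format=f"%.{SCORE_DIGITS}f")
        written.append(out.name)
    manifest_body = dict(manifest or {})
    manifest_body["tables"] = written
    (path / "manifest.json").write_text(
        json.dumps(manifest_body, indent=2, ensure_ascii=False, default=str) + "\n",
        "utf-8",
    )
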