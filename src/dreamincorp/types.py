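"""Core domain types of the dream-incorporation analysis.

A study session yields *dream reports* (one per awakening with dream
recall, from REM or NREM-2 sleep), a fixed set of three *task plans*
(each a title plus five ordered subtask sentences learned before sleep),
and a per-participant *status assignment* mapping each plan bijectively
onto the three execution statuses: completed before sleep, uncompleted
(deferred to the morning), or interrupted mid-execution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

from .errors import AssignmentError, ValidationError


class SleepStage(str, Enum):
    REM = "REM"
    N2 = "N2"


class ExecutionStatus(str, Enum):
    COMPLETED = "completed"
    UNCOMPLETED = "uncompleted"
    INTERRUPTED = "interrupted"


#: Canonical reporting order for the three conditions.
STATUS_ORDER = (
    ExecutionStatus.COMPLETED,
    ExecutionStatus.UNCOMPLETED,
    ExecutionStatus.INTERRUPTED,
)

#: Tie-break priority for forced choice: the completed condition wins a
#: tie so that ties count against the hypothesis of preferential
#: incorporation of uncompleted/interrupted plans.
TIE_PRIORITY = (
    ExecutionStatus.COMPLETED,
    ExecutionStatus.INTERRUPTED,
    ExecutionStatus.UNCOMPLETED,
)

N_SUBTASKS = 5


@dataclass
class DreamReport:
    """One awakening's transcript plus derived cleaned text and sentences."""

    report_id: str
    participant_id: str
    awakening_index: int
    sleep_stage: SleepStage
    raw_text: str
    cleaned_text: str | None = None
    sentences: list[str] | None = None

    def __post_init__(self) -> None:
        if not self.report_id:
            raise ValidationError("report_id must be non-empty")
        if self.awakening_index < 1:
            raise ValidationError(
                f"report {self.report_id}: awakening_index must be >= 1"
            )
        try:
            self.sleep_stage = SleepStage(self.sleep_stage)
        except ValueError:
            raise ValidationError(
                f"report {self.report_id}: unknown sleep stage "
                f"{self.sleep_stage!r} (allowed: REM, N2)"
            ) from None

    @property
    def text(self) -> str:
        """Cleaned text if preparation has run, else the raw transcript."""
        return self.cleaned_text if self.cleaned_text is not None else self.raw_text


@dataclass
class TaskPlan:
    """A titled action script of exactly five ordered subtasks."""

    plan_id: str
    title: str
    subtasks: list[str]

    def __post_init__(self) -> None:
        if len(self.subtasks) != N_SUBTASKS:
            raise ValidationError(
                f"plan {self.plan_id}: expected {N_SUBTASKS} subtasks, "
                f"got {len(self.subtasks)}"
            )
        if any(not s.strip() for s in self.subtasks):
            raise ValidationError(f"plan {self.plan_id}: empty subtask")


@dataclass
class StatusAssignment:
    """One participant's bijection of their 3 plans onto the 3 statuses."""

    participant_id: str
    mapping: dict[str, ExecutionStatus]

    def __post_init__(self) -> None:
        self.mapping = {
            str(k): ExecutionStatus(v) for k, v in self.mapping.items()
        }
        if len(self.mapping) != 3 or set(self.mapping.values()) != set(
            ExecutionStatus
        ):
            raise AssignmentError(
                f"participant {self.participant_id}: plan->status mapping "
                "must be a bijection of 3 plans onto the 3 statuses, got "
                f"{ {k: v.value for k, v in self.mapping.items()} }"
            )

    def status_of(self, plan_id: str) -> ExecutionStatus:
        try:
            return self.mapping[plan_id]
        except KeyError:
            raise AssignmentError(
                f"participant {self.participant_id}: no status for plan "
                f"{plan_id!r}"
            ) from None


@dataclass
class Corpus:
    """A validated collection of reports, plans, and assignments."""

    reports: list[DreamReport] = field(default_factory=list)
    plans: list[TaskPlan] = field(default_factory=list)
    assignments: list[StatusAssignment] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for r in self.reports:
            if r.report_id in seen:
                raise ValidationError(f"duplicate report_id {r.report_id!r}")
            seen.add(r.report_id)
        plan_ids = {p.plan_id for p in self.plans}
        by_participant = {a.participant_id: a for a in self.assignments}
        if len(by_participant) != len(self.assignments):
            raise AssignmentError("duplicate participant in assignments")
        for a in self.assignments:
            unknown = set(a.mapping) - plan_ids
            if unknown:
                raise AssignmentError(
                    f"participant {a.participant_id}: assignment references "
                    f"unknown plans {sorted(unknown)}"
                )
        for r in self.reports:
            if r.participant_id not in by_participant:
                raise ValidationError(
                    f"report {r.report_id}: participant "
                    f"{r.participant_id!r} has no status assignment"
                )

    def assignment_for(self, participant_id: str) -> StatusAssignment:
        for a in self.assignments:
            if a.participant_id == participant_id:
                return a
        raise AssignmentError(f"no assignment for participant {participant_id!r}")

    def status_index(self) -> dict[tuple[str, str], ExecutionStatus]:
        """Map (report_id, plan_id) -> execution status of that plan for
        the report's participant."""
        by_participant = {a.participant_id: a for a in self.assignments}
        out: dict[tuple[str, str], ExecutionStatus] = {}
        for r in self.reports:
            a = by_participant[r.participant_id]
            for p in self.plans:
                out[(r.report_id, p.plan_id)] = a.status_of(p.plan_id)
        return out
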