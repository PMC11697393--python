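"""Transcript normalization and sentence segmentation.

Transcribed dream reports contain spoken-language fillers that a
written-language encoder was never trained on; cleaning removes them
mechanically from an editable lexicon. Grammar correction is a human
editing step and is deliberately not automated here.

Sentence segmentation is rule-based (terminal punctuation with an
abbreviation exception list) for reproducibility; model-based segmenters
trade determinism for marginal accuracy on this kind of short text.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources as _ilres

from .errors import EmptyTextError, ValidationError
from .types import N_SUBTASKS, TaskPlan


def _load_resource_lexicon(name: str) -> frozenset[str]:
    text = _ilres.files("dreamincorp.resources").joinpath(name).read_text("utf-8")
    entries = []
    for line in text.splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            entries.append(line)
    return frozenset(entries)


def default_filler_lexicon() -> frozenset[str]:
    """Lowercase German disfluency tokens shipped with the package."""
    return frozenset(t.lower() for t in _load_resource_lexicon("fillers_de.txt"))


def default_abbreviations() -> frozenset[str]:
    return _load_resource_lexicon("abbreviations_de.txt")


@dataclass(frozen=True)
class CleaningConfig:
    """How transcripts are normalized before embedding.

    filler_lexicon entries must be single tokens; they are removed as
    whole words (case-insensitive).
    """

    filler_lexicon: frozenset[str] = field(default_factory=default_filler_lexicon)
    normalize_whitespace: bool = True
    lowercase: bool = False

    def __post_init__(self) -> None:
        for tok in self.filler_lexicon:
            if not tok or any(ch.isspace() for ch in tok):
                raise ValidationError(
                    f"filler lexicon entry {tok!r} is not a single token"
                )


def clean_transcript(raw_text: str, config: CleaningConfig | None = None) -> str:
    """Remove filler words and normalize whitespace; idempotent."""
    if config is None:
        config = CleaningConfig()
    if not raw_text or not raw_text.strip():
        raise EmptyTextError("cannot clean empty transcript")
    text = raw_text
    if config.lowercase:
        text = text.lower()
    if config.filler_lexicon:
        pattern = re.compile(
            r"(?<!\w)(?:" + "|".join(
                re.escape(t) for t in sorted(config.filler_lexicon, key=len, reverse=True)
            ) + r")(?!\w)",
            re.IGNORECASE,
        )
        text = pattern.sub("", text)
    if config.normalize_whitespace:
        text = re.sub(r"\s+", " ", text)
        # dropped fillers may leave stray space before punctuation
        text = re.sub(r"\s+([,.;:!?])", r"\1", text)
        text = text.strip()
    return text


_BOUNDARY = re.compile(r"([.!?]+)(\s+)")


def split_sentences(
    cleaned_text: str, abbreviations: frozenset[str] | None = None
) -> list[str]:
    """Split text on terminal punctuation, keeping the punctuation.

    Periods following a known abbreviation (``z.B.``, ``Dr.`` ...) do not
    open a boundary. Text without any boundary is returned as a single
    sentence. Joining the result with single spaces recovers the input
    modulo whitespace.
    """
    if not cleaned_text or not cleaned_text.strip():
        raise EmptyTextError("cannot segment empty text")
    if abbreviations is None:
        abbreviations = default_abbreviations()
    abbrev_lower = {a.lower() for a in abbreviations}

    sentences: list[str] = []
    start = 0
    for m in _BOUNDARY.finditer(cleaned_text):
        candidate = cleaned_text[start : m.end(1)]
        last_token = candidate.rsplit(None, 1)[-1] if candidate.split() else ""
        if last_token.lower() in abbrev_lower:
            continue
        if candidate.strip():
            sentences.append(candidate.strip())
            start = m.end()
    tail = cleaned_text[start:].strip()
    if tail:
        sentences.append(tail)
    if not sentences:
        sentences = [cleaned_text.strip()]
    return sentences


_ENUM_PREFIX = re.compile(r"^\s*(?:\(\d+\)|\d+[.)]|[-*•])\s*")

#: Template used to expand a bullet-point subtask into a full sentence.
#: ``{title}`` is the plan title, ``{phrase}`` the de-enumerated bullet.
DEFAULT_SUBTASK_TEMPLATE = "{title} involves {phrase}."

_TERMINAL = (".", "!", "?")


@dataclass
class PlanSentences:
    """A plan rendered as five full sentences, title kept as context."""

    plan_id: str
    title: str
    sentences: list[str]


def plan_to_sentences(
    plan: TaskPlan, template: str = DEFAULT_SUBTASK_TEMPLATE
) -> PlanSentences:
    """Render each subtask as one full sentence, preserving order.

    Subtasks that already read as full sentences (initial capital,
    terminal punctuation) pass through unchanged; bullet-point phrases
    are expanded through ``template``. The converted text is returned,
    not written back, so users can hand-edit the result.
    """
    if len(plan.subtasks) != N_SUBTASKS:
        raise ValidationError(
            f"plan {plan.plan_id}: expected {N_SUBTASKS} subtasks, "
            f"got {len(plan.subtasks)}"
        )
    sentences = []
    for sub in plan.subtasks:
        phrase = _ENUM_PREFIX.sub("", sub).strip()
        if not phrase:
            raise ValidationError(f"plan {plan.plan_id}: empty subtask")
        if phrase.endswith(_TERMINAL) and phrase[0].isupper():
            sentences.append(phrase)
        else:
            sentences.append(
                template.format(title=plan.title, phrase=phrase.rstrip("."))
            )
    return PlanSentences(plan_id=plan.plan_id, title=plan.title, sentences=sentences)
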