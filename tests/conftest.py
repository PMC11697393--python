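import pytest

from dreamincorp.embed import EmbedderSpec
from dreamincorp.synth import GeneratorConfig, generate_corpus
from dreamincorp.types import (
    Corpus,
    DreamReport,
    SleepStage,
    StatusAssignment,
    TaskPlan,
)


@pytest.fixture
def plans():
    return [
        TaskPlan(
            plan_id=f"plan_{k}",
            title=f"Plan {k.upper()}",
            subtasks=[f"Plan {k} schritt {i} wort{k}{i}." for i in range(1, 6)],
        )
        for k in "abc"
    ]


@pytest.fixture
def assignment():
    return StatusAssignment(
        participant_id="p1",
        mapping={
            "plan_a": "completed",
            "plan_b": "uncompleted",
            "plan_c": "interrupted",
        },
    )


@pytest.fixture
def tiny_corpus(plans, assignment):
    reports = [
        DreamReport(
            report_id="r1",
            participant_id="p1",
            awakening_index=1,
            sleep_stage=SleepStage.REM,
            raw_text="Ich war in einem Garten. Dann kam ein Hund.",
        ),
        DreamReport(
            report_id="r2",
            participant_id="p1",
            awakening_index=2,
            sleep_stage=SleepStage.N2,
            raw_text="Plan b schritt 2 wortb2. Sonst nichts weiter.",
        ),
    ]
    return Corpus(reports=reports, plans=plans, assignments=[assignment])


@pytest.fixture
def embedder_spec():
    return EmbedderSpec(seed=7)


@pytest.fixture
def synthetic_corpus():
    corpus, truth = generate_corpus(GeneratorConfig(seed=11))
    return corpus, truth
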