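"""Sentence-wise scoring and forced choice on a hand-built report.

Builds three tiny task plans and one dream report whose second sentence
paraphrases (here: copies tokens of) a subtask of the plan assigned to
the uncompleted condition, then shows the sentence x subtask score
matrix and the resulting allocation.
"""

from dreamincorp.embed import EmbedderSpec
from dreamincorp.similarity import allocate_forced_choice, score_report_sentences
from dreamincorp.types import DreamReport, SleepStage, StatusAssignment, TaskPlan

plans = [
    TaskPlan("desk", "Desk tidying",
             [f"Desk tidying involves step {i} akte ordner stift karte." for i in range(5)]),
    TaskPlan("leave", "Getting ready to leave",
             [f"Getting ready involves step {i} rechner fenster mantel licht." for i in range(5)]),
    TaskPlan("table", "Setting the table",
             [f"Setting the table involves step {i} decke teller glas kerze." for i in range(5)]),
]
assignment = StatusAssignment(
    "p1", {"desk": "completed", "leave": "uncompleted", "table": "interrupted"}
)
report = DreamReport(
    report_id="r1", participant_id="p1", awakening_index=1,
    sleep_stage=SleepStage.REM,
    raw_text=("Ich lief durch eine fremde Stadt. "
              "Dann stand ich am rechner und schloss das fenster und nahm den mantel. "
              "Danach wachte ich auf."),
)

records = score_report_sentences(report, plans, EmbedderSpec(seed=0))
for rec in records:
    print(f"plan {rec.plan_id}: matrix {rec.matrix.shape}, "
          f"max score {rec.max_score:.3f}")

alloc = allocate_forced_choice(records, assignment)
print(f"allocated to: {alloc.chosen_status.value} "
      f"(winning score {alloc.winning_score:.3f}, tie={alloc.tie_flag})")

# The second sentence shares tokens with the 'leave' plan, so the
# report is allocated to that plan's status: uncompleted.
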