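"""Bundled example count tables from an 86-report overnight study.

The package ships the bookkeeping tables of a within-subject night
study (19 participants, 3 task plans, 117 awakenings, 86 recalled
dreams) as plain-CSV resources. They are *inputs* — printed count
tables on which the chi-square machinery can be exercised without any
text corpus — not outputs of this package.
"""

from __future__ import annotations

from importlib import resources as _ilres

import pandas as pd

from .stats import CountTable
from .types import STATUS_ORDER, ExecutionStatus

#: Awakenings performed and dreams recalled per sleep stage.
EXAMPLE_AWAKENINGS = {"REM": 59, "N2": 58}
EXAMPLE_REPORTS_BY_STAGE = {"REM": 51, "N2": 35}


def _resource_frame(name: str) -> pd.DataFrame:
    with _ilres.files("dreamincorp.resources").joinpath(name).open("r") as fh:
        return pd.read_csv(fh)


def example_report_counts() -> dict[str, dict[ExecutionStatus, int]]:
    """Reports available per (plan, execution status); rows sum to 86."""
    df = _resource_frame("example_report_counts.csv")
    return {
        str(row["plan"]): {s: int(row[s.value]) for s in ExecutionStatus}
        for _, row in df.iterrows()
    }


def example_criterion_counts() -> dict[str, CountTable]:
    """Above-criterion / allocation counts per analysis, by status.

    Keys: ``whole_text_overall``, ``whole_text_tidying_the_desk``,
    ``whole_text_getting_ready_to_leave``, ``forced_choice_allocation``.
    """
    df = _resource_frame("example_criterion_counts.csv")
    out = {}
    for _, row in df.iterrows():
        name = str(row["analysis"])
        out[name] = CountTable(
            labels=[s.value for s in STATUS_ORDER],
            counts=[int(row[s.value]) for s in STATUS_ORDER],
            name=name,
        )
    return out
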