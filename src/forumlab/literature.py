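"""Published PCOS cohort summaries used as the reference side of comparisons.

Two packaged fixtures:

* ``literature.csv`` — one row per (study, test): the ten reference studies'
  PCOS group sizes and per-test mean/SD in this package's canonical units,
  plus study metadata (cycle phase, fasting status). The ``printed_label``
  column transcribes the published per-study verdict letters (a =
  equivalent, b = literature lower, c = literature higher) and is used only
  to validate reproduced verdicts, never as a computation input.
* ``aggregate.csv`` — per test: the forum-cohort summary (n, mean, SD) and
  the published aggregate-literature summary it was compared against. The
  published aggregate SD is taken as an input because its provenance is not
  reproducible from the per-study table (see the methods note).
"""
from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Optional

import pandas as pd

from .types import CohortSummary

STUDY_ORDER = [
    "diamanti_kandarakis", "cai", "tosi", "paschou", "sova",
    "kumar", "bahceci", "homburg", "pigny", "wright",
]


def _read_packaged(name: str) -> pd.DataFrame:
    ref = resources.files("forumlab.data").joinpath(name)
    with ref.open("rb") as fh:
        return pd.read_csv(fh)


def load_study_table(path: Optional[str | Path] = None) -> pd.DataFrame:
    """Tidy per-(study, test) literature table."""
    return pd.read_csv(path) if path is not None else _read_packaged("literature.csv")


def load_aggregate_table(path: Optional[str | Path] = None) -> pd.DataFrame:
    """Forum-cohort and published-aggregate summary per test."""
    return pd.read_csv(path) if path is not None else _read_packaged("aggregate.csv")


def study_summaries(
    table: Optional[pd.DataFrame] = None,
) -> dict[str, dict[str, CohortSummary]]:
    """study label -> (test id -> CohortSummary)."""
    if table is None:
        table = load_study_table()
    out: dict[str, dict[str, CohortSummary]] = {}
    for row in table.itertuples():
        out.setdefault(row.study, {})[row.test] = CohortSummary(
            test_id=row.test, n=int(row.study_n), mean=float(row.mean), sd=float(row.sd)
        )
    return out


def subreddit_summaries(
    table: Optional[pd.DataFrame] = None,
) -> dict[str, CohortSummary]:
    """The published forum-cohort side (test id -> CohortSummary)."""
    if table is None:
        table = load_aggregate_table()
    return {
        row.test: CohortSummary(
            test_id=row.test, n=int(row.sub_n), mean=float(row.sub_mean),
            sd=float(row.sub_sd),
        )
        for row in table.itertuples()
    }


def published_aggregate_summaries(
    table: Optional[pd.DataFrame] = None,
) -> dict[str, CohortSummary]:
    """The published aggregate-literature side (test id -> CohortSummary)."""
    if table is None:
        table = load_aggregate_table()
    return {
        row.test: CohortSummary(
            test_id=row.test, n=int(row.agg_n), mean=float(row.agg_mean),
            sd=float(row.agg_sd),
        )
        for row in table.itertuples()
    }


def printed_labels(table: Optional[pd.DataFrame] = None) -> dict[tuple[str, str], str]:
    """(test id, study) -> transcribed published verdict letter."""
    if table is None:
        table = load_study_table()
    return {(row.test, row.study): row.printed_label for row in table.itertuples()}
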