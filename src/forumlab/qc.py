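"""Cohort quality control: reprocess flags, outlier removal, summary table.

Per test, z-scores are computed against that test's own mean and sample SD
(ddof=1) over all current values. Results flagged for reprocessing are the
uncertain ones plus those with |z| > 2; results with |z| > 4 are removed in
a single pass against the pre-removal mean/SD — a deliberately generous
allowance, since dysregulated cohorts are expected to contain genuine
extremes. The cohort summary reports every test with at least ``min_count``
post-removal observations.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .types import LabObservation, TestSet

REPROCESS_Z = 2.0
REMOVAL_Z = 4.0
MIN_COUNT = 20


def _zscores(values: np.ndarray) -> np.ndarray:
    """|z| against the sample's own mean/SD; zeros when SD is 0 or n < 2."""
    if len(values) < 2:
        return np.zeros(len(values))
    sd = values.std(ddof=1)
    if sd == 0:
        return np.zeros(len(values))
    return np.abs(values - values.mean()) / sd


def flag_reprocess(
    observations: Sequence[LabObservation], z_threshold: float = REPROCESS_Z
) -> list[LabObservation]:
    """Uncertain observations plus |z| > threshold, for one test."""
    values = np.array([o.value for o in observations], dtype=float)
    z = _zscores(values)
    return [
        o for o, zi in zip(observations, z) if o.uncertain or zi > z_threshold
    ]


def remove_outliers(
    observations: Sequence[LabObservation], zmax: float = REMOVAL_Z
) -> tuple[list[LabObservation], list[LabObservation], float]:
    """Single-pass removal of |z| > zmax against pre-removal mean/SD.

    Returns (kept, removed, removal rate in percent).
    """
    observations = list(observations)
    if not observations:
        return [], [], 0.0
    values = np.array([o.value for o in observations], dtype=float)
    z = _zscores(values)
    kept = [o for o, zi in zip(observations, z) if zi <= zmax]
    removed = [o for o, zi in zip(observations, z) if zi > zmax]
    return kept, removed, 100.0 * len(removed) / len(observations)


@dataclass
class QCReport:
    """Per-test reprocess/removal bookkeeping."""

    reprocess_ids: dict[str, list[str]] = field(default_factory=dict)
    removed_ids: dict[str, list[str]] = field(default_factory=dict)
    removal_rate: dict[str, float] = field(default_factory=dict)
    uncertainty_rate: dict[str, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        tests = sorted(
            set(self.reprocess_ids) | set(self.removed_ids)
            | set(self.removal_rate) | set(self.uncertainty_rate)
        )
        return pd.DataFrame(
            [
                {
                    "test": t,
                    "n_reprocess_flagged": len(self.reprocess_ids.get(t, [])),
                    "n_removed": len(self.removed_ids.get(t, [])),
                    "removal_rate_pct": self.removal_rate.get(t, 0.0),
                    "uncertainty_rate_pct": self.uncertainty_rate.get(t, 0.0),
                }
                for t in tests
            ]
        )


def _by_test(sets: Iterable[TestSet]) -> dict[str, list[LabObservation]]:
    grouped: dict[str, list[LabObservation]] = {}
    for ts in sets:
        for obs in ts.observations:
            grouped.setdefault(obs.test_id, []).append(obs)
    return grouped


def qc_report(
    sets: Iterable[TestSet],
    reprocess_z: float = REPROCESS_Z,
    removal_z: float = REMOVAL_Z,
) -> QCReport:
    report = QCReport()
    for test_id, obs in sorted(_by_test(sets).items()):
        flagged = flag_reprocess(obs, reprocess_z)
        kept, removed, rate = remove_outliers(obs, removal_z)
        report.reprocess_ids[test_id] = [o.post_id for o in flagged]
        report.removed_ids[test_id] = [o.post_id for o in removed]
        report.removal_rate[test_id] = rate
        report.uncertainty_rate[test_id] = (
            100.0 * sum(o.uncertain for o in obs) / len(obs)
        )
    return report


def summarize_cohort(
    sets: Sequence[TestSet],
    min_count: int = MIN_COUNT,
    removal_z: float = REMOVAL_Z,
    test_order: Optional[list[str]] = None,
) -> pd.DataFrame:
    """Cohort summary table, one row per test with >= min_count post-removal
    observations.

    Columns: n (post-removal), percent of test sets containing the result,
    mean, SD, median, quartiles, observed min/max (all post-removal),
    percent uncertain (pre-removal), percent outliers removed. The
    percent-of-sets denominator is the total number of test sets.
    """
    n_sets = len(sets)
    rows = []
    grouped = _by_test(sets)
    order = test_order or sorted(grouped)
    for test_id in order:
        obs = grouped.get(test_id)
        if not obs:
            continue
        kept, removed, rate = remove_outliers(obs, removal_z)
        if len(kept) < min_count:
            continue
        values = np.array([o.value for o in kept], dtype=float)
        n_sets_with = sum(1 for ts in sets if ts.has(test_id))
        rows.append(
            {
                "test": test_id,
                "n": len(kept),
                "pct_sets": 100.0 * n_sets_with / n_sets if n_sets else 0.0,
                "mean": values.mean(),
                "sd": values.std(ddof=1) if len(values) > 1 else 0.0,
                "median": float(np.median(values)),
                "q1": float(np.percentile(values, 25)),
                "q3": float(np.percentile(values, 75)),
                "min": float(values.min()),
                "max": float(values.max()),
                "pct_uncertain": 100.0 * sum(o.uncertain for o in obs) / len(obs),
                "pct_outliers_removed": rate,
            }
        )
    frame = pd.DataFrame(
        rows,
        columns=[
            "test", "n", "pct_sets", "mean", "sd", "median", "q1", "q3",
            "min", "max", "pct_uncertain", "pct_outliers_removed",
        ],
    )
    return frame.sort_values("n", ascending=False).reset_index(drop=True)


def render_summary_table(frame: pd.DataFrame) -> pd.DataFrame:
    """Printable cohort table: ``mean (SD)`` and ``median (min-max)``
    columns, matching the convention of printing observed extremes in the
    parenthesis."""
    out = pd.DataFrame()
    out["test"] = frame["test"]
    out["n"] = frame["n"]
    out["pct_sets"] = frame["pct_sets"].map(lambda v: f"{v:.1f}")
    out["mean_sd"] = [
        f"{m:.1f} ({s:.1f})" for m, s in zip(frame["mean"], frame["sd"])
    ]
    out["median_range"] = [
        f"{md:.1f} ({lo:.2g}-{hi:.4g})"
        for md, lo, hi in zip(frame["median"], frame["min"], frame["max"])
    ]
    out["pct_uncertain"] = frame["pct_uncertain"].map(lambda v: f"{v:.1f}")
    out["pct_outliers_removed"] = frame["pct_outliers_removed"].map(
        lambda v: f"{v:.1f}"
    )
    return out
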