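"""Equivalence testing between cohort summary statistics.

Two cohorts are compared from their summary statistics (n, mean, SD) alone,
using the two one-sided t-test (TOST) procedure. The equivalence boundary is

    b = d * SD_pooled,        d = 0.499 (a medium Cohen's d),

where SD_pooled is the degrees-of-freedom-weighted pooled standard deviation
of the two groups. The TOST null hypothesis is |mu_B - mu_A| >= b; rejecting
it (p < alpha) concludes the cohorts are equivalent to within b. When
equivalence is not concluded, one-sided pooled-variance t tests decide
whether the second cohort's mean is statistically lower or higher.

Pooled-variance (Student) errors are used throughout because the boundary
itself is built from SD_pooled; Welch errors are available behind a switch.
No multiple-testing correction is applied: the comparisons are exploratory
and are read jointly, not in isolation.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .types import CohortSummary

#: Default equivalence-boundary multiplier (medium Cohen's d).
DEFAULT_COHEN_D = 0.499
DEFAULT_ALPHA = 0.05

VERDICT_EQUIVALENT = "equivalent"
VERDICT_B_LOWER = "B-lower"
VERDICT_B_HIGHER = "B-higher"
VERDICT_INCONCLUSIVE = "inconclusive"

#: Footnote codes used in the per-study comparison table: a = equivalent,
#: b = literature (second group) lower, c = literature higher.
VERDICT_CODES = {
    VERDICT_EQUIVALENT: "a",
    VERDICT_B_LOWER: "b",
    VERDICT_B_HIGHER: "c",
    VERDICT_INCONCLUSIVE: "-",
}


class EquivalenceError(ValueError):
    pass


@dataclass(frozen=True)
class BoundarySpec:
    """Equivalence-boundary definition: b = cohen_d * pooled SD."""

    cohen_d: float = DEFAULT_COHEN_D
    alpha: float = DEFAULT_ALPHA
    welch: bool = False

    def __post_init__(self) -> None:
        if self.cohen_d <= 0:
            raise EquivalenceError("cohen_d must be > 0")
        if not 0 < self.alpha < 1:
            raise EquivalenceError("alpha must be in (0,1)")


def pooled_sd(groups: Sequence[tuple[float, float]]) -> float:
    """Degrees-of-freedom-weighted pooled SD.

    Parameters
    ----------
    groups : sequence of (n, SD) pairs, each n >= 2.
    """
    if not groups:
        raise EquivalenceError("pooled_sd needs at least one group")
    num = 0.0
    den = 0.0
    for n, sd in groups:
        if n < 2:
            raise EquivalenceError("every group needs n >= 2 for pooling")
        if sd < 0:
            raise EquivalenceError("SD must be >= 0")
        num += (n - 1) * sd * sd
        den += n - 1
    return math.sqrt(num / den)


def aggregate_mean(
    studies: Iterable[CohortSummary], test_id: Optional[str] = None
) -> CohortSummary:
    """Sample-size-weighted mean across studies reporting one test.

    Returns a :class:`CohortSummary` whose ``sd`` slot carries the pooled SD
    of the contributing studies (reported for reference; comparisons against
    a published aggregate may instead take the published SD as an input).
    """
    rows = [s for s in studies if test_id is None or s.test_id == test_id]
    if not rows:
        raise EquivalenceError(f"no study reports test {test_id!r}")
    tid = rows[0].test_id
    n = sum(r.n for r in rows)
    mean = sum(r.n * r.mean for r in rows) / n
    sd = pooled_sd([(r.n, r.sd) for r in rows]) if all(r.n >= 2 for r in rows) else 0.0
    return CohortSummary(test_id=tid, n=n, mean=mean, sd=sd)


def _se_and_df(
    sdA: float, nA: int, sdB: float, nB: int, welch: bool
) -> tuple[float, float, float]:
    """(standard error of the mean difference, df, pooled SD)."""
    sp = pooled_sd([(nA, sdA), (nB, sdB)])
    if welch:
        va, vb = sdA**2 / nA, sdB**2 / nB
        se = math.sqrt(va + vb)
        df = (va + vb) ** 2 / (va**2 / (nA - 1) + vb**2 / (nB - 1))
    else:
        se = sp * math.sqrt(1.0 / nA + 1.0 / nB)
        df = nA + nB - 2
    return se, df, sp


def tost(
    meanA: float,
    sdA: float,
    nA: int,
    meanB: float,
    sdB: float,
    nB: int,
    spec: BoundarySpec = BoundarySpec(),
) -> tuple[float, float, bool]:
    """Two one-sided t tests for equivalence of two summarized cohorts.

    Returns ``(boundary, p, equivalent)`` where ``p`` is the larger of the
    two one-sided p-values for H0: |mean difference| >= boundary, and
    ``equivalent`` is ``p < alpha``.
    """
    if nA < 2 or nB < 2:
        raise EquivalenceError("TOST needs n >= 2 in both groups")
    if sdA < 0 or sdB < 0:
        raise EquivalenceError("SDs must be >= 0")
    if sdA == 0 and sdB == 0:
        raise EquivalenceError("both SDs are zero; boundary is degenerate")
    se, df, sp = _se_and_df(sdA, nA, sdB, nB, spec.welch)
    b = spec.cohen_d * sp
    if b == 0 or se == 0:
        raise EquivalenceError("degenerate boundary or standard error")
    delta = meanB - meanA
    t_lower = (delta + b) / se  # H0: delta <= -b, reject for large t
    t_upper = (delta - b) / se  # H0: delta >= +b, reject for small t
    p_lower = stats.t.sf(t_lower, df)
    p_upper = stats.t.cdf(t_upper, df)
    p = max(p_lower, p_upper)
    return b, float(p), bool(p < spec.alpha)


def directional_test(
    meanA: float,
    sdA: float,
    nA: int,
    meanB: float,
    sdB: float,
    nB: int,
    alpha: float = DEFAULT_ALPHA,
    welch: bool = False,
) -> tuple[str, float]:
    """One-sided two-sample t test for the direction of a mean difference.

    Returns ``(direction, p)`` with direction ``"B-lower"`` when the second
    group's mean is statistically lower than the first's (one-sided p <
    alpha), ``"B-higher"`` for the opposite, ``"none"`` when neither
    one-sided test rejects. ``p`` is the smaller one-sided p-value.
    """
    if nA < 2 or nB < 2:
        raise EquivalenceError("t test needs n >= 2 in both groups")
    se, df, _ = _se_and_df(sdA, nA, sdB, nB, welch)
    if se == 0:
        raise EquivalenceError("zero standard error")
    t = (meanB - meanA) / se
    p_lower = stats.t.cdf(t, df)   # H1: meanB < meanA
    p_higher = stats.t.sf(t, df)   # H1: meanB > meanA
    if p_lower < p_higher:
        direction, p = VERDICT_B_LOWER, p_lower
    else:
        direction, p = VERDICT_B_HIGHER, p_higher
    if p >= alpha:
        return "none", float(p)
    return direction, float(p)


@dataclass(frozen=True)
class ComparisonRow:
    """Full record of one two-cohort comparison."""

    test_id: str
    label: str
    nA: int
    meanA: float
    sdA: float
    nB: int
    meanB: float
    sdB: float
    pooled_sd: float
    boundary: float
    p_tost: float
    equivalent: bool
    direction: str
    p_directional: Optional[float]
    verdict: str

    @property
    def code(self) -> str:
        return VERDICT_CODES[self.verdict]


class CohortComparison:
    """Model comparing one cohort against one or more reference cohorts.

    Built from summary statistics; ``fit()`` runs the TOST procedure (with
    one-sided fallback) for every test both sides report and returns a
    :class:`ComparisonResults`.

    Parameters
    ----------
    cohort : mapping test_id -> CohortSummary
        The cohort of interest (side A; here, the forum-derived cohort).
    references : mapping label -> (mapping test_id -> CohortSummary)
        One or more reference cohorts (side B; individual studies and/or a
        pre-computed aggregate).
    spec : BoundarySpec
    """

    def __init__(
        self,
        cohort: dict[str, CohortSummary],
        references: dict[str, dict[str, CohortSummary]],
        spec: BoundarySpec = BoundarySpec(),
    ):
        self.cohort = cohort
        self.references = references
        self.spec = spec

    @classmethod
    def from_dataframe(
        cls,
        cohort: pd.DataFrame,
        references: pd.DataFrame,
        spec: BoundarySpec = BoundarySpec(),
        label_col: str = "study",
    ) -> "CohortComparison":
        """Build from tidy frames with columns test, n, mean, sd
        (references additionally carry a label column)."""
        side_a = {
            r.test: CohortSummary(r.test, int(r.n), float(r.mean), float(r.sd))
            for r in cohort.itertuples()
        }
        side_b: dict[str, dict[str, CohortSummary]] = {}
        for r in references.itertuples():
            label = getattr(r, label_col)
            side_b.setdefault(label, {})[r.test] = CohortSummary(
                r.test, int(r.n), float(r.mean), float(r.sd)
            )
        return cls(side_a, side_b, spec)

    def fit(self) -> "ComparisonResults":
        rows = []
        for label, ref in self.references.items():
            for test_id, a in self.cohort.items():
                if test_id not in ref:
                    continue
                bsum = ref[test_id]
                rows.append(self._compare_one(label, a, bsum))
        return ComparisonResults(self, rows)

    def _compare_one(
        self, label: str, a: CohortSummary, b: CohortSummary
    ) -> ComparisonRow:
        bound, p_tost, equivalent = tost(
            a.mean, a.sd, a.n, b.mean, b.sd, b.n, self.spec
        )
        sp = pooled_sd([(a.n, a.sd), (b.n, b.sd)])
        direction, p_dir = "none", None
        if equivalent:
            verdict = VERDICT_EQUIVALENT
        else:
            direction, p_dir = directional_test(
                a.mean, a.sd, a.n, b.mean, b.sd, b.n,
                alpha=self.spec.alpha, welch=self.spec.welch,
            )
            verdict = direction if direction != "none" else VERDICT_INCONCLUSIVE
        return ComparisonRow(
            test_id=a.test_id,
            label=label,
            nA=a.n, meanA=a.mean, sdA=a.sd,
            nB=b.n, meanB=b.mean, sdB=b.sd,
            pooled_sd=sp,
            boundary=bound,
            p_tost=p_tost,
            equivalent=equivalent,
            direction=direction,
            p_directional=p_dir,
            verdict=verdict,
        )


class ComparisonResults:
    """Results of :meth:`CohortComparison.fit`."""

    def __init__(self, model: CohortComparison, rows: list[ComparisonRow]):
        self.model = model
        self.rows = rows

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "test": r.test_id,
                    "reference": r.label,
                    "n_A": r.nA,
                    "mean_A": r.meanA,
                    "sd_A": r.sdA,
                    "n_B": r.nB,
                    "mean_B": r.meanB,
                    "sd_B": r.sdB,
                    "pooled_sd": r.pooled_sd,
                    "boundary": r.boundary,
                    "p_tost": r.p_tost,
                    "p_directional": r.p_directional,
                    "verdict": r.verdict,
                    "code": r.code,
                }
                for r in self.rows
            ]
        )

    def verdict_of(self, test_id: str, label: str) -> str:
        for r in self.rows:
            if r.test_id == test_id and r.label == label:
                return r.verdict
        raise KeyError((test_id, label))

    def matrix(self) -> pd.DataFrame:
        """Tests x references matrix of verdict codes (a/b/c)."""
        frame = self.to_frame()
        return frame.pivot(index="test", columns="reference", values="code")

    def summary(self) -> str:
        spec = self.model.spec
        frame = self.to_frame()
        lines = [
            "Cohort equivalence comparison (TOST with one-sided fallback)",
            f"  boundary b = {spec.cohen_d} x pooled SD, alpha = {spec.alpha}, "
            f"errors = {'Welch' if spec.welch else 'pooled'}",
            f"  comparisons: {len(frame)}",
            "",
        ]
        with pd.option_context("display.width", 120, "display.max_rows", 200):
            sub = frame[
                ["test", "reference", "n_A", "mean_A", "n_B", "mean_B",
                 "boundary", "p_tost", "p_directional", "verdict"]
            ].copy()
            for col in ("mean_A", "mean_B", "boundary"):
                sub[col] = sub[col].map(lambda v: f"{v:.2f}")
            for col in ("p_tost", "p_directional"):
                sub[col] = sub[col].map(
                    lambda v: "" if v is None or (isinstance(v, float) and np.isnan(v))
                    else ("<.001" if v < 0.001 else f"{v:.3f}")
                )
            lines.append(sub.to_string(index=False))
        return "\n".join(lines)


def compare_matrix(
    cohort: dict[str, CohortSummary],
    studies: dict[str, dict[str, CohortSummary]],
    aggregate: Optional[dict[str, CohortSummary]] = None,
    spec: BoundarySpec = BoundarySpec(),
) -> tuple[Optional[ComparisonResults], ComparisonResults]:
    """Run the aggregate-level and per-study comparison tables.

    Returns ``(aggregate_results, per_study_results)``; the first is None
    when no aggregate side is supplied. Units must already agree (all values
    canonical); per-study cells where a study does not report a test are
    simply absent from the per-study table.
    """
    agg_res = None
    if aggregate is not None:
        agg_res = CohortComparison(cohort, {"aggregate": aggregate}, spec).fit()
    per_study = CohortComparison(cohort, studies, spec).fit()
    return agg_res, per_study
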