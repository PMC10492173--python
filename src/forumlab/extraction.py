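"""Turning flagged posts into canonicalized laboratory observations.

The recording process mirrors how a careful human reader works through a
post: find test-name/number/unit patterns, decide whether a stated unit
makes physiological sense (reinterpreting the rare mistyped unit label),
infer the unit of bare numbers from condition-plausible ranges, flag results
whose unit cannot be resolved unambiguously as *uncertain* rather than
discarding them, convert everything to the catalog's canonical units, and
group results into per-(account, day) test sets with duplicate removal and
same-day merging.
"""
from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Iterable, Optional

from .catalog import CatalogError, TestCatalog, TestEntry
from .types import ForumPost, LabObservation, RawMention, Rejection, TestSet

log = logging.getLogger(__name__)

#: Relative disagreement between plausible unit interpretations above which
#: a bare-number result is flagged uncertain.
AMBIGUITY_THRESHOLD = 0.2

_NUMBER = r"-?\d+(?:\.\d+)?"
_CONNECTOR = r"(?:\s*(?:was|is|were|came back at|level of|level|at|:|=|-)\s*|\s+)"
_UNIT = r"(%|[a-zA-Zµ]{1,4}\s*/\s*[a-zA-Z0-9^]{1,4})"

_CYCLE_RE = re.compile(
    r"(luteal phase|follicular phase|cycle day \d+|cd \d+)", re.IGNORECASE
)


def _mention_pattern(synonym: str) -> re.Pattern:
    syn = re.escape(synonym)
    return re.compile(
        rf"(?<![a-z0-9]){syn}(?![a-z]){_CONNECTOR}({_NUMBER})\s*{_UNIT}?",
        re.IGNORECASE,
    )


class _CompiledCatalog:
    """Per-catalog compiled synonym patterns and the global unit vocabulary."""

    def __init__(self, catalog: TestCatalog):
        self.catalog = catalog
        self.patterns: list[tuple[TestEntry, str, re.Pattern]] = []
        for entry in catalog:
            for syn in entry.synonyms:
                self.patterns.append((entry, syn, _mention_pattern(syn)))
        self.known_units = {"%"}
        for entry in catalog:
            self.known_units.update(u.lower() for u in entry.units)
            self.known_units.update(
                a for a, c in catalog.unit_aliases.items()
                if c in entry.units or c == "percent"
            )


_compiled_cache: dict[int, _CompiledCatalog] = {}


def _compiled(catalog: TestCatalog) -> _CompiledCatalog:
    key = id(catalog)
    if key not in _compiled_cache:
        _compiled_cache[key] = _CompiledCatalog(catalog)
    return _compiled_cache[key]


def find_mentions(post: ForumPost, catalog: TestCatalog) -> list[RawMention]:
    """Scan title+body for synonym/number/unit patterns.

    Overlapping synonym matches resolve to the longest synonym (so
    ``LH/FSH 2.2`` is the ratio, not an FSH result). A token after the
    number is taken as the unit only when it normalizes into the catalog's
    unit vocabulary; otherwise the unit is treated as absent.
    """
    comp = _compiled(catalog)
    text = post.text
    candidates = []
    for entry, syn, pattern in comp.patterns:
        for m in pattern.finditer(text):
            syn_span = (m.start(), m.start() + len(syn))
            value = float(m.group(1))
            unit = m.group(2)
            if unit is not None:
                unit_norm = re.sub(r"\s*/\s*", "/", unit).lower()
                if unit_norm not in comp.known_units:
                    unit = None
                else:
                    unit = catalog.normalize_unit(unit_norm)
                    if unit == "percent":
                        unit = None if entry.unit != "percent" else entry.unit
            candidates.append(
                (syn_span, len(syn), entry.test_id, m.group(1), value, unit,
                 (m.start(), m.end()))
            )
    # longest synonym wins on overlap; ties broken by position
    candidates.sort(key=lambda c: (-c[1], c[0]))
    kept: list = []
    used: list[tuple[int, int]] = []
    for cand in candidates:
        (s, e) = cand[0]
        if any(s < ue and us < e for us, ue in used):
            continue
        used.append((s, e))
        kept.append(cand)
    kept.sort(key=lambda c: c[0])
    return [
        RawMention(
            post_id=post.id,
            account_id=post.author,
            post_day=post.day,
            test_id=test_id,
            matched_text=text[span[0]:span[1]],
            value=value,
            unit=unit,
            span=span,
        )
        for (_, _, test_id, _, value, unit, span) in kept
    ]


def find_cycle_phase(post: ForumPost) -> Optional[str]:
    m = _CYCLE_RE.search(post.text)
    return m.group(1).lower() if m else None


def convert_unit(
    test_id: str, value: float, unit: str, catalog: TestCatalog
) -> float:
    """Convert ``value`` from ``unit`` to the test's canonical unit."""
    entry = catalog[test_id]
    unit = catalog.normalize_unit(unit)
    return value * entry.factor_to_canonical(unit)


@dataclass(frozen=True)
class Verdict:
    kind: str                 # accept | reinterpret | reject
    unit: Optional[str] = None  # the reinterpreted unit

    @property
    def accepted(self) -> bool:
        return self.kind != "reject"


def check_mistranscription(
    test_id: str,
    value: float,
    unit: str,
    catalog: TestCatalog,
    widen: float = 1.0,
) -> Verdict:
    """Physiological-sense check of a (value, stated unit) pair.

    Accept when the converted value lies in the condition-plausible range;
    reinterpret when the stated unit is implausible (or unknown for the
    test) and exactly one other common unit places the value in the
    plausible range; reject when no unit interpretation is plausible.
    """
    entry = catalog[test_id]
    if not (value == value and abs(value) != float("inf")) or value <= 0:
        return Verdict("reject")
    unit = catalog.normalize_unit(unit)
    lo, hi = entry.plausible
    lo, hi = lo / widen, hi * widen
    known = unit in entry.units
    if known and lo <= value * entry.factor_to_canonical(unit) <= hi:
        return Verdict("accept", unit)
    others = [
        u for u in entry.units
        if u != unit and lo <= value * entry.factor_to_canonical(u) <= hi
    ]
    if len(others) == 1:
        return Verdict("reinterpret", others[0])
    return Verdict("reject")


def infer_unit(
    test_id: str,
    value: float,
    unit: Optional[str],
    catalog: TestCatalog,
    ambiguity_threshold: float = AMBIGUITY_THRESHOLD,
    widen: float = 1.0,
) -> tuple[str, float, bool]:
    """Resolve a mention to a canonical value with an uncertainty flag.

    Returns ``("ok", canonical_value, uncertain)`` or
    ``("reject", value_as_written, False)``. With a stated unit the
    mistranscription check runs first; reinterpretations are decisive (the
    rare mistyped unit label is corrected, not flagged). With no unit the
    value is read under every unit of the test: a single plausible reading
    is taken at face value; multiple readings that disagree by more than
    ``ambiguity_threshold`` fall back to the canonical-unit reading when
    plausible (flagged uncertain), else the reading closest to the cohort's
    typical level (flagged uncertain).
    """
    entry = catalog[test_id]
    if value <= 0 and entry.kind == "analyte":
        return ("reject", value, False)
    if unit is not None:
        verdict = check_mistranscription(test_id, value, unit, catalog, widen=widen)
        if verdict.kind == "reject":
            return ("reject", value, False)
        return ("ok", value * entry.factor_to_canonical(verdict.unit), False)

    lo, hi = entry.plausible
    lo, hi = lo / widen, hi * widen
    interps = [
        (u, value * entry.factor_to_canonical(u))
        for u in entry.units
        if lo <= value * entry.factor_to_canonical(u) <= hi
    ]
    if not interps:
        return ("reject", value, False)
    if len(interps) == 1:
        return ("ok", interps[0][1], False)
    values = [v for _, v in interps]
    if max(values) <= min(values) * (1.0 + ambiguity_threshold):
        return ("ok", interps[0][1], False)  # readings agree; take canonical
    canonical = [v for u, v in interps if u == entry.unit]
    if canonical:
        return ("ok", canonical[0], True)
    best = min(values, key=lambda v: abs(v - entry.mean) / entry.sd)
    return ("ok", best, True)


def resolve_mention(
    mention: RawMention,
    catalog: TestCatalog,
    ambiguity_threshold: float = AMBIGUITY_THRESHOLD,
    widen: float = 1.0,
) -> LabObservation | Rejection:
    status, value, uncertain = infer_unit(
        mention.test_id, mention.value, mention.unit, catalog,
        ambiguity_threshold=ambiguity_threshold, widen=widen,
    )
    if status == "reject":
        return Rejection(
            test_id=mention.test_id, value=mention.value, unit=mention.unit,
            post_id=mention.post_id, reason="no-plausible-interpretation",
        )
    return LabObservation(
        test_id=mention.test_id, value=value, uncertain=uncertain,
        post_id=mention.post_id, account_id=mention.account_id,
        test_day=mention.post_day,
    )


def extract_observations(
    posts: Iterable[ForumPost],
    catalog: TestCatalog,
    ambiguity_threshold: float = AMBIGUITY_THRESHOLD,
) -> tuple[list[LabObservation], list[Rejection], dict[tuple[str, str], str]]:
    """find_mentions + infer_unit over a stream of posts.

    Returns observations, rejections (never silently dropped), and the
    cycle-phase free text found per (account, day).
    """
    observations, rejections = [], []
    cycle_notes: dict[tuple[str, str], str] = {}
    for post in posts:
        for mention in find_mentions(post, catalog):
            resolved = resolve_mention(
                mention, catalog, ambiguity_threshold=ambiguity_threshold
            )
            if isinstance(resolved, Rejection):
                rejections.append(resolved)
            else:
                observations.append(resolved)
        phase = find_cycle_phase(post)
        if phase:
            cycle_notes.setdefault((post.author, post.day), phase)
    return observations, rejections, cycle_notes


# ---------------------------------------------------------------------------
# test-set assembly

def assemble_test_sets(
    observations: Iterable[LabObservation],
    cycle_notes: Optional[dict[tuple[str, str], str]] = None,
) -> list[TestSet]:
    """Group observations into per-(account, day) test sets.

    Same-day repeats of a (test, value) pair collapse to one observation
    (split posts merge into one set); identical (test, value) pairs reposted
    by the same account on a *later* day are dropped as duplicates; a
    same-day conflict (same test, different values) keeps both values and
    flags the set for reprocessing.
    """
    cycle_notes = cycle_notes or {}
    seen_pairs: dict[tuple[str, str, float], str] = {}  # (account,test,value) -> day
    groups: dict[tuple[str, str], list[LabObservation]] = {}
    for obs in sorted(
        observations, key=lambda o: (o.account_id, o.test_day, o.test_id, o.post_id)
    ):
        key = (obs.account_id, obs.test_id, obs.value)
        first_day = seen_pairs.setdefault(key, obs.test_day)
        if obs.test_day != first_day:
            continue  # verbatim repost on a later day
        groups.setdefault((obs.account_id, obs.test_day), []).append(obs)

    sets = []
    for (account, day), group in sorted(groups.items()):
        merged: list[LabObservation] = []
        conflict = False
        seen_values: dict[tuple[str, float], bool] = {}
        per_test: dict[str, float] = {}
        for obs in group:
            vkey = (obs.test_id, obs.value)
            if vkey in seen_values:
                continue  # same-day duplicate of the same value
            seen_values[vkey] = True
            if obs.test_id in per_test and per_test[obs.test_id] != obs.value:
                conflict = True
            per_test.setdefault(obs.test_id, obs.value)
            merged.append(obs)
        # demographics populate the set fields but also stay observations so
        # cohort summaries see them
        ts = TestSet(
            account_id=account,
            test_day=day,
            observations=merged,
            cycle_phase=cycle_notes.get((account, day)),
            needs_reprocess=conflict,
        )
        for o in merged:
            if o.test_id == "age":
                ts.age = o.value
            elif o.test_id == "bmi":
                ts.bmi = o.value
        sets.append(ts)
    return sets


def compute_derived(ts: TestSet) -> TestSet:
    """Add LH/FSH and HOMA-IR when computable and not already posted.

    Posted ratios/indices are never overwritten. HOMA-IR uses fasting
    insulin (mU/L) x fasting glucose (mg/dL) / 405.
    """
    lh, fsh = ts.value_of("lh"), ts.value_of("fsh")
    if not ts.has("lh_fsh") and lh is not None and fsh is not None:
        if fsh > 0:
            _append_derived(ts, "lh_fsh", lh / fsh, ("lh", "fsh"))
        else:
            log.warning("FSH is 0 for %s/%s; LH/FSH omitted",
                        ts.account_id, ts.test_day)
    fi, fpg = ts.value_of("fi"), ts.value_of("fpg")
    if not ts.has("homa_ir") and fi is not None and fpg is not None:
        _append_derived(ts, "homa_ir", fi * fpg / 405.0, ("fi", "fpg"))
    return ts


def _append_derived(ts: TestSet, test_id: str, value: float,
                    operands: tuple[str, ...]) -> None:
    parents = [o for o in ts.observations if o.test_id in operands]
    ts.observations.append(
        LabObservation(
            test_id=test_id,
            value=value,
            uncertain=any(p.uncertain for p in parents),
            post_id=parents[0].post_id,
            account_id=ts.account_id,
            test_day=ts.test_day,
        )
    )
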