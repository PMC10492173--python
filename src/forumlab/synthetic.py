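"""Seeded synthetic forum corpora with ground truth.

The generator emulates the statistical and textual structure of a patient
forum where members post laboratory panels in heterogeneous phrasings: full
test names with units, bare abbreviations, values with no unit, alternate
units, occasional mistyped unit labels, panels split across two same-day
posts, and verbatim reposts on later days — all buried among distractor
posts that discuss symptoms and treatment but carry no results.

Every rendered number is an exact unit conversion of a latent value drawn
from the test catalog's per-test distribution (lognormal for right-skewed
analytes, zero-truncated normal otherwise), rounded to lab-typical
precision. The ground truth records, per post, every embedded (test, true
canonical value) pair together with the rendered unit and a tolerance
reflecting the rounding, so downstream recovery can be scored exactly.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from scipy import stats

from .catalog import TestCatalog, TestEntry, CatalogError, plausible_interpretations
from .types import ForumPost

STYLES = (
    "full-name-with-unit",
    "abbreviation-with-unit",
    "no-unit",
    "alternate-unit",
    "mistyped-unit",
    "split-pair",
    "duplicate-repost",
    "distractor",
)

#: Default style mix. The real corpus's style distribution is unknown; this
#: mix keeps roughly half the corpus distractors and spreads the result
#: styles with rare mistypes, mirroring how rarely mistranscribed units
#: occur in practice.
DEFAULT_STYLE_MIX = {
    "distractor": 0.55,
    "full-name-with-unit": 0.10,
    "abbreviation-with-unit": 0.12,
    "no-unit": 0.08,
    "alternate-unit": 0.06,
    "mistyped-unit": 0.01,
    "split-pair": 0.05,
    "duplicate-repost": 0.03,
}

_EPOCH_2016 = 1451606400  # 2016-01-01 UTC
_FIVE_YEARS = 5 * 365 * 86400
_DAY = 86400


class GeneratorError(ValueError):
    pass


@dataclass(frozen=True)
class TruthMention:
    """One embedded lab value: what was rendered and what it truly is."""

    test_id: str
    true_value: float       # canonical unit, pre-rounding
    rendered_value: float   # number as written in the post
    unit: Optional[str]     # unit label as written (None for no-unit style)
    style: str
    tol: float              # |extracted - true| tolerance from rounding


@dataclass
class GroundTruth:
    """post id -> mentions; contains_results iff any mention was rendered."""

    posts: dict[str, list[TruthMention]] = field(default_factory=dict)

    def contains_results(self, post_id: str) -> bool:
        return bool(self.posts[post_id])

    def labels(self) -> dict[str, bool]:
        return {pid: bool(m) for pid, m in self.posts.items()}

    def all_mentions(self) -> list[tuple[str, TruthMention]]:
        return [(pid, m) for pid, ms in self.posts.items() for m in ms]

    def to_json_dict(self) -> dict:
        return {
            pid: {
                "contains_results": bool(ms),
                "mentions": [
                    {
                        "test_id": m.test_id,
                        "true_value": m.true_value,
                        "rendered_value": m.rendered_value,
                        "unit": m.unit,
                        "style": m.style,
                        "tol": m.tol,
                    }
                    for m in ms
                ],
            }
            for pid, ms in self.posts.items()
        }

    @classmethod
    def from_json_dict(cls, raw: dict) -> "GroundTruth":
        gt = cls()
        for pid, rec in raw.items():
            gt.posts[pid] = [
                TruthMention(
                    test_id=m["test_id"],
                    true_value=m["true_value"],
                    rendered_value=m["rendered_value"],
                    unit=m["unit"],
                    style=m["style"],
                    tol=m["tol"],
                )
                for m in rec["mentions"]
            ]
        return gt


class LabPanelSpec:
    """Per-test latent distributions, prevalences and units for the
    generator; by default taken straight from the test catalog."""

    def __init__(self, catalog: TestCatalog):
        self.catalog = catalog
        for entry in catalog:
            if entry.sd <= 0:
                raise GeneratorError(f"{entry.test_id}: nonpositive scale")

    @classmethod
    def default(cls) -> "LabPanelSpec":
        return cls(TestCatalog.default())

    def entries(self) -> list[TestEntry]:
        return list(self.catalog)

    def draw_value(self, entry: TestEntry, rng: np.random.Generator) -> float:
        """One latent value from the test's distribution, canonical unit."""
        m, s = entry.mean, entry.sd
        if entry.dist == "lognormal":
            sigma2 = math.log(1.0 + (s / m) ** 2)
            mu = math.log(m) - sigma2 / 2.0
            return float(math.exp(rng.normal(mu, math.sqrt(sigma2))))
        # normal truncated at 0 (demographics truncated at their plausible low)
        lo = entry.plausible[0] if entry.kind == "demographic" else 0.0
        a = (lo - m) / s
        u = rng.uniform(stats.norm.cdf(a), 1.0)
        return float(m + s * stats.norm.ppf(u))


@dataclass
class SyntheticPerson:
    """One forum account with latent per-day lab panels."""

    account_id: str
    age: float
    bmi: float
    panels: list[dict[str, float]]  # one latent panel per test day

    def __post_init__(self) -> None:
        if self.age <= 0 or self.bmi <= 0:
            raise GeneratorError("age and BMI must be positive")

    @property
    def panel(self) -> dict[str, float]:
        return self.panels[0]

    @property
    def n_test_days(self) -> int:
        return len(self.panels)


def sample_cohort(
    spec: LabPanelSpec,
    n_persons: int,
    seed: int,
    n_days: int = 1,
    force_full_panels: bool = False,
) -> list[SyntheticPerson]:
    """Draw a cohort of synthetic accounts with latent lab panels.

    Tests enter a person's day-panel with the catalog prevalence (always,
    with ``force_full_panels``); latent values are independent across days,
    reflecting treatment and lifestyle changes between test days. Derived
    indices (LH/FSH, HOMA-IR) are computed from their operands when both are
    present, else drawn from their own distributions.
    """
    if n_persons < 1:
        raise GeneratorError("n_persons must be >= 1")
    rng = np.random.default_rng(seed)
    persons = []
    entries = spec.entries()
    for i in range(n_persons):
        age = spec.draw_value(spec.catalog["age"], rng)
        bmi = spec.draw_value(spec.catalog["bmi"], rng)
        panels = []
        for _ in range(n_days):
            panel: dict[str, float] = {}
            for entry in entries:
                if entry.kind == "demographic":
                    continue
                if force_full_panels or rng.uniform() < entry.prevalence:
                    panel[entry.test_id] = spec.draw_value(entry, rng)
            if "lh_fsh" in panel and "lh" in panel and "fsh" in panel:
                panel["lh_fsh"] = panel["lh"] / panel["fsh"]
            if "homa_ir" in panel and "fi" in panel and "fpg" in panel:
                panel["homa_ir"] = panel["fi"] * panel["fpg"] / 405.0
            if not panel:  # analyte posts need at least one test
                entry = entries[int(rng.integers(len(entries)))]
                while entry.kind == "demographic":
                    entry = entries[int(rng.integers(len(entries)))]
                panel[entry.test_id] = spec.draw_value(entry, rng)
            panels.append(panel)
        persons.append(
            SyntheticPerson(
                account_id=f"user{i:05d}", age=age, bmi=bmi, panels=panels
            )
        )
    return persons


# ---------------------------------------------------------------------------
# rendering

_TITLES = [
    "Lab results are in",
    "Confused about my labs",
    "Bloodwork back - thoughts?",
    "New labs after 3 months",
    "Are these numbers normal for pcos?",
    "Endo appointment follow up",
]

_INTROS = [
    "Finally got my results back from the endo.",
    "Posting my numbers in case anyone can help interpret.",
    "These are from last week, fasting.",
    "My doctor did not explain anything so here goes.",
    "Got bloodwork done on cycle day 3.",
]

_OUTROS = [
    "Does anyone else have numbers like these?",
    "Any advice appreciated!",
    "Trying to make sense of all this.",
    "Thanks in advance.",
    "",
]

_DISTRACTORS = [
    "Has anyone tried inositol for their symptoms? Thinking of starting it.",
    "My cystic acne has been so much worse this month, any skincare tips?",
    "Been ttc for 2 years now and feeling really discouraged.",
    "Finally found a doctor who listens to me, so relieved.",
    "The spearmint tea really seems to help with the hair growth.",
    "I lost 10 pounds since starting to walk every day, small wins.",
    "Getting my testosterone tested next week, nervous about the results.",
    "Waiting on my bloodwork, the anxiety is real.",
    "Switched from the pill to metformin last month, adjusting slowly.",
    "Anyone else get terrible cramps around cd 14 even without ovulating?",
    "My dermatologist suggested spironolactone for the hirsutism.",
    "How do you all deal with the fatigue? Coffee stopped working for me.",
    "Just diagnosed last week and feeling overwhelmed by all the info.",
    "Does the keto diet actually help or is it just hype?",
]

_MENTION_TEMPLATES = {
    "named_unit": [
        "{name} was {v} {u}",
        "{name}: {v} {u}",
        "{name} came back at {v} {u}",
    ],
    "named_unit_range": [
        "{name} {v} {u} (range {rl}-{rh})",
    ],
    "no_unit": [
        "{name} was {v}",
        "{name}: {v}",
        "{name} came back at {v}",
    ],
}

_CYCLE_NOTES = ["", "", "", "Tested in the luteal phase.", "This was follicular phase."]


def _round_to(value: float, decimals: int) -> float:
    return float(f"{value:.{decimals}f}")


def _alt_decimals(entry: TestEntry, factor: float) -> int:
    """Rendering precision in an alternate unit: shift the canonical
    precision by the order of magnitude of the conversion factor."""
    return int(min(4, max(0, entry.decimals + round(math.log10(factor)))))


def _fmt(value: float, decimals: int) -> str:
    return f"{value:.{decimals}f}"


def _display_name(entry: TestEntry, rng: np.random.Generator, abbreviated: bool) -> str:
    syns = sorted(entry.synonyms, key=len)
    pool = syns[:2] if abbreviated else syns[-2:]
    name = pool[int(rng.integers(len(pool)))]
    return name.upper() if abbreviated and len(name) <= 5 else name


def _render_mention(
    entry: TestEntry,
    latent: float,
    style: str,
    rng: np.random.Generator,
) -> tuple[str, TruthMention]:
    """One sentence embedding one lab value, plus its truth record."""
    if style in ("full-name-with-unit", "abbreviation-with-unit", "split-pair",
                 "duplicate-repost"):
        abbreviated = style != "full-name-with-unit"
        name = _display_name(entry, rng, abbreviated)
        dec = entry.decimals
        v = _round_to(latent, dec)
        if entry.unit in ("years", "kg/m2", "ratio", "index"):
            unit_str = ""  # unitless quantities are written bare
        elif entry.unit == "percent":
            unit_str = "%"
        else:
            unit_str = entry.unit
        tmpl_pool = (
            _MENTION_TEMPLATES["named_unit"]
            + (_MENTION_TEMPLATES["named_unit_range"] if not abbreviated else [])
        )
        if not unit_str:
            tmpl_pool = _MENTION_TEMPLATES["no_unit"]
        tmpl = tmpl_pool[int(rng.integers(len(tmpl_pool)))]
        text = tmpl.format(
            name=name, v=_fmt(v, dec), u=unit_str,
            rl=_fmt(entry.healthy[0], dec), rh=_fmt(entry.healthy[1], dec),
        )
        truth = TruthMention(
            test_id=entry.test_id, true_value=latent, rendered_value=v,
            unit=unit_str or None, style=style, tol=0.51 * 10.0 ** (-dec),
        )
        return text, truth

    if style == "no-unit":
        name = _display_name(entry, rng, abbreviated=bool(rng.integers(2)))
        dec = entry.decimals
        v = _round_to(latent, dec)
        tmpl = _MENTION_TEMPLATES["no_unit"][int(rng.integers(3))]
        text = tmpl.format(name=name, v=_fmt(v, dec))
        truth = TruthMention(
            test_id=entry.test_id, true_value=latent, rendered_value=v,
            unit=None, style=style, tol=0.51 * 10.0 ** (-dec),
        )
        return text, truth

    if style == "alternate-unit":
        if not entry.alt_units:
            return _render_mention(entry, latent, "abbreviation-with-unit", rng)
        units = sorted(entry.alt_units)
        unit = units[int(rng.integers(len(units)))]
        factor = entry.alt_units[unit]
        dec = _alt_decimals(entry, factor)
        v = _round_to(latent / factor, dec)
        name = _display_name(entry, rng, abbreviated=bool(rng.integers(2)))
        tmpl = _MENTION_TEMPLATES["named_unit"][int(rng.integers(3))]
        text = tmpl.format(name=name, v=_fmt(v, dec), u=unit)
        truth = TruthMention(
            test_id=entry.test_id, true_value=latent, rendered_value=v,
            unit=unit, style=style, tol=0.51 * 10.0 ** (-dec) * factor,
        )
        return text, truth

    if style == "mistyped-unit":
        # Number written on an alternate-unit scale but labeled with the
        # canonical unit (the classic swap). Only emitted when the swap is
        # recoverable: the number must be implausible under the stated unit
        # and plausible under exactly one unit — the true one.
        for unit in sorted(entry.alt_units):
            factor = entry.alt_units[unit]
            dec = _alt_decimals(entry, factor)
            v = _round_to(latent / factor, dec)
            interp = plausible_interpretations(entry, v)
            if len(interp) == 1 and interp[0][0] == unit and not entry.is_plausible(v):
                name = _display_name(entry, rng, abbreviated=True)
                tmpl = _MENTION_TEMPLATES["named_unit"][int(rng.integers(3))]
                text = tmpl.format(name=name, v=_fmt(v, dec), u=entry.unit)
                truth = TruthMention(
                    test_id=entry.test_id, true_value=latent, rendered_value=v,
                    unit=entry.unit, style=style,
                    tol=0.51 * 10.0 ** (-dec) * factor,
                )
                return text, truth
        return _render_mention(entry, latent, "abbreviation-with-unit", rng)

    raise GeneratorError(f"unknown style {style!r}")


def _demographic_sentences(
    person: SyntheticPerson, spec: LabPanelSpec, rng: np.random.Generator
) -> tuple[list[str], list[TruthMention]]:
    sentences, truths = [], []
    for test_id, value in (("age", person.age), ("bmi", person.bmi)):
        entry = spec.catalog[test_id]
        if rng.uniform() < entry.prevalence:
            dec = entry.decimals
            v = _round_to(value, dec)
            label = "age" if test_id == "age" else ("BMI" if rng.integers(2) else "bmi")
            sentences.append(f"{label} {_fmt(v, dec)}")
            truths.append(
                TruthMention(
                    test_id=test_id, true_value=value, rendered_value=v,
                    unit=None, style="demographic", tol=0.51 * 10.0 ** (-dec),
                )
            )
    return sentences, truths


def render_post(
    person: SyntheticPerson,
    style: str,
    seed: int,
    spec: Optional[LabPanelSpec] = None,
    post_id_base: str = "p0",
    base_utc: int = _EPOCH_2016,
) -> tuple[list[ForumPost], dict[str, list[TruthMention]]]:
    """Render one posting event for ``person`` in the given style.

    Most styles yield a single post; ``split-pair`` yields two same-day
    posts whose union is one panel, and ``duplicate-repost`` yields the same
    panel verbatim on two different days. Returns the posts and their
    ground-truth entries.
    """
    if style not in STYLES:
        raise GeneratorError(f"unknown style {style!r}")
    spec = spec or LabPanelSpec.default()
    rng = np.random.default_rng(seed)
    day_start = base_utc - (base_utc % _DAY)
    tod = int(rng.integers(6 * 3600, 23 * 3600))

    if style == "distractor":
        body = _DISTRACTORS[int(rng.integers(len(_DISTRACTORS)))]
        if rng.integers(2):
            body += " " + _DISTRACTORS[int(rng.integers(len(_DISTRACTORS)))]
        post = ForumPost(
            id=post_id_base, author=person.account_id,
            created_utc=day_start + tod,
            title=_TITLES[int(rng.integers(len(_TITLES)))] if rng.integers(4) == 0
            else "Venting / support needed",
            selftext=body,
        )
        return [post], {post.id: []}

    panel = person.panels[int(rng.integers(person.n_test_days))]
    items = sorted(panel.items())

    def build_body(mention_items, mention_style):
        sentences, truths = [], []
        sentences.append(_INTROS[int(rng.integers(len(_INTROS)))])
        for test_id, latent in mention_items:
            entry = spec.catalog[test_id]
            text, truth = _render_mention(entry, latent, mention_style, rng)
            sentences.append(text + ".")
            truths.append(truth)
        demo_sents, demo_truths = _demographic_sentences(person, spec, rng)
        sentences.extend(s + "." for s in demo_sents)
        truths.extend(demo_truths)
        note = _CYCLE_NOTES[int(rng.integers(len(_CYCLE_NOTES)))]
        if note:
            sentences.append(note)
        outro = _OUTROS[int(rng.integers(len(_OUTROS)))]
        if outro:
            sentences.append(outro)
        return " ".join(sentences), truths

    title = _TITLES[int(rng.integers(len(_TITLES)))]

    if style == "split-pair":
        half = max(1, len(items) // 2)
        first, second = items[:half], items[half:] or items[:1]
        posts, truth = [], {}
        for k, part in enumerate((first, second)):
            body, truths = build_body(part, style)
            pid = f"{post_id_base}{'ab'[k]}"
            posts.append(
                ForumPost(
                    id=pid, author=person.account_id,
                    created_utc=day_start + tod + k * 1800,  # same UTC day
                    title=title if k == 0 else "Part 2 of my labs",
                    selftext=body,
                )
            )
            truth[pid] = truths
        return posts, truth

    if style == "duplicate-repost":
        body, truths = build_body(items, style)
        later = day_start + int(rng.integers(2, 30)) * _DAY + tod
        posts = [
            ForumPost(id=f"{post_id_base}a", author=person.account_id,
                      created_utc=day_start + tod, title=title, selftext=body),
            ForumPost(id=f"{post_id_base}b", author=person.account_id,
                      created_utc=later, title="Reposting my labs for visibility",
                      selftext=body),
        ]
        return posts, {posts[0].id: truths, posts[1].id: list(truths)}

    body, truths = build_body(items, style)
    post = ForumPost(
        id=post_id_base, author=person.account_id,
        created_utc=day_start + tod, title=title, selftext=body,
    )
    return [post], {post.id: truths}


def generate_corpus(
    spec: Optional[LabPanelSpec] = None,
    style_mix: Optional[dict[str, float]] = None,
    n_posts: int = 2000,
    seed: int = 0,
) -> tuple[list[ForumPost], GroundTruth]:
    """Generate a corpus of ``n_posts`` posts with ground truth.

    Posting events are drawn from the style mix; two-post styles count both
    posts toward ``n_posts`` (falling back to a single-post style when one
    slot remains). Deterministic given (spec, mix, n_posts, seed).
    """
    spec = spec or LabPanelSpec.default()
    mix = dict(DEFAULT_STYLE_MIX if style_mix is None else style_mix)
    for s, w in mix.items():
        if s not in STYLES:
            raise GeneratorError(f"unknown style {s!r}")
        if w < 0:
            raise GeneratorError("style weights must be nonnegative")
    total = sum(mix.values())
    if n_posts and total <= 0:
        raise GeneratorError("style mix needs at least one positive weight")
    if n_posts == 0:
        return [], GroundTruth()

    rng = np.random.default_rng(seed)
    styles = sorted(mix)
    weights = np.array([mix[s] for s in styles]) / total

    # decide posting events first, then sample exactly the cohort needed
    events: list[str] = []
    remaining = n_posts
    while remaining > 0:
        style = styles[int(rng.choice(len(styles), p=weights))]
        if style in ("split-pair", "duplicate-repost") and remaining < 2:
            style = "abbreviation-with-unit"
        events.append(style)
        remaining -= 2 if style in ("split-pair", "duplicate-repost") else 1

    persons = sample_cohort(
        spec, len(events), seed=int(rng.integers(2**31)), n_days=2
    )
    posts: list[ForumPost] = []
    truth = GroundTruth()
    for i, style in enumerate(events):
        base_utc = _EPOCH_2016 + int(rng.integers(_FIVE_YEARS))
        new_posts, new_truth = render_post(
            persons[i], style, seed=int(rng.integers(2**31)), spec=spec,
            post_id_base=f"p{i:06d}", base_utc=base_utc,
        )
        posts.extend(new_posts)
        for pid, ms in new_truth.items():
            truth.posts[pid] = ms
    return posts, truth


# ---------------------------------------------------------------------------
# serialization (Pushshift-dialect JSONL + JSON truth)

def write_posts_jsonl(posts: list[ForumPost], path: str | Path) -> None:
    with open(path, "w") as fh:
        for post in posts:
            fh.write(json.dumps(post.to_json_dict()) + "\n")


def write_truth_json(truth: GroundTruth, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(truth.to_json_dict(), fh, indent=1)


def read_truth_json(path: str | Path) -> GroundTruth:
    with open(path) as fh:
        return GroundTruth.from_json_dict(json.load(fh))
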