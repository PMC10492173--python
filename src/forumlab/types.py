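"""Core domain records shared across pipeline stages.

The analysis unit is the *test set*: every laboratory observation attributed
to one forum account on one calendar day. Repeated testing by the same
account on different days yields distinct test sets, because between tests
people frequently change treatment or lifestyle.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional


@dataclass(frozen=True)
class ForumPost:
    """One forum submission in the Pushshift record shape."""

    id: str
    author: str
    created_utc: int
    title: str
    selftext: str

    def __post_init__(self) -> None:
        if self.created_utc < 0:
            raise ValueError("created_utc must be >= 0")

    @property
    def text(self) -> str:
        return f"{self.title}\n{self.selftext}".strip()

    @property
    def day(self) -> str:
        """UTC calendar day, the proxy for the laboratory test date."""
        import datetime as _dt

        return _dt.datetime.fromtimestamp(
            self.created_utc, tz=_dt.timezone.utc
        ).strftime("%Y-%m-%d")

    def to_json_dict(self) -> dict:
        return {
            "id": self.id,
            "author": self.author,
            "created_utc": self.created_utc,
            "title": self.title,
            "selftext": self.selftext,
        }


@dataclass(frozen=True)
class RawMention:
    """A (test string, number, optional unit) hit inside one post."""

    post_id: str
    account_id: str
    post_day: str
    test_id: str
    matched_text: str
    value: float
    unit: Optional[str]
    span: tuple[int, int]


@dataclass
class LabObservation:
    """One canonicalized laboratory result."""

    test_id: str
    value: float
    uncertain: bool
    post_id: str
    account_id: str
    test_day: str

    def to_json_dict(self) -> dict:
        return asdict(self)


@dataclass
class Rejection:
    """A mention that could not be resolved to a plausible observation."""

    test_id: str
    value: float
    unit: Optional[str]
    post_id: str
    reason: str


@dataclass
class TestSet:
    """All observations for one account on one day — one point of data."""

    __test__ = False  # domain class, not a pytest case

    account_id: str
    test_day: str
    observations: list[LabObservation] = field(default_factory=list)
    age: Optional[float] = None
    bmi: Optional[float] = None
    cycle_phase: Optional[str] = None
    needs_reprocess: bool = False

    def value_of(self, test_id: str) -> Optional[float]:
        for obs in self.observations:
            if obs.test_id == test_id:
                return obs.value
        return None

    def has(self, test_id: str) -> bool:
        return any(o.test_id == test_id for o in self.observations)


@dataclass(frozen=True)
class CohortSummary:
    """(n, mean, SD) for one test in one cohort."""

    test_id: str
    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.sd < 0:
            raise ValueError("SD must be >= 0")
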