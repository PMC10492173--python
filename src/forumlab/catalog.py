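"""Laboratory test catalog: units, synonyms, conversion factors, ranges.

The catalog is a versioned YAML data file shipped with the package. Every
unit conversion is a positive multiplicative factor to the test's canonical
unit; every test carries two ranges in canonical units:

* ``healthy`` — the standard clinical reference range, and
* ``plausible`` — the healthy range widened to admit the dysregulation seen
  in PCOS cohorts. Unit inference and mistranscription checks test values
  against the plausible range, never the healthy one, so that genuinely
  abnormal results are not discarded as transcription errors.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional

import yaml


class CatalogError(ValueError):
    """Raised for malformed catalog data or unknown tests/units."""


@dataclass(frozen=True)
class TestEntry:
    __test__ = False  # domain class, not a pytest case

    test_id: str
    name: str
    synonyms: tuple[str, ...]
    unit: str
    alt_units: dict[str, float]
    healthy: tuple[float, float]
    plausible: tuple[float, float]
    kind: str
    decimals: int
    dist: str
    mean: float
    sd: float
    prevalence: float

    def __post_init__(self) -> None:
        if not self.synonyms:
            raise CatalogError(f"{self.test_id}: synonyms must be non-empty")
        if self.sd <= 0:
            raise CatalogError(f"{self.test_id}: scale must be > 0")
        if not 0 <= self.prevalence <= 1:
            raise CatalogError(f"{self.test_id}: prevalence outside [0,1]")
        lo, hi = self.healthy
        plo, phi = self.plausible
        if not lo < hi:
            raise CatalogError(f"{self.test_id}: healthy range inverted")
        if not (plo <= lo and hi <= phi):
            raise CatalogError(
                f"{self.test_id}: healthy range not within plausible range"
            )
        for unit, factor in self.alt_units.items():
            if not (math.isfinite(factor) and factor > 0):
                raise CatalogError(f"{self.test_id}: bad factor for {unit}")

    @property
    def units(self) -> tuple[str, ...]:
        """Canonical unit first, then alternates."""
        return (self.unit, *self.alt_units)

    def factor_to_canonical(self, unit: str) -> float:
        if unit == self.unit:
            return 1.0
        try:
            return self.alt_units[unit]
        except KeyError:
            raise CatalogError(
                f"unit {unit!r} is not known for test {self.test_id!r}"
            ) from None

    def is_plausible(self, canonical_value: float) -> bool:
        lo, hi = self.plausible
        return lo <= canonical_value <= hi


class TestCatalog:
    """All catalog entries plus unit-alias normalization."""

    __test__ = False  # domain class, not a pytest case

    def __init__(self, entries: dict[str, TestEntry], unit_aliases: dict[str, str]):
        self.entries = entries
        self.unit_aliases = unit_aliases

    def __contains__(self, test_id: str) -> bool:
        return test_id in self.entries

    def __getitem__(self, test_id: str) -> TestEntry:
        try:
            return self.entries[test_id]
        except KeyError:
            raise CatalogError(f"unknown test {test_id!r}") from None

    def __iter__(self):
        return iter(self.entries.values())

    @property
    def test_ids(self) -> list[str]:
        return list(self.entries)

    def normalize_unit(self, unit: str) -> str:
        """Map a free-text unit token to its catalog spelling."""
        return self.unit_aliases.get(unit.strip().lower(), unit.strip())

    def analytes(self) -> list[TestEntry]:
        return [e for e in self if e.kind == "analyte"]

    @classmethod
    def from_file(cls, path: str | Path) -> "TestCatalog":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls._from_raw(raw)

    @classmethod
    def default(cls) -> "TestCatalog":
        ref = resources.files("forumlab.data").joinpath("catalog.yaml")
        raw = yaml.safe_load(ref.read_text())
        return cls._from_raw(raw)

    @classmethod
    def _from_raw(cls, raw: dict) -> "TestCatalog":
        entries = {}
        for test_id, spec in raw["tests"].items():
            entries[test_id] = TestEntry(
                test_id=test_id,
                name=spec["name"],
                synonyms=tuple(str(s).lower() for s in spec["synonyms"]),
                unit=spec["unit"],
                alt_units={str(u): float(f) for u, f in spec.get("alt_units", {}).items()},
                healthy=tuple(float(x) for x in spec["healthy"]),
                plausible=tuple(float(x) for x in spec["plausible"]),
                kind=spec.get("kind", "analyte"),
                decimals=int(spec.get("decimals", 1)),
                dist=spec.get("dist", "normal"),
                mean=float(spec["mean"]),
                sd=float(spec["sd"]),
                prevalence=float(spec.get("prevalence", 0.0)),
            )
        return cls(entries, {k.lower(): v for k, v in raw.get("unit_aliases", {}).items()})


def plausible_interpretations(
    entry: TestEntry, value: float, catalog: Optional[TestCatalog] = None
) -> list[tuple[str, float]]:
    """All (unit, canonical value) readings of ``value`` that land in the
    condition-plausible range, canonical unit listed first."""
    out = []
    for unit in entry.units:
        canonical = value * entry.factor_to_canonical(unit)
        if entry.is_plausible(canonical):
            out.append((unit, canonical))
    return out
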