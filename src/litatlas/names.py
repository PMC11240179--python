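"""Historical name–gender lookup tables.

Author gender is inferred from the first name together with the publication
year, because naming practices drift: a name can be majority-male in one era
and majority-female a few decades later ("Leslie" is the textbook example).
The lookup is a plain table mapping (forename, year) to the proportion of
name bearers recorded as female in that year; any model with that interface
can be plugged in.

The packaged table (``data/synthetic_name_gender.tsv``) is a small synthetic
illustration covering 1930–2012 — it is NOT derived from Social Security
Administration records and should be replaced with a real table for any
substantive analysis.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

__all__ = ["NameGenderTable", "builtin_name_table"]


@dataclass
class NameGenderTable:
    """Map (forename, year) -> proportion female, clamped to a covered year range.

    ``entries`` maps a forename to two parallel arrays: anchor years (sorted)
    and the proportion of female bearers at each anchor. Lookups outside the
    covered range are clamped to the nearest covered year; lookups between
    anchors use the nearest anchor.
    """

    entries: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)

    @property
    def year_range(self) -> tuple[int, int]:
        lo = min(int(y[0]) for y, _ in self.entries.values())
        hi = max(int(y[-1]) for y, _ in self.entries.values())
        return lo, hi

    def prop_female(self, name: str, year: int) -> float | None:
        """Proportion of female bearers of ``name`` at ``year``; None if unknown."""
        rec = self.entries.get(name)
        if rec is None:
            return None
        years, props = rec
        year = min(max(year, int(years[0])), int(years[-1]))
        i = int(np.argmin(np.abs(years - year)))
        return float(props[i])

    def names(self, year: int, female: bool) -> list[str]:
        """Names whose majority gender at ``year`` matches ``female``."""
        out = []
        for name in sorted(self.entries):
            p = self.prop_female(name, year)
            if (p >= 0.5) == female:
                out.append(name)
        return out

    @classmethod
    def from_rows(cls, rows) -> "NameGenderTable":
        """Build from (name, year, proportion_female) triples."""
        by_name: dict[str, list[tuple[int, float]]] = {}
        for name, year, p in rows:
            p = float(p)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"proportion out of [0,1] for {name!r}: {p}")
            by_name.setdefault(str(name), []).append((int(year), p))
        entries = {}
        for name, pairs in by_name.items():
            pairs.sort()
            years = np.array([y for y, _ in pairs], dtype=float)
            props = np.array([p for _, p in pairs], dtype=float)
            entries[name] = (years, props)
        return cls(entries)


def builtin_name_table() -> NameGenderTable:
    """Load the packaged synthetic name–gender table (anchors 1930–2012).

    Includes at least one name ("Leslie") whose majority gender flips over
    the covered period. Synthetic illustration data, not SSA records.
    """
    ref = resources.files("litatlas").joinpath("data/synthetic_name_gender.tsv")
    rows = []
    with ref.open("r", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            rows.append((row["name"], int(row["year"]), float(row["prop_female"])))
    return NameGenderTable.from_rows(rows)
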