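"""Levan chromosome categories, standardized karyotype formulas and
nearest-chromosome assignment.

Categories follow the Levan nomenclature on the centromeric index i:

    M   metacentric sensu stricto      i = 50 exactly (in practice [49.95, 50])
    m   metacentric                    i in [37.505, 49.95)
    sm  submetacentric                 i in [25.005, 37.505)
    st  subtelocentric                 i in [12.505, 25.005)
    a   acro-/telocentric              i in (0, 12.505)
    T   telocentric sensu stricto      i = 0 exactly

The published boundary table prints gapped two-decimal ranges (st ends at
25.00, sm starts at 25.01); the scheme here places each cut at the midpoint
of the printed gap with half-open intervals, so every i in [0, 50] gets
exactly one category.  The table is internally inconsistent at arm ratio
r = 3.00 (listed sm, though i = 100/(3+1) = 25.00 is listed st); this toolkit
classifies on i only, which is the convention the index was introduced for.

A standardized karyotype is the ordered list of per-chromosome median indices
(Q2) with their categories.  Its formula concatenates the nonzero diploid
category counts in the fixed order M, m, sm, st, a, T ("24m+40sm+2st+2a+32T");
the shortened formula merges st, a and T into one "st-T" terminal count.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence, Union

from .errors import FormulaError, KaryostdError

CATEGORY_ORDER = ("M", "m", "sm", "st", "a", "T")


@dataclass(frozen=True)
class CategoryScheme:
    """Half-open category cuts on i; T and M are the exact edge categories.

    ``cuts`` are the ascending inner boundaries (a/st, st/sm, sm/m, m/M); an i
    equal to a cut belongs to the category above it.
    """

    a_st: float = 12.505
    st_sm: float = 25.005
    sm_m: float = 37.505
    m_M: float = 49.95

    def __post_init__(self) -> None:
        cuts = (self.a_st, self.st_sm, self.sm_m, self.m_M)
        if not all(0 < lo < hi < 50 for lo, hi in zip(cuts, cuts[1:])) or not (
            0 < self.a_st and self.m_M < 50
        ):
            raise KaryostdError(f"category cuts must be strictly ascending in (0, 50): {cuts}")

    def classify(self, i: float) -> str:
        if not 0 <= i <= 50:
            raise KaryostdError(f"centromeric index {i} outside [0, 50]")
        if i == 0:
            return "T"
        if i < self.a_st:
            return "a"
        if i < self.st_sm:
            return "st"
        if i < self.sm_m:
            return "sm"
        if i < self.m_M:
            return "m"
        return "M"


LEVAN = CategoryScheme()


def classify(i: float, scheme: CategoryScheme = LEVAN) -> str:
    """Levan category of a centromeric index (one of M, m, sm, st, a, T)."""
    return scheme.classify(i)


@dataclass(frozen=True)
class KaryotypeEntry:
    index: int  # chr_k
    median_i: float  # Q2 of the pooled indices
    category: str


@dataclass(frozen=True)
class StandardKaryotype:
    """Ordered standardized karyotype of one species."""

    species_id: str
    entries: tuple[KaryotypeEntry, ...]
    ploidy_factor: int = 2

    @property
    def n_chromosomes(self) -> int:
        """Total chromosome number (2n at the default ploidy factor)."""
        return self.ploidy_factor * len(self.entries)

    def counts(self) -> dict[str, int]:
        """Diploid category counts in fixed order, zero categories included."""
        c = {cat: 0 for cat in CATEGORY_ORDER}
        for e in self.entries:
            c[e.category] += self.ploidy_factor
        return c

    @property
    def formula(self) -> str:
        return format_formula(self.counts())

    @property
    def shortened_formula(self) -> str:
        return format_formula(self.counts(), shortened=True)

    def to_dict(self) -> dict:
        return {
            "species": self.species_id,
            "ploidy_factor": self.ploidy_factor,
            "formula": self.formula,
            "shortened_formula": self.shortened_formula,
            "entries": [
                {"chromosome": e.index, "median_i": e.median_i, "category": e.category}
                for e in self.entries
            ],
        }

    def to_json(self, path: Union[str, Path, None] = None) -> str:
        text = json.dumps(self.to_dict(), indent=1)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "StandardKaryotype":
        return cls(
            species_id=d["species"],
            ploidy_factor=int(d.get("ploidy_factor", 2)),
            entries=tuple(
                KaryotypeEntry(int(e["chromosome"]), float(e["median_i"]), e["category"])
                for e in d["entries"]
            ),
        )

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "StandardKaryotype":
        return cls.from_dict(json.loads(Path(path).read_text()))


def build_karyotype(
    species_id: str,
    medians: Sequence[float],
    scheme: CategoryScheme = LEVAN,
    ploidy_factor: int = 2,
) -> StandardKaryotype:
    """Classify a non-increasing sequence of per-chromosome medians.

    The medians must already be sorted non-increasing (chr1 is the most
    metacentric identity by construction of the ranking step).
    """
    meds = [float(m) for m in medians]
    if not meds:
        raise KaryostdError("cannot build a karyotype from zero chromosomes")
    if any(a < b for a, b in zip(meds, meds[1:])):
        raise KaryostdError("medians must be sorted non-increasing (chr1 first)")
    entries = tuple(
        KaryotypeEntry(index=k + 1, median_i=m, category=scheme.classify(m))
        for k, m in enumerate(meds)
    )
    return StandardKaryotype(
        species_id=species_id, entries=entries, ploidy_factor=ploidy_factor
    )


def format_formula(counts: dict[str, int], shortened: bool = False) -> str:
    """Render category counts as a karyotype formula string.

    Fixed category order M, m, sm, st, a, T; zero-count categories are
    omitted.  ``shortened`` merges st + a + T into a single "st-T" range
    count (e.g. ``24m+40sm+36st-T``).
    """
    if shortened:
        merged = dict(counts)
        terminal = merged.pop("st", 0) + merged.pop("a", 0) + merged.pop("T", 0)
        parts = [f"{merged[c]}{c}" for c in ("M", "m", "sm") if merged.get(c, 0)]
        if terminal:
            parts.append(f"{terminal}st-T")
        return "+".join(parts)
    return "+".join(f"{counts[c]}{c}" for c in CATEGORY_ORDER if counts.get(c, 0))


_FORMULA_TERM = re.compile(r"^(\d+)(M|m|sm|st|a|T)$")


def parse_formula(formula: str) -> dict[str, int]:
    """Parse ``24m+40sm+2st+2a+32T`` back into category counts.

    Inverse of :func:`format_formula` for the unshortened form.
    """
    counts = {cat: 0 for cat in CATEGORY_ORDER}
    for term in formula.split("+"):
        m = _FORMULA_TERM.match(term.strip())
        if not m:
            raise FormulaError(f"unparseable formula term {term!r} in {formula!r}")
        n, cat = int(m.group(1)), m.group(2)
        if counts[cat]:
            raise FormulaError(f"category {cat} repeated in {formula!r}")
        counts[cat] = n
    return counts


@dataclass(frozen=True)
class Assignment:
    """Result of matching an observed i to a standardized karyotype.

    A unique nearest chromosome gives a single index; an observed value whose
    nearest median is 0 matches the whole telocentric block and is reported as
    the contiguous index range instead.
    """

    first: int
    last: int

    @property
    def is_range(self) -> bool:
        return self.last != self.first

    @property
    def indices(self) -> range:
        return range(self.first, self.last + 1)

    def __str__(self) -> str:
        if self.is_range:
            return f"chr{self.first}-{self.last}"
        return f"chr{self.first}"


def assign_to_standard(observed_i: float, karyotype: StandardKaryotype) -> Assignment:
    """Nearest-median chromosome assignment of an externally measured index.

    Used to place chromosomes measured on rehybridised (e.g. FISH) metaphases
    onto the standardized karyotype: the chromosome whose median i is closest
    to the observation is returned, ties going to the smaller index.  When the
    nearest median is 0 the observation is compatible with every telocentric
    identity, so the whole all-T block is returned as a range.
    """
    if not 0 <= observed_i <= 50:
        raise KaryostdError(f"observed i {observed_i} outside [0, 50]")
    if not karyotype.entries:
        raise KaryostdError("empty karyotype")
    best = min(
        karyotype.entries, key=lambda e: (abs(e.median_i - observed_i), e.index)
    )
    if best.median_i == 0:
        zero = [e.index for e in karyotype.entries if e.median_i == 0]
        return Assignment(first=min(zero), last=max(zero))
    return Assignment(first=best.index, last=best.index)
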