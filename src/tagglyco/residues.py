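"""Residue registry, label schemes, and glycan-composition mass arithmetic.

All N-glycans share the trimannosyl-chitobiose core (Man)3(GlcNAc)2 ("M3
core"); compositions are expressed as counts of non-core residues plus a
core flag.  Monoisotopic residue masses are used throughout; the observed
[M+Na]+ m/z of a reducing-end-labeled glycan is

    sum(count_i * residue_mass_i) + core + water + label_delta + adduct

where ``core`` is 3*Hex + 2*HexNAc residue masses.  Sialic acids appear as
linkage-resolved residues: after linkage-specific alkylamidation (SALSA),
alpha-2,6-linked sialic acids carry an isopropylamide (+41.0891 relative to
the free acid residue after amidation chemistry) and alpha-2,3/2,8-linked
ones a methylamide, so the two linkage classes differ by exactly
28.0313 Da and can be told apart in MS1.
"""

from __future__ import annotations

import csv
import hashlib
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Mapping

__all__ = [
    "WATER",
    "SODIUM",
    "BOA_DELTA",
    "Residue",
    "LabelScheme",
    "BOA_SODIUM",
    "Composition",
    "Registry",
    "default_registry",
    "CompositionError",
]

#: Monoisotopic mass of H2O in Da (free reducing terminus).
WATER = 18.010565
#: Monoisotopic mass of Na (sodium adduct; the charge carrier for [M+Na]+).
SODIUM = 22.989770
#: Net mass increment of the O-benzylhydroxylamine (BOA) oxime label:
#: C7H9NO minus the water lost on condensation.
BOA_DELTA = 105.057849

#: Number of hexoses / N-acetylhexosamines in the M3 core.
CORE_HEX = 3
CORE_HEXNAC = 2

#: Width of the fixed-slot composition ID.
N_SLOTS = 15

_CORE_TEXT = "(Man)3(GlcNAc)2"

RESIDUE_CATEGORIES = ("neutral", "deoxyhexose", "acidic", "modification")


class CompositionError(ValueError):
    """Raised for malformed compositions, unknown residues, or bad IDs."""


@dataclass(frozen=True)
class Residue:
    """One monosaccharide or modification unit occupying a registry slot."""

    id: int
    name: str
    mass: float
    description: str = ""
    min_count: int = 0
    max_count: int = 0
    category: str = "neutral"

    def __post_init__(self) -> None:
        if not 1 <= self.id <= N_SLOTS:
            raise ValueError(f"residue id must be in 1..{N_SLOTS}, got {self.id}")
        if self.max_count > 0 and self.mass <= 0:
            raise ValueError(f"residue {self.name!r} has non-positive mass {self.mass}")
        if self.min_count < 0 or self.min_count > self.max_count:
            raise ValueError(
                f"residue {self.name!r}: invalid count range "
                f"{self.min_count}..{self.max_count}"
            )
        if self.category not in RESIDUE_CATEGORIES:
            raise ValueError(f"unknown residue category {self.category!r}")

    @property
    def is_placeholder(self) -> bool:
        return self.max_count == 0


@dataclass(frozen=True)
class LabelScheme:
    """Reducing-end derivatization plus adduct for a whole run.

    ``label_delta`` is the net mass the label adds (formula increment minus
    condensation water); ``include_water`` keeps the free-glycan water term,
    which is present for oxime labels such as BOA.
    """

    name: str
    label_delta: float
    adduct_mass: float
    include_water: bool = True

    @property
    def constant(self) -> float:
        """Total constant K added to every composition's residue-mass sum."""
        k = self.label_delta + self.adduct_mass
        if self.include_water:
            k += WATER
        return k


#: BOA oxime label with sodium adduct — the default derivatization.
BOA_SODIUM = LabelScheme("BOA-Na", label_delta=BOA_DELTA, adduct_mass=SODIUM)

#: Unlabeled free glycan, no adduct (neutral monoisotopic mass).
FREE_GLYCAN = LabelScheme("free", label_delta=0.0, adduct_mass=0.0)


@dataclass(frozen=True)
class Composition:
    """Multiset of non-core residue counts plus the M3-core flag.

    ``counts`` maps registry slot id -> count; zero counts are dropped so
    that equal compositions compare (and hash) equal.
    """

    counts: tuple[tuple[int, int], ...]
    has_core: bool = True

    @classmethod
    def make(cls, counts: Mapping[int, int], has_core: bool = True) -> "Composition":
        items = []
        for rid, n in counts.items():
            if n < 0:
                raise CompositionError(f"negative count {n} for residue id {rid}")
            if n > 0:
                items.append((int(rid), int(n)))
        return cls(tuple(sorted(items)), has_core)

    def as_dict(self) -> dict[int, int]:
        return dict(self.counts)

    def count(self, rid: int) -> int:
        return dict(self.counts).get(rid, 0)

    def total_residues(self) -> int:
        n = sum(c for _, c in self.counts)
        if self.has_core:
            n += CORE_HEX + CORE_HEXNAC
        return n

    def combine(self, other: "Composition") -> "Composition":
        """Count-wise sum; the core is counted once (either side suffices)."""
        merged = self.as_dict()
        for rid, n in other.counts:
            merged[rid] = merged.get(rid, 0) + n
        return Composition.make(merged, self.has_core or other.has_core)


class Registry:
    """Fixed 15-slot table of residues; unused slots are placeholders."""

    def __init__(self, residues: Iterable[Residue]):
        by_id: dict[int, Residue] = {}
        for r in residues:
            if r.id in by_id:
                raise ValueError(f"duplicate residue id {r.id}")
            by_id[r.id] = r
        for slot in range(1, N_SLOTS + 1):
            if slot not in by_id:
                by_id[slot] = Residue(slot, f"res{slot}", 0.0, "unused slot")
        self._slots: tuple[Residue, ...] = tuple(by_id[i] for i in range(1, N_SLOTS + 1))
        self._by_name = {r.name: r for r in self._slots if not r.is_placeholder}
        # core masses come from the Hex / HexNAc slots
        try:
            self._hex = self._by_name["Hex"]
            self._hexnac = self._by_name["HexNAc"]
        except KeyError as exc:
            raise ValueError("registry must define Hex and HexNAc residues") from exc

    def __iter__(self) -> Iterator[Residue]:
        return iter(self._slots)

    def __getitem__(self, rid: int) -> Residue:
        if not 1 <= rid <= N_SLOTS:
            raise CompositionError(f"unknown residue id {rid}")
        return self._slots[rid - 1]

    def by_name(self, name: str) -> Residue:
        try:
            return self._by_name[name]
        except KeyError:
            raise CompositionError(f"unknown residue name {name!r}") from None

    @property
    def active(self) -> tuple[Residue, ...]:
        return tuple(r for r in self._slots if not r.is_placeholder)

    @property
    def core_mass(self) -> float:
        return CORE_HEX * self._hex.mass + CORE_HEXNAC * self._hexnac.mass

    def fingerprint(self) -> str:
        """Stable hash of slot contents, recorded in generated lists."""
        text = ";".join(
            f"{r.id}:{r.name}:{r.mass:.6f}:{r.min_count}-{r.max_count}" for r in self._slots
        )
        return hashlib.sha1(text.encode()).hexdigest()[:12]

    # ------------------------------------------------------------------ mass

    def composition_mass(self, comp: Composition, label: LabelScheme) -> float:
        """Theoretical m/z of a labeled, adducted composition."""
        total = label.constant
        for rid, n in comp.counts:
            residue = self[rid]
            if residue.is_placeholder:
                raise CompositionError(f"unknown residue id {rid}")
            total += n * residue.mass
        if comp.has_core:
            total += self.core_mass
        return total

    # ------------------------------------------------------ text round trip

    def format_composition(self, comp: Composition) -> str:
        """Canonical text such as ``(Hex)2 (6NeuAc)1 + (Man)3(GlcNAc)2``."""
        parts = []
        counts = comp.as_dict()
        for residue in self._slots:
            n = counts.get(residue.id, 0)
            if n:
                if residue.is_placeholder:
                    raise CompositionError(f"unknown residue id {residue.id}")
                parts.append(f"({residue.name}){n}")
        body = " ".join(parts)
        if comp.has_core:
            return f"{body} + {_CORE_TEXT}" if body else _CORE_TEXT
        return body

    _TOKEN = re.compile(r"\(([^)]+)\)(\d+)")

    def parse_composition(self, text: str) -> Composition:
        """Inverse of :meth:`format_composition`."""
        s = text.strip()
        has_core = False
        if s.endswith("+ " + _CORE_TEXT):
            has_core = True
            s = s[: -len("+ " + _CORE_TEXT)].strip()
        elif s == _CORE_TEXT:
            return Composition.make({}, True)
        counts: dict[int, int] = {}
        pos = 0
        while pos < len(s):
            if s[pos] == " ":
                pos += 1
                continue
            m = self._TOKEN.match(s, pos)
            if not m:
                raise CompositionError(
                    f"cannot parse composition {text!r} at position {pos}"
                )
            residue = self.by_name(m.group(1))
            n = int(m.group(2))
            if residue.id in counts:
                raise CompositionError(
                    f"residue {residue.name!r} repeated in {text!r}"
                )
            counts[residue.id] = n
            pos = m.end()
        if not counts and not has_core:
            if s:
                raise CompositionError(f"cannot parse composition {text!r} at position 0")
        return Composition.make(counts, has_core)

    # ---------------------------------------------------------------- 15-digit ID

    def composition_id(self, comp: Composition) -> str:
        """15 digits (slot order) plus trailing ``C`` when the core is present."""
        digits = []
        counts = comp.as_dict()
        for slot in range(1, N_SLOTS + 1):
            n = counts.get(slot, 0)
            if n > 9:
                raise CompositionError(
                    f"count {n} for residue id {slot} exceeds single-digit encoding"
                )
            digits.append(str(n))
        return "".join(digits) + ("C" if comp.has_core else "")

    def parse_composition_id(self, text: str) -> Composition:
        s = text.strip()
        has_core = s.endswith("C")
        if has_core:
            s = s[:-1]
        if len(s) != N_SLOTS or not s.isdigit():
            raise CompositionError(f"malformed composition id {text!r}")
        counts = {slot: int(ch) for slot, ch in enumerate(s, start=1) if ch != "0"}
        return Composition.make(counts, has_core)


# -------------------------------------------------------------- registry I/O


def read_registry_csv(path: str | Path) -> Registry:
    """Load a registry from CSV (columns id,name,mass,min,max,category,description)."""
    residues = []
    with open(path, newline="") as fh:
        for i, row in enumerate(csv.DictReader(fh), start=2):
            try:
                residues.append(
                    Residue(
                        id=int(row["id"]),
                        name=row["name"].strip(),
                        mass=float(row["mass"]),
                        description=(row.get("description") or "").strip(),
                        min_count=int(row["min"]),
                        max_count=int(row["max"]),
                        category=(row.get("category") or "neutral").strip(),
                    )
                )
            except (KeyError, ValueError) as exc:
                raise ValueError(f"{path}: bad registry row at line {i}: {exc}") from exc
    return Registry(residues)


def write_registry_csv(registry: Registry, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["id", "name", "mass", "min", "max", "category", "description"])
        for r in registry.active:
            w.writerow([r.id, r.name, f"{r.mass:.4f}", r.min_count, r.max_count,
                        r.category, r.description])


def default_registry() -> Registry:
    """The shipped serum N-glycomics registry (SALSA-resolved sialic acids)."""
    with resources.as_file(
        resources.files("tagglyco").joinpath("data/residues.csv")
    ) as p:
        return read_registry_csv(p)
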