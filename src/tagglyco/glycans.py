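"""Candidate N-glycan list: enumeration, SALSA expansion, CSV round trip.

Compositions are first enumerated with *generic* sialic-acid counts
(NeuAc, NeuGc) under per-class biosynthetic rules, then each generic entry
is expanded into every split between the two SALSA linkage classes
(alpha-2,3/2,8 vs alpha-2,6), giving (a+1)(g+1) variants for a NeuAc and
g NeuGc.  Class rules:

* ``HM`` — oligomannose, 2-6 hexoses beyond the M3 core, nothing else.
* ``hybrid`` — one mannose arm retained: more non-core hexoses than
  HexNAc (1-3 HexNAc allowing a LacDiNAc unit); "mannose-rich" when more
  than three non-core hexoses.
* complex (``1_n`` .. ``4_a``) — 1-5 non-core HexNAc (up to four antennae
  plus one LacDiNAc increment), galactoses capped by antennae, named by
  antenna count and neutral/acidic.

Global caps: Fuc <= 3, NeuAc + NeuGc + GlcA <= 4, GlcA <= 1, acidic
residues capped by available antennae (non-core HexNAc).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path
from typing import Callable, Iterable, Sequence

from .residues import (
    BOA_SODIUM,
    Composition,
    CompositionError,
    LabelScheme,
    Registry,
    default_registry,
)

__all__ = [
    "GenericComposition",
    "GlycanClassRule",
    "GlycanListEntry",
    "GlycanList",
    "default_rules",
    "enumerate_compositions",
    "salsa_expand",
    "build_default_list",
    "filter_list",
    "write_list_csv",
    "read_list_csv",
]

#: Generic (pre-SALSA) residue axes used by class rules.
GENERIC_AXES = ("Hex", "HexNAc", "Fuc", "NeuAc", "NeuGc", "GlcA")

#: SALSA split targets: generic name -> (2,3/2,8-linked slot name, 2,6-linked slot name)
SALSA_SPLITS = {"NeuAc": ("3-8NeuAc", "6NeuAc"), "NeuGc": ("3-8NeuGc", "6NeuGc")}


@dataclass(frozen=True)
class GenericComposition:
    """Composition with linkage-unresolved sialic-acid counts."""

    counts: tuple[tuple[str, int], ...]  # generic-name -> count, zeros dropped
    has_core: bool = True

    @classmethod
    def make(cls, counts: dict[str, int], has_core: bool = True) -> "GenericComposition":
        return cls(tuple(sorted((k, v) for k, v in counts.items() if v)), has_core)

    def as_dict(self) -> dict[str, int]:
        return dict(self.counts)


@dataclass
class GlycanClassRule:
    """Count ranges plus cross-residue predicates defining one glycan class."""

    class_name: str
    ranges: dict[str, tuple[int, int]]
    predicate: Callable[[dict[str, int]], bool] = lambda c: True
    namer: Callable[[dict[str, int]], str] | None = None

    def name_for(self, counts: dict[str, int]) -> str:
        return self.namer(counts) if self.namer else self.class_name


def _acid_total(c: dict[str, int]) -> int:
    return c.get("NeuAc", 0) + c.get("NeuGc", 0) + c.get("GlcA", 0)


def default_rules() -> list[GlycanClassRule]:
    """Built-in serum N-glycan class rules (see module docstring)."""

    def global_ok(c: dict[str, int]) -> bool:
        return _acid_total(c) <= 4 and c.get("GlcA", 0) <= 1

    hm = GlycanClassRule(
        "HM",
        {"Hex": (2, 6)},
    )

    hybrid = GlycanClassRule(
        "hybrid",
        {"Hex": (2, 6), "HexNAc": (1, 3), "Fuc": (0, 3),
         "NeuAc": (0, 4), "NeuGc": (0, 4), "GlcA": (0, 1)},
        predicate=lambda c: (
            c["Hex"] > c["HexNAc"]
            and _acid_total(c) <= c["HexNAc"]
            and global_ok(c)
        ),
        namer=lambda c: "hybrid-MR" if c["Hex"] > 3 else "hybrid",
    )

    cx = GlycanClassRule(
        "complex",
        {"Hex": (0, 4), "HexNAc": (1, 5), "Fuc": (0, 3),
         "NeuAc": (0, 4), "NeuGc": (0, 4), "GlcA": (0, 1)},
        predicate=lambda c: (
            c["Hex"] <= min(c["HexNAc"], 4)
            and _acid_total(c) <= c["HexNAc"]
            and global_ok(c)
        ),
        namer=lambda c: f"{min(c['HexNAc'], 4)}_{'a' if _acid_total(c) else 'n'}",
    )

    return [hm, hybrid, cx]


@dataclass(frozen=True)
class GlycanListEntry:
    class_name: str
    composition: Composition
    composition_id: str
    theoretical_mz: float
    composition_text: str = ""


@dataclass
class GlycanList:
    """Ordered candidate list with provenance of label scheme and registry."""

    entries: list[GlycanListEntry]
    label_name: str = BOA_SODIUM.name
    registry_fingerprint: str = ""

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for e in self.entries:
            if e.composition_id in seen:
                raise ValueError(f"duplicate composition_id {e.composition_id}")
            seen.add(e.composition_id)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)


def enumerate_compositions(
    rules: Sequence[GlycanClassRule] | None = None,
    registry: Registry | None = None,
) -> list[tuple[str, GenericComposition]]:
    """Exhaustive generic (pre-SALSA) enumeration under the class rules.

    Registry count ranges act as global caps on the generic axes (the two
    linkage variants of each sialic acid share one registry range).
    """
    registry = registry or default_registry()
    rules = list(rules) if rules is not None else default_rules()

    caps: dict[str, int] = {}
    for axis in GENERIC_AXES:
        names = SALSA_SPLITS.get(axis, (axis,))
        try:
            caps[axis] = max(registry.by_name(n).max_count for n in names)
        except CompositionError:
            caps[axis] = 0

    out: list[tuple[str, GenericComposition]] = []
    seen: set[GenericComposition] = set()
    for rule in rules:
        axes = [a for a in GENERIC_AXES if a in rule.ranges]
        spans = []
        for a in axes:
            lo, hi = rule.ranges[a]
            hi = min(hi, caps[a])
            if lo > hi:
                raise ValueError(
                    f"rule {rule.class_name!r}: empty range for {a} "
                    f"({lo}..{hi} after registry cap)"
                )
            spans.append(range(lo, hi + 1))
        for combo in product(*spans):
            counts = dict(zip(axes, combo))
            full = {a: counts.get(a, 0) for a in GENERIC_AXES}
            if not rule.predicate(full):
                continue
            gc = GenericComposition.make(full)
            if gc in seen:
                continue
            seen.add(gc)
            out.append((rule.name_for(full), gc))
    return out


def salsa_expand(generic: GenericComposition, registry: Registry) -> list[Composition]:
    """All linkage splits of the generic sialic-acid counts.

    A generic entry with a NeuAc and g NeuGc yields exactly (a+1)(g+1)
    linkage-resolved compositions whose masses differ by multiples of the
    methylamide/isopropylamide gap (28.0313 Da).
    """
    counts = generic.as_dict()
    base: dict[int, int] = {}
    for name in ("Hex", "HexNAc", "Fuc"):
        if counts.get(name):
            base[registry.by_name(name).id] = counts[name]
    if counts.get("GlcA"):
        base[registry.by_name("GlcA").id] = counts["GlcA"]

    variants = [base]
    for generic_name, (lo_name, hi_name) in SALSA_SPLITS.items():
        total = counts.get(generic_name, 0)
        expanded = []
        for v in variants:
            for six in range(total + 1):
                w = dict(v)
                if total - six:
                    w[registry.by_name(lo_name).id] = total - six
                if six:
                    w[registry.by_name(hi_name).id] = six
                expanded.append(w)
        variants = expanded
    return [Composition.make(v, generic.has_core) for v in variants]


def build_default_list(
    registry: Registry | None = None,
    label: LabelScheme = BOA_SODIUM,
    rules: Sequence[GlycanClassRule] | None = None,
    exclude_neugc: bool = False,
) -> GlycanList:
    """Enumerate, SALSA-expand, and sort the candidate list by m/z."""
    registry = registry or default_registry()
    entries: list[GlycanListEntry] = []
    for class_name, generic in enumerate_compositions(rules, registry):
        for comp in salsa_expand(generic, registry):
            entries.append(
                GlycanListEntry(
                    class_name=class_name,
                    composition=comp,
                    composition_id=registry.composition_id(comp),
                    theoretical_mz=registry.composition_mass(comp, label),
                    composition_text=registry.format_composition(comp),
                )
            )
    entries.sort(key=lambda e: (e.theoretical_mz, e.composition_id))
    lst = GlycanList(entries, label.name, registry.fingerprint())
    if exclude_neugc:
        lst = filter_list(lst, exclude_neugc=True)
    return lst


def filter_list(
    lst: GlycanList,
    exclude_neugc: bool = False,
    mass_range: tuple[float, float] | None = None,
    classes: Iterable[str] | None = None,
    registry: Registry | None = None,
) -> GlycanList:
    """Order-preserving subset; no option means identity."""
    registry = registry or default_registry()
    neugc_ids = {registry.by_name("3-8NeuGc").id, registry.by_name("6NeuGc").id}
    wanted = set(classes) if classes is not None else None
    out = []
    for e in lst.entries:
        if exclude_neugc and any(e.composition.count(i) for i in neugc_ids):
            continue
        if mass_range and not (mass_range[0] <= e.theoretical_mz <= mass_range[1]):
            continue
        if wanted is not None and e.class_name not in wanted:
            continue
        out.append(e)
    return GlycanList(out, lst.label_name, lst.registry_fingerprint)


# ------------------------------------------------------------------ list CSV

_HEADER = ["class", "composition_id", "composition_text", "theoretical_mz"]


def write_list_csv(lst: GlycanList, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_HEADER + [f"label={lst.label_name}",
                              f"registry={lst.registry_fingerprint}"])
        for e in lst.entries:
            w.writerow([e.class_name, e.composition_id, e.composition_text,
                        f"{e.theoretical_mz:.6f}"])


def read_list_csv(path: str | Path, registry: Registry | None = None) -> GlycanList:
    registry = registry or default_registry()
    entries = []
    label_name = ""
    fingerprint = ""
    with open(path, newline="") as fh:
        rows = csv.reader(fh)
        try:
            header = next(rows)
        except StopIteration:
            raise ValueError(f"{path}: empty glycan list") from None
        if header[: len(_HEADER)] != _HEADER:
            raise ValueError(f"{path}: unexpected header {header[:4]}")
        for extra in header[len(_HEADER):]:
            if extra.startswith("label="):
                label_name = extra[len("label="):]
            elif extra.startswith("registry="):
                fingerprint = extra[len("registry="):]
        for lineno, row in enumerate(rows, start=2):
            if not row or not any(row):
                continue
            try:
                class_name, comp_id, comp_text, mz = row[:4]
                comp = registry.parse_composition(comp_text)
                if registry.composition_id(comp) != comp_id:
                    raise ValueError(
                        f"composition text {comp_text!r} does not match id {comp_id!r}"
                    )
                entries.append(
                    GlycanListEntry(class_name, comp, comp_id, float(mz), comp_text)
                )
            except (ValueError, CompositionError, IndexError) as exc:
                raise ValueError(f"{path}: bad glycan-list row at line {lineno}: {exc}") from exc
    return GlycanList(entries, label_name, fingerprint)
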