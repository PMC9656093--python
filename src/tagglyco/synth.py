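"""Synthetic masslists, plate files, and truth tables.

Emulates a calibration experiment on a MALDI plate: a panel of glycans at
known serum concentrations (pmol/uL) spotted at several volumes with
replicates, plus an internal standard at fixed pmol in every spot.  The
noise model is deliberately simple but exercises every pipeline stage:

* Gaussian m/z jitter (``mz_sigma``, Da) moves peaks within/outside the
  matching tolerance,
* multiplicative Gaussian area noise (``area_cv``, fraction) perturbs the
  quantitation and calibration linearity,
* uniform contaminant peaks test false-positive rejection; they are kept
  away from a configurable exclusion zone around real masses.

Seeded runs are bit-reproducible.  The truth CSV lists the spiked pmol of
every panel glycan per experiment.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import openpyxl

from .expression import DEFAULT_IS_MZ, DEFAULT_TOLERANCE
from .plate import PLATE_CAPACITY, PLATE_COLS, PLATE_ROWS
from .residues import BOA_SODIUM, Composition, LabelScheme, Registry, default_registry

__all__ = ["SyntheticDesign", "generate_masslist", "generate_plate", "write_design"]


@dataclass
class SyntheticDesign:
    """Study design for a synthetic calibration (or category) plate."""

    panel: list[tuple[str, float]] = field(default_factory=list)  # (composition text, pmol/uL)
    volumes: tuple[float, ...] = (2.0, 4.0, 6.0, 8.0, 10.0)
    replicates: int = 4
    is_pmol: float = 20.0
    is_mz: float = DEFAULT_IS_MZ
    tolerance: float = DEFAULT_TOLERANCE
    mz_sigma: float = 0.0
    area_cv: float = 0.0
    n_noise_peaks: int = 0
    noise_mz_range: tuple[float, float] = (900.0, 3500.0)
    noise_exclusion: float = 0.3  # Da kept clear of real masses on each side
    area_per_pmol: float = 1000.0  # detector response (area counts per pmol)
    seed: int = 0
    #: optional category-mode series: (series_id, label, concentration scale)
    series: list[tuple[int, str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not all(c > 0 for _, c in self.panel):
            raise ValueError("panel concentrations must be positive")
        if self.mz_sigma < 0 or self.area_cv < 0:
            raise ValueError("noise parameters must be non-negative")

    @property
    def mode(self) -> str:
        return "category" if self.series else "calibration"

    def spot_codes(self) -> list[str]:
        """Plate cell codes in spotting (row-major) order."""
        if self.series:
            return [f"{sid}#{label}" for sid, label, _ in self.series
                    for _ in range(self.replicates)]
        return [f"{v:g}_{r}" for v in self.volumes for r in range(1, self.replicates + 1)]

    def experiment_names(self) -> list[str]:
        if self.series:
            return [f"{label}_r{r}" for _, label, _ in self.series
                    for r in range(1, self.replicates + 1)]
        return [f"v{v:g}_r{r}" for v in self.volumes for r in range(1, self.replicates + 1)]


def _panel_masses(
    design: SyntheticDesign, registry: Registry, label: LabelScheme
) -> list[tuple[Composition, float, float]]:
    out = []
    for text, conc in design.panel:
        comp = registry.parse_composition(text)
        out.append((comp, registry.composition_mass(comp, label), conc))
    return out


def generate_masslist(
    design: SyntheticDesign,
    out_xlsx: str | Path,
    truth_csv: str | Path | None = None,
    registry: Registry | None = None,
    label: LabelScheme = BOA_SODIUM,
    avoid_mzs: Sequence[float] | None = None,
) -> Path:
    """Write the masslist workbook (one tab per spot) and the truth table.

    ``avoid_mzs`` extends the contaminant exclusion zone beyond the panel
    masses (e.g. every theoretical mass of a glycan list, to guarantee
    contaminants can never be annotated).
    """
    registry = registry or default_registry()
    rng = np.random.default_rng(design.seed)
    panel = _panel_masses(design, registry, label)

    avoid = [m for _, m, _ in panel] + [design.is_mz] + list(avoid_mzs or [])
    margin = max(2.0 * design.mz_sigma, design.noise_exclusion)
    lo, hi = design.noise_mz_range
    if design.n_noise_peaks and not _free_mass_exists(lo, hi, avoid, margin):
        raise ValueError("noise m/z range is entirely blocked by the exclusion zone")

    wb = openpyxl.Workbook()
    wb.remove(wb.active)
    truth_rows = []

    names = design.experiment_names()
    scales = _per_experiment_scale(design)
    for name, scale in zip(names, scales):
        ws = wb.create_sheet(title=name)
        ws.append(["m/z", "area"])
        peaks: list[tuple[float, float]] = []
        for comp, mass, conc in panel:
            pmol = conc * scale
            area = pmol * design.area_per_pmol
            if design.area_cv > 0:
                area *= max(1e-9, 1.0 + design.area_cv * rng.standard_normal())
            mz = mass + (design.mz_sigma * rng.standard_normal() if design.mz_sigma else 0.0)
            peaks.append((mz, area))
            truth_rows.append((name, registry.composition_id(comp), f"{pmol:.6f}"))
        is_area = design.is_pmol * design.area_per_pmol
        if design.area_cv > 0:
            is_area *= max(1e-9, 1.0 + design.area_cv * rng.standard_normal())
        peaks.append((design.is_mz, is_area))
        for _ in range(design.n_noise_peaks):
            mz = _draw_noise_mz(rng, lo, hi, avoid, margin)
            peaks.append((mz, float(rng.uniform(0.1, 2.0)) * design.area_per_pmol))
        for mz, area in sorted(peaks):
            ws.append([round(mz, 6), round(area, 4)])
    wb.save(out_xlsx)

    if truth_csv is not None:
        with open(truth_csv, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["experiment", "composition_id", "pmol_spiked"])
            w.writerows(truth_rows)
    return Path(out_xlsx)


def _per_experiment_scale(design: SyntheticDesign) -> list[float]:
    """Spiked pmol per unit concentration for each experiment in order."""
    if design.series:
        return [scale for _, _, scale in design.series
                for _ in range(design.replicates)]
    return [v for v in design.volumes for _ in range(design.replicates)]


def _free_mass_exists(lo: float, hi: float, avoid: Sequence[float], margin: float) -> bool:
    grid = np.linspace(lo, hi, 2048)
    a = np.asarray(avoid)
    return bool((np.abs(grid[:, None] - a[None, :]).min(axis=1) > margin).any())


def _draw_noise_mz(rng, lo, hi, avoid, margin, max_tries=10000) -> float:
    for _ in range(max_tries):
        mz = float(rng.uniform(lo, hi))
        if all(abs(mz - a) > margin for a in avoid):
            return mz
    raise RuntimeError("could not place a contaminant peak outside the exclusion zone")


def generate_plate(design: SyntheticDesign, out_xlsx: str | Path) -> Path:
    """Write the matching plate file: common row plus row-major spot codes."""
    codes = design.spot_codes()
    if len(codes) > PLATE_CAPACITY:
        raise ValueError(
            f"design needs {len(codes)} spots; plate capacity is {PLATE_CAPACITY}"
        )
    wb = openpyxl.Workbook()
    ws = wb.active
    ws.append([f"is_pmol={design.is_pmol:g}", f"tolerance_da={design.tolerance:g}"])
    ncols = len(PLATE_COLS)
    for i, code in enumerate(codes):
        ws.cell(row=2 + i // ncols, column=1 + i % ncols, value=code)
    wb.save(out_xlsx)
    return Path(out_xlsx)


def write_design(design: SyntheticDesign, path: str | Path) -> None:
    """Serialize a design to the key=value config format used by the CLI."""
    with open(path, "w") as fh:
        fh.write(f"seed={design.seed}\n")
        fh.write(f"volumes={','.join(f'{v:g}' for v in design.volumes)}\n")
        fh.write(f"replicates={design.replicates}\n")
        fh.write(f"is_pmol={design.is_pmol:g}\n")
        fh.write(f"is_mz={design.is_mz!r}\n")
        fh.write(f"tolerance={design.tolerance:g}\n")
        fh.write(f"mz_sigma={design.mz_sigma!r}\n")
        fh.write(f"area_cv={design.area_cv!r}\n")
        fh.write(f"n_noise_peaks={design.n_noise_peaks}\n")
        fh.write(f"noise_mz_range={design.noise_mz_range[0]:g},{design.noise_mz_range[1]:g}\n")
        for sid, lab, scale in design.series:
            fh.write(f"series={sid}#{lab}:{scale!r}\n")
        for text, conc in design.panel:
            fh.write(f"panel={text}:{conc!r}\n")


def read_design(path: str | Path) -> SyntheticDesign:
    """Parse the key=value design config written by :func:`write_design`."""
    kw: dict[str, object] = {}
    panel: list[tuple[str, float]] = []
    series: list[tuple[int, str, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected key=value, got {line!r}")
            key, _, value = line.partition("=")
            key = key.strip()
            value = value.strip()
            if key == "panel":
                text, _, conc = value.rpartition(":")
                panel.append((text, float(conc)))
            elif key == "series":
                code, _, scale = value.rpartition(":")
                sid, _, lab = code.partition("#")
                series.append((int(sid), lab, float(scale)))
            elif key == "volumes":
                kw["volumes"] = tuple(float(v) for v in value.split(","))
            elif key == "noise_mz_range":
                lo, hi = value.split(",")
                kw["noise_mz_range"] = (float(lo), float(hi))
            elif key in ("replicates", "n_noise_peaks", "seed"):
                kw[key] = int(value)
            elif key in ("is_pmol", "is_mz", "tolerance", "mz_sigma", "area_cv",
                         "area_per_pmol", "noise_exclusion"):
                kw[key] = float(value)
            else:
                raise ValueError(f"{path}:{lineno}: unknown design key {key!r}")
    return SyntheticDesign(panel=panel, series=series, **kw)
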