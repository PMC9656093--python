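"""Masslist (multi-tab XLSX) and MALDI-plate-file I/O.

A *masslist* is the instrument export: one workbook tab per plate spot,
two numeric columns (m/z, peak area).  A *plate file* mirrors the 384-spot
MALDI plate: row 1 carries run-wide parameters as ``key=value`` cells
(internal-standard pmol, tolerance, optional protein level); rows 2-17 map
to plate rows A-P and columns 1-24 to plate columns.  Occupied cells hold
spot codes:

* ``<volume>_<replicate>`` — a calibration spot (serum volume in uL);
  the replicate part is optional and defaults to occurrence order.
* ``<series>#<label>`` — a category spot (series id, free-text label).
* a bare integer — a category spot whose label is the series id.

Per-spot input files are plain CSV: a ``key,value`` metadata block
followed by a ``mz,area`` header and the peak rows.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import openpyxl

__all__ = [
    "Peak",
    "PeakList",
    "CalibrationSpot",
    "CategorySpot",
    "PlateFile",
    "SpotInput",
    "read_masslist",
    "convert_to_multicsv",
    "parse_plate",
    "parse_spot_code",
    "generate_inputs",
    "read_input_csv",
    "write_input_csv",
]

PLATE_ROWS = [chr(ord("A") + i) for i in range(16)]  # A..P
PLATE_COLS = list(range(1, 25))  # 1..24
PLATE_CAPACITY = len(PLATE_ROWS) * len(PLATE_COLS)  # 384


@dataclass(frozen=True)
class Peak:
    mz: float
    area: float


@dataclass
class PeakList:
    """Peaks of one experiment (= one masslist tab = one plate spot)."""

    experiment: str
    peaks: list[Peak]

    def __len__(self) -> int:
        return len(self.peaks)


@dataclass(frozen=True)
class CalibrationSpot:
    volume: float  # uL of serum spotted
    replicate: int

    def code(self) -> str:
        v = f"{self.volume:g}"
        return f"{v}_{self.replicate}"


@dataclass(frozen=True)
class CategorySpot:
    series_id: int
    label: str

    def code(self) -> str:
        return f"{self.series_id}#{self.label}"


SpotCode = CalibrationSpot | CategorySpot


@dataclass
class PlateFile:
    """Common run parameters plus the spot-code grid."""

    common: dict[str, object]
    spots: dict[str, SpotCode]  # address ("A1".."P24") -> code

    @property
    def is_pmol(self) -> float | None:
        v = self.common.get("is_pmol")
        return float(v) if v is not None else None

    @property
    def tolerance(self) -> float | None:
        v = self.common.get("tolerance_da")
        return float(v) if v is not None else None

    def occupied(self) -> list[tuple[str, SpotCode]]:
        """Occupied spots in row-major plate order (A1..A24, B1.., P24)."""
        order = {f"{r}{c}": (ri, c) for ri, r in enumerate(PLATE_ROWS) for c in PLATE_COLS}
        return sorted(self.spots.items(), key=lambda kv: order[kv[0]])


# ------------------------------------------------------------------ masslist


def _cell_number(value, tab: str, row: int, col: str) -> float:
    if isinstance(value, (int, float)):
        return float(value)
    try:
        return float(str(value).strip())
    except (TypeError, ValueError):
        raise ValueError(
            f"non-numeric cell in tab {tab!r} at row {row}, column {col}: {value!r}"
        ) from None


def read_masslist(path: str | Path) -> list[PeakList]:
    """Read every tab of an instrument masslist, tab order preserved.

    A leading non-numeric row per tab (column headers) is skipped; any
    other non-numeric cell in the data region is an error.
    """
    wb = openpyxl.load_workbook(path, read_only=True, data_only=True)
    out: list[PeakList] = []
    try:
        for ws in wb.worksheets:
            peaks: list[Peak] = []
            for i, row in enumerate(ws.iter_rows(min_col=1, max_col=2, values_only=True), 1):
                if row[0] is None and row[1] is None:
                    continue
                if i == 1 and isinstance(row[0], str):
                    try:
                        float(row[0])
                    except ValueError:
                        continue  # header row
                mz = _cell_number(row[0], ws.title, i, "A")
                area = _cell_number(row[1], ws.title, i, "B")
                if mz <= 0:
                    raise ValueError(f"non-positive m/z {mz} in tab {ws.title!r} row {i}")
                peaks.append(Peak(mz, area))
            out.append(PeakList(ws.title, peaks))
    finally:
        wb.close()
    names = [p.experiment for p in out]
    if len(set(names)) != len(names):
        raise ValueError(f"{path}: duplicate tab names")
    return out


def sanitize_name(name: str) -> str:
    """Filesystem-safe tab name: path separators and whitespace become '_'."""
    return re.sub(r"[\\/\s:]+", "_", name.strip())


def convert_to_multicsv(masslist_path: str | Path, out_dir: str | Path | None = None) -> list[Path]:
    """One CSV per tab, named after the tab, under a folder named after the
    masslist basename (default) or ``out_dir``."""
    masslist_path = Path(masslist_path)
    peaklists = read_masslist(masslist_path)
    root = Path(out_dir) if out_dir is not None else masslist_path.with_suffix("")
    root.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    seen: dict[str, str] = {}
    for pl in peaklists:
        safe = sanitize_name(pl.experiment)
        if safe in seen:
            raise ValueError(
                f"tab names {seen[safe]!r} and {pl.experiment!r} collide after "
                f"sanitization ({safe!r})"
            )
        seen[safe] = pl.experiment
        path = root / f"{safe}.csv"
        with open(path, "w", newline="") as fh:
            fh.write("mz,area\n")
            for p in pl.peaks:
                fh.write(f"{p.mz!r},{p.area!r}\n")
        written.append(path)
    return written


# ---------------------------------------------------------------- plate file

# "<volume>_<replicate>"; the replicate digits may be omitted ("2_")
_CAL_RE = re.compile(r"^(\d+(?:\.\d+)?)(?:_(\d*))?$")


def parse_spot_code(text: str, default_replicate: int = 1) -> SpotCode:
    s = str(text).strip()
    if "#" in s:
        series_s, _, label = s.partition("#")
        try:
            series = int(series_s)
        except ValueError:
            raise ValueError(f"bad series id in spot code {text!r}") from None
        if series < 1:
            raise ValueError(f"series id must be >= 1 in spot code {text!r}")
        return CategorySpot(series, label)
    if "_" in s:
        m = _CAL_RE.match(s)
        if not m:
            raise ValueError(f"bad calibration spot code {text!r}")
        volume = float(m.group(1))
        if volume <= 0:
            raise ValueError(f"volume must be positive in spot code {text!r}")
        rep = int(m.group(2)) if m.group(2) else default_replicate
        return CalibrationSpot(volume, rep)
    try:
        series = int(float(s))
    except ValueError:
        raise ValueError(f"spot code {text!r} matches neither grammar") from None
    if series < 1:
        raise ValueError(f"series id must be >= 1 in spot code {text!r}")
    return CategorySpot(series, str(series))


_KNOWN_COMMON = {"is_pmol": float, "tolerance_da": float, "protein_level": float}


def parse_plate(path: str | Path) -> PlateFile:
    wb = openpyxl.load_workbook(path, read_only=True, data_only=True)
    try:
        ws = wb.worksheets[0]
        rows = list(ws.iter_rows(min_row=1, max_row=1 + len(PLATE_ROWS),
                                 max_col=len(PLATE_COLS), values_only=True))
    finally:
        wb.close()

    common: dict[str, object] = {}
    if rows:
        for cell in rows[0]:
            if cell is None or str(cell).strip() == "":
                continue
            text = str(cell).strip()
            if "=" not in text:
                raise ValueError(f"{path}: common-parameter cell {text!r} is not key=value")
            key, _, value = text.partition("=")
            key = key.strip()
            value = value.strip()
            conv = _KNOWN_COMMON.get(key)
            common[key] = conv(value) if conv and value != "" else value

    spots: dict[str, SpotCode] = {}
    vol_seen: dict[float, int] = {}  # per-volume occurrence order for default replicates
    for ri, row in enumerate(rows[1:]):
        plate_row = PLATE_ROWS[ri]
        for ci, cell in enumerate(row):
            if cell is None or str(cell).strip() == "":
                continue
            address = f"{plate_row}{PLATE_COLS[ci]}"
            try:
                code = parse_spot_code(cell, default_replicate=0)
            except ValueError as exc:
                raise ValueError(f"{path}: cell {address}: {exc}") from exc
            if isinstance(code, CalibrationSpot):
                n = vol_seen.get(code.volume, 0) + 1
                vol_seen[code.volume] = n
                if code.replicate == 0:
                    code = CalibrationSpot(code.volume, n)
            spots[address] = code
    if len(spots) > PLATE_CAPACITY:
        raise ValueError(f"{path}: more than {PLATE_CAPACITY} occupied spots")
    return PlateFile(common, spots)


# -------------------------------------------------------------- spot inputs


@dataclass
class SpotInput:
    """One TAG Expression input: peaks plus spot and run metadata."""

    experiment: str
    address: str
    spot: SpotCode
    common: Mapping[str, object]
    peaks: list[Peak]

    @property
    def kind(self) -> str:
        return "calibration" if isinstance(self.spot, CalibrationSpot) else "analysis"

    @property
    def series_key(self) -> str:
        """Grouping key: serum volume for calibration, label for categories."""
        if isinstance(self.spot, CalibrationSpot):
            return f"{self.spot.volume:g}uL"
        return self.spot.label


def write_input_csv(inp: SpotInput, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        fh.write("key,value\n")
        fh.write(f"experiment,{inp.experiment}\n")
        fh.write(f"spot,{inp.address}\n")
        fh.write(f"type,{inp.kind}\n")
        if isinstance(inp.spot, CalibrationSpot):
            fh.write(f"volume_ul,{inp.spot.volume:g}\n")
            fh.write(f"replicate,{inp.spot.replicate}\n")
        else:
            fh.write(f"series_id,{inp.spot.series_id}\n")
            fh.write(f"label,{inp.spot.label}\n")
        for key, value in inp.common.items():
            fh.write(f"{key},{value}\n")
        fh.write("mz,area\n")
        for p in inp.peaks:
            fh.write(f"{p.mz!r},{p.area!r}\n")


def read_input_csv(path: str | Path) -> SpotInput:
    meta: dict[str, str] = {}
    peaks: list[Peak] = []
    with open(path, newline="") as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if not lines or lines[0] != "key,value":
        raise ValueError(f"{path}: not a spot-input CSV (missing key,value header)")
    i = 1
    while i < len(lines) and lines[i] != "mz,area":
        key, _, value = lines[i].partition(",")
        meta[key] = value
        i += 1
    if i == len(lines):
        raise ValueError(f"{path}: missing mz,area section")
    for ln in lines[i + 1:]:
        if not ln.strip():
            continue
        mz_s, _, area_s = ln.partition(",")
        peaks.append(Peak(float(mz_s), float(area_s)))

    if meta.get("type") == "calibration":
        spot: SpotCode = CalibrationSpot(float(meta["volume_ul"]), int(meta["replicate"]))
    else:
        spot = CategorySpot(int(meta["series_id"]), meta.get("label", ""))
    reserved = {"experiment", "spot", "type", "volume_ul", "replicate", "series_id", "label"}
    common: dict[str, object] = {}
    for key, value in meta.items():
        if key in reserved:
            continue
        conv = _KNOWN_COMMON.get(key)
        try:
            common[key] = conv(value) if conv and value != "" else value
        except ValueError:
            common[key] = value
    return SpotInput(meta.get("experiment", Path(path).stem), meta.get("spot", ""),
                     spot, common, peaks)


def generate_inputs(
    masslist_path: str | Path,
    plate: PlateFile | str | Path,
    out_root: str | Path | None = None,
    mapping: Mapping[str, str] | None = None,
) -> dict[str, list[Path]]:
    """Route every masslist tab to calibration_line/ or analysis/.

    Tabs pair with occupied spots by position (tab i <-> i-th occupied
    spot, row-major) unless ``mapping`` gives explicit tab-name -> address
    pairs.  Tab/spot count mismatches are an error.
    """
    masslist_path = Path(masslist_path)
    if not isinstance(plate, PlateFile):
        plate = parse_plate(plate)
    peaklists = read_masslist(masslist_path)
    occupied = plate.occupied()

    if mapping is not None:
        by_addr = dict(plate.spots)
        pairs = []
        for pl in peaklists:
            if pl.experiment not in mapping:
                raise ValueError(f"tab {pl.experiment!r} missing from tab->spot map")
            addr = mapping[pl.experiment]
            if addr not in by_addr:
                raise ValueError(f"mapped address {addr!r} is not an occupied spot")
            pairs.append((pl, addr, by_addr[addr]))
    else:
        if len(peaklists) != len(occupied):
            tabs = [p.experiment for p in peaklists]
            raise ValueError(
                f"masslist has {len(peaklists)} tabs but plate has "
                f"{len(occupied)} occupied spots; tabs={tabs[:5]}..., "
                f"spots={[a for a, _ in occupied[:5]]}..."
            )
        pairs = [(pl, addr, code) for pl, (addr, code) in zip(peaklists, occupied)]

    root = Path(out_root) if out_root is not None else masslist_path.with_suffix("")
    written: dict[str, list[Path]] = {"calibration_line": [], "analysis": []}
    seen: dict[str, str] = {}
    for pl, addr, code in pairs:
        folder = "calibration_line" if isinstance(code, CalibrationSpot) else "analysis"
        dest = root / folder
        dest.mkdir(parents=True, exist_ok=True)
        safe = sanitize_name(pl.experiment)
        if safe in seen:
            raise ValueError(
                f"tab names {seen[safe]!r} and {pl.experiment!r} collide after sanitization"
            )
        seen[safe] = pl.experiment
        path = dest / f"{safe}.csv"
        write_input_csv(SpotInput(pl.experiment, addr, code, plate.common, pl.peaks), path)
        written[folder].append(path)
    return written
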