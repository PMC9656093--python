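"""Calibration curves, the R-squared filter, linked glycans, and reports.

For each annotated glycan a least-squares line of amount (pmol) against
spotted serum volume (uL) is fitted through the individual replicate
points.  Glycans whose response is concentration-linear (R^2 at or above
the cut, 0.8 by default) are the quantifiable subset.  ``linked glycans``
are detected compositions one residue away from a target composition — a
proxy for adjacency in the biosynthetic pathway that supports an
assignment.  Glyconnect browser URLs are built from total residue counts
(core included) so users can look up candidate structures.
"""

from __future__ import annotations

import csv
import html
import io
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .expression import ExpressionTable
from .glycans import GlycanListEntry
from .residues import (
    CORE_HEX,
    CORE_HEXNAC,
    Composition,
    CompositionError,
    Registry,
    default_registry,
)

__all__ = [
    "DEFAULT_RCUT",
    "GLYCONNECT_BASE",
    "CalibrationFit",
    "fit_calibration",
    "fit_table",
    "rcut_filter",
    "linked_glycans",
    "glyconnect_url",
    "build_summary",
    "write_summary",
    "write_exp_list",
    "render_calibration_html",
    "render_category_html",
]

DEFAULT_RCUT = 0.8
GLYCONNECT_BASE = "https://glyconnect.expasy.org/browser/compositions?f="


@dataclass
class CalibrationFit:
    """OLS line pmol = a * volume + b with its coefficient of determination."""

    spectral_id: int
    observed_mz: float
    composition_id: str
    composition_text: str
    points: list[tuple[float, float]]  # (volume uL, pmol)
    slope: float
    intercept: float
    r_squared: float
    slope_se: float = math.nan


def fit_calibration(points: Sequence[tuple[float, float]]) -> tuple[float, float, float, float]:
    """Least squares on replicate points: returns (slope, intercept, R^2, slope SE).

    Degenerate case SS_tot = 0 (constant response): R^2 is 1 when the fit
    is also residual-free, else 0.
    """
    pts = [(float(x), float(y)) for x, y in points
           if not (math.isnan(x) or math.isnan(y))]
    x = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    if len(np.unique(x)) < 2:
        raise ValueError("need at least two distinct volumes to fit a line")
    n = len(x)
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0.0:
        # perfect constant response: residual-free up to float round-off
        r2 = 1.0 if ss_res <= 1e-12 * max(1.0, float(y @ y)) else 0.0
    else:
        r2 = 1.0 - ss_res / ss_tot
    if n > 2:
        sxx = float(((x - x.mean()) ** 2).sum())
        se = math.sqrt(ss_res / (n - 2) / sxx) if sxx > 0 else math.nan
    else:
        se = math.nan
    return float(slope), float(intercept), float(r2), se


def fit_table(table: ExpressionTable) -> list[CalibrationFit]:
    """One calibration fit per (spectral cluster, candidate glycan) row.

    Volumes come from the per-experiment series keys (``<volume>uL``);
    invalid experiments (missing IS) contribute no points.
    """
    volumes: dict[str, float] = {}
    for exp in table.experiments:
        if exp in table.invalid_experiments:
            continue
        key = table.series[exp]
        if not key.endswith("uL"):
            raise ValueError(
                f"experiment {exp!r} is not a calibration spot (series {key!r})"
            )
        volumes[exp] = float(key[:-2])
    fits = []
    for _, row in table.data.iterrows():
        pts = [(volumes[e], row[f"pmol:{e}"]) for e in volumes]
        slope, intercept, r2, se = fit_calibration(pts)
        fits.append(
            CalibrationFit(
                int(row["spectral_id"]), float(row["observed_mz"]),
                str(row["composition_id"]), str(row["composition_text"]),
                pts, slope, intercept, r2, se,
            )
        )
    return fits


def rcut_filter(fits: Iterable[CalibrationFit], threshold: float = DEFAULT_RCUT) -> list[CalibrationFit]:
    """Keep fits with R^2 >= threshold (inclusive)."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"rcut threshold must be in [0, 1], got {threshold}")
    return [f for f in fits if f.r_squared >= threshold]


# ------------------------------------------------------------ linked glycans


def linked_glycans(
    target: Composition,
    detected: Iterable[tuple[Composition, int]],
) -> list[tuple[Composition, int]]:
    """Detected compositions exactly one residue count away from the target.

    Distance is the L1 distance in residue-count space; the core flag must
    agree.  The relation is symmetric by construction.
    """
    out = []
    tc = target.as_dict()
    for comp, spectral_id in detected:
        if comp.has_core != target.has_core:
            continue
        cc = comp.as_dict()
        dist = sum(abs(tc.get(k, 0) - cc.get(k, 0)) for k in set(tc) | set(cc))
        if dist == 1:
            out.append((comp, spectral_id))
    return out


# ------------------------------------------------------------ Glyconnect URL

#: Query segments in emission order: (segment name, registry residue names).
_URL_SEGMENTS = (
    ("Hex", ("Hex",)),
    ("HexNAc", ("HexNAc",)),
    ("dHex", ("Fuc",)),
    ("NeuAc", ("3-8NeuAc", "6NeuAc")),
    ("NeuGc", ("3-8NeuGc", "6NeuGc")),
    ("HexA", ("GlcA",)),
)


def glyconnect_url(comp: Composition, registry: Registry | None = None) -> str:
    """Glyconnect composition-browser URL from total residue counts.

    Counts include the M3 core (Hex+3, HexNAc+2); the SALSA linkage
    variants of each sialic acid are summed, fucose is reported as dHex
    and glucuronic acid as HexA; zero segments are omitted.
    """
    registry = registry or default_registry()
    if not comp.has_core:
        raise CompositionError("Glyconnect URLs are defined for core-bearing N-glycans")
    counts = comp.as_dict()
    parts = []
    for segment, names in _URL_SEGMENTS:
        n = sum(counts.get(registry.by_name(name).id, 0) for name in names)
        if segment == "Hex":
            n += CORE_HEX
        elif segment == "HexNAc":
            n += CORE_HEXNAC
        if n:
            parts.append(f"{segment}:{n}")
    return GLYCONNECT_BASE + "".join(parts)


# ----------------------------------------------------------------- summary


def build_summary(
    df: pd.DataFrame,
    registry: Registry | None = None,
) -> pd.DataFrame:
    """Summary rows: one per (spectral id, candidate), with linked glycans.

    ``df`` is an aggregated expression table (``aggregate_series`` output
    or the raw table).  Linked glycans are drawn from every candidate
    composition detected anywhere in the table and rendered as
    ``composition [spectral id]`` lists.
    """
    registry = registry or default_registry()
    detected: list[tuple[Composition, int]] = []
    for _, row in df.iterrows():
        detected.append(
            (registry.parse_composition_id(str(row["composition_id"])), int(row["spectral_id"]))
        )

    agg_cols = [c for c in df.columns
                if c.split(":")[0] in ("mean", "sd", "cv%", "p")]
    pmol_cols = [c for c in df.columns if c.startswith("pmol:")]

    rows = []
    for i, (_, row) in enumerate(df.iterrows()):
        target = detected[i][0]
        target_id = str(row["composition_id"])
        links = [
            f"{registry.format_composition(c)} [{sid}]"
            for c, sid in linked_glycans(target, detected)
            if registry.composition_id(c) != target_id
        ]
        out = {
            "spectral_id": int(row["spectral_id"]),
            "observed_mz": float(row["observed_mz"]),
            "composition_id": target_id,
            "composition_text": row["composition_text"],
            "linked_glycans": "; ".join(sorted(set(links))),
        }
        for c in agg_cols:
            out[c] = row[c]
        for c in pmol_cols:
            out[c] = row[c]
        out["glyconnect_url"] = glyconnect_url(target, registry)
        rows.append(out)
    cols = (["spectral_id", "observed_mz", "composition_id", "composition_text",
             "linked_glycans"] + agg_cols + pmol_cols + ["glyconnect_url"])
    return pd.DataFrame(rows, columns=cols)


def write_summary(summary: pd.DataFrame, path: str | Path) -> None:
    summary.to_csv(path, index=False, float_format="%.6g")


def write_exp_list(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, float_format="%.6g")


# -------------------------------------------------------------- HTML charts

_PAGE = """<!DOCTYPE html>
<html><head><meta charset="utf-8"><title>{title}</title>
<style>
body {{ font-family: sans-serif; margin: 1em; }}
.panel {{ display: inline-block; margin: 8px; border: 1px solid #ccc; padding: 6px; }}
.panel h3 {{ margin: 2px 0; font-size: 13px; }}
.panel p {{ margin: 2px 0; font-size: 12px; color: #333; }}
</style></head>
<body><h1>{title}</h1>
{body}
</body></html>
"""


def _fig_svg(draw) -> str:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(3.2, 2.6), dpi=100)
    draw(ax)
    buf = io.StringIO()
    fig.tight_layout()
    fig.savefig(buf, format="svg", metadata={"Date": None})
    plt.close(fig)
    return buf.getvalue()


def render_calibration_html(
    fits: Sequence[CalibrationFit],
    path: str | Path,
    title: str = "Calibration curves",
) -> None:
    """Self-contained HTML: one scatter+line panel per fit.

    Markers are per-volume means with sample-SD error bars; the fitted
    line and its a, b, R^2 are annotated on each panel, together with the
    observed m/z, composition, and 15-digit composition ID.
    """
    panels = []
    for f in sorted(fits, key=lambda f: (f.observed_mz, f.composition_id)):
        vols = sorted({v for v, _ in f.points})
        means = [float(np.mean([y for v, y in f.points if v == vol])) for vol in vols]
        sds = [float(np.std([y for v, y in f.points if v == vol], ddof=1))
               if len([y for v, y in f.points if v == vol]) > 1 else 0.0
               for vol in vols]

        def draw(ax, f=f, vols=vols, means=means, sds=sds):
            ax.errorbar(vols, means, yerr=sds, fmt="o", ms=4, capsize=3)
            xs = np.array([min(vols), max(vols)])
            ax.plot(xs, f.slope * xs + f.intercept, "-", lw=1)
            ax.set_xlabel("serum (uL)")
            ax.set_ylabel("pmol")
            ax.text(0.97, 0.03,
                    f"y={f.slope:.3g}x+{f.intercept:.3g}\nR2={f.r_squared:.3f}",
                    transform=ax.transAxes, ha="right", va="bottom", fontsize=7)

        panels.append(
            '<div class="panel"><h3>m/z {mz:.1f} [{sid}]</h3>'
            "<p>{comp}</p><p>ID {cid}</p>{svg}</div>".format(
                mz=f.observed_mz, sid=f.spectral_id,
                comp=html.escape(f.composition_text), cid=f.composition_id,
                svg=_fig_svg(draw),
            )
        )
    body = "\n".join(panels) if panels else "<p>No glycans passed the filter.</p>"
    Path(path).write_text(_PAGE.format(title=html.escape(title), body=body))


def render_category_html(
    df: pd.DataFrame,
    path: str | Path,
    title: str = "Glycan abundances by series",
) -> None:
    """Bar chart (mean +/- SD per series) per (spectral id, candidate) row."""
    mean_cols = [c for c in df.columns if c.startswith("mean:")]
    sd_cols = {c[len("mean:"):]: f"sd:{c[len('mean:'):]}" for c in mean_cols}
    panels = []
    for _, row in df.iterrows():
        keys = [c[len("mean:"):] for c in mean_cols]
        means = [row[f"mean:{k}"] for k in keys]
        sds = [row[sd_cols[k]] if sd_cols[k] in df.columns else 0.0 for k in keys]
        sds = [0.0 if (isinstance(s, float) and math.isnan(s)) else s for s in sds]

        def draw(ax, keys=keys, means=means, sds=sds):
            ax.bar(range(len(keys)), means, yerr=sds, capsize=3)
            ax.set_xticks(range(len(keys)))
            ax.set_xticklabels(keys, rotation=30, ha="right", fontsize=7)
            ax.set_ylabel("pmol")

        panels.append(
            '<div class="panel"><h3>m/z {mz:.1f} [{sid}]</h3><p>{comp}</p>'
            "<p>ID {cid}</p>{svg}</div>".format(
                mz=float(row["observed_mz"]), sid=int(row["spectral_id"]),
                comp=html.escape(str(row["composition_text"])),
                cid=row["composition_id"], svg=_fig_svg(draw),
            )
        )
    body = "\n".join(panels) if panels else "<p>No annotated glycans.</p>"
    Path(path).write_text(_PAGE.format(title=html.escape(title), body=body))
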