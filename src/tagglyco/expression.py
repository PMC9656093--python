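"""Peak annotation, replicate clustering, and internal-standard quantitation.

The analysis chain:

1. In each experiment the internal-standard (IS) peak is located as the
   peak nearest the configured IS m/z within tolerance; an experiment
   without it is flagged invalid (its amounts become missing, not zero).
2. Every remaining peak is matched against the glycan list: all candidates
   within ``|observed - theoretical| <= tolerance`` are kept — isobaric
   candidates are never arbitrated at MS1.
3. Matched peaks from all experiments are clustered into "spectral IDs":
   peaks are processed in ascending m/z and joined to the nearest open
   cluster whose running mean is within tolerance and which has no member
   from the same experiment yet (so a cluster spans at most 2x tolerance
   and holds at most one peak per experiment); cluster numbering is dense
   from 1 in ascending mean m/z.
4. Amounts are one-point internal-standard quantitation:
   ``pmol = area / IS_area * IS_pmol``.
5. Per-series mean, sample SD (n-1), and CV% are aggregated and series are
   compared by two-sided Welch t-tests (optionally Benjamini-Hochberg
   adjusted).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .glycans import GlycanList, GlycanListEntry
from .plate import Peak, PeakList, SpotInput
from .residues import Composition

__all__ = [
    "DEFAULT_TOLERANCE",
    "DEFAULT_IS_MZ",
    "PeakMatch",
    "SpectralCluster",
    "ExpressionTable",
    "match_peaks",
    "cluster_across_experiments",
    "quantify",
    "find_internal_standard",
    "analyze_inputs",
    "aggregate_series",
    "test_between_series",
    "welch_p",
    "benjamini_hochberg",
    "zero_cut",
]

#: Fallback mass tolerance (Da) when the plate file does not set one.
DEFAULT_TOLERANCE = 0.2

#: Default internal-standard m/z: BOA-labeled sodiated surrogate of the
#: disialyl octasaccharide standard (Hex)2 (HexNAc)2 (6NeuAc)2 without the
#: M3 core — 2*162.0528 + 2*203.0793 + 2*332.1583 + 146.058184.
DEFAULT_IS_MZ = 1540.638984


@dataclass
class PeakMatch:
    experiment: str
    observed_mz: float
    area: float
    candidates: list[GlycanListEntry]
    deltas: list[float]


@dataclass
class SpectralCluster:
    spectral_id: int
    members: dict[str, PeakMatch]  # experiment -> at most one match
    mean_observed_mz: float
    candidates: list[GlycanListEntry]


def match_peaks(
    peaklist: PeakList, glycan_list: GlycanList, tolerance: float
) -> list[PeakMatch]:
    """Annotate each peak with every list entry within the tolerance.

    Peaks with no candidate are dropped; all isobaric candidates are kept.
    """
    if tolerance <= 0:
        raise ValueError(f"tolerance must be positive, got {tolerance}")
    if len(glycan_list) == 0:
        raise ValueError("empty glycan list")
    entries = sorted(glycan_list.entries, key=lambda e: e.theoretical_mz)
    masses = np.array([e.theoretical_mz for e in entries])
    out: list[PeakMatch] = []
    for peak in peaklist.peaks:
        lo = int(np.searchsorted(masses, peak.mz - tolerance, side="left"))
        hi = int(np.searchsorted(masses, peak.mz + tolerance, side="right"))
        cands = [entries[i] for i in range(lo, hi)
                 if abs(peak.mz - entries[i].theoretical_mz) <= tolerance]
        if cands:
            out.append(
                PeakMatch(
                    peaklist.experiment, peak.mz, peak.area, cands,
                    [peak.mz - c.theoretical_mz for c in cands],
                )
            )
    return out


def cluster_across_experiments(
    matches: Iterable[PeakMatch], tolerance: float
) -> list[SpectralCluster]:
    """Group matched peaks across experiments into spectral clusters."""
    pool = sorted(matches, key=lambda m: (m.observed_mz, m.experiment))
    open_clusters: list[dict] = []  # {"members": {exp: match}, "sum": float, "n": int}
    for m in pool:
        best = None
        best_d = None
        for c in open_clusters:
            mean = c["sum"] / c["n"]
            d = abs(m.observed_mz - mean)
            if d <= tolerance and m.experiment not in c["members"]:
                if best is None or d < best_d:
                    best, best_d = c, d
        if best is None:
            open_clusters.append({"members": {m.experiment: m}, "sum": m.observed_mz, "n": 1})
        else:
            best["members"][m.experiment] = m
            best["sum"] += m.observed_mz
            best["n"] += 1

    open_clusters.sort(key=lambda c: c["sum"] / c["n"])
    out: list[SpectralCluster] = []
    for i, c in enumerate(open_clusters, start=1):
        cands: dict[str, GlycanListEntry] = {}
        for m in c["members"].values():
            for e in m.candidates:
                cands[e.composition_id] = e
        out.append(
            SpectralCluster(
                spectral_id=i,
                members=dict(c["members"]),
                mean_observed_mz=c["sum"] / c["n"],
                candidates=sorted(cands.values(), key=lambda e: (e.theoretical_mz, e.composition_id)),
            )
        )
    return out


def quantify(area: float, is_area: float, is_pmol: float) -> float:
    """One-point internal-standard quantitation: pmol = area/IS_area * IS_pmol."""
    if is_area <= 0:
        raise ValueError(f"internal-standard area must be positive, got {is_area}")
    if is_pmol <= 0:
        raise ValueError(f"internal-standard pmol must be positive, got {is_pmol}")
    return area / is_area * is_pmol


def find_internal_standard(
    peaklist: PeakList, is_mz: float, tolerance: float
) -> Peak | None:
    """Nearest peak to the configured IS m/z within tolerance, else None."""
    best = None
    for p in peaklist.peaks:
        d = abs(p.mz - is_mz)
        if d <= tolerance and (best is None or d < abs(best.mz - is_mz)):
            best = p
    return best


@dataclass
class ExpressionTable:
    """Clusters x candidate glycans with per-experiment amounts (pmol).

    ``data`` rows are (spectral_id, candidate); experiment columns are
    prefixed ``pmol:``.  ``invalid_experiments`` lacked an IS peak; their
    amounts are missing (NaN), not zero.
    """

    data: pd.DataFrame
    clusters: list[SpectralCluster]
    experiments: list[str]
    series: dict[str, str]  # experiment -> series key
    invalid_experiments: list[str] = field(default_factory=list)

    def amounts(self, experiment: str) -> pd.Series:
        return self.data[f"pmol:{experiment}"]


def analyze_inputs(
    inputs: Sequence[SpotInput],
    glycan_list: GlycanList,
    is_mz: float = DEFAULT_IS_MZ,
    is_pmol: float | None = None,
    tolerance: float | None = None,
) -> ExpressionTable:
    """Run the full annotation/quantitation chain over per-spot inputs.

    ``is_pmol`` and ``tolerance`` default to the plate-file common
    parameters carried in the inputs (then to ``DEFAULT_TOLERANCE``).
    The identified IS peak is excluded from glycan annotation.
    """
    if not inputs:
        raise ValueError("no input experiments")
    if len(glycan_list) == 0:
        raise ValueError("empty glycan list")

    all_matches: list[PeakMatch] = []
    is_areas: dict[str, float] = {}
    is_pmols: dict[str, float] = {}
    invalid: list[str] = []
    experiments: list[str] = []
    series: dict[str, str] = {}
    for inp in inputs:
        tol = tolerance
        if tol is None and inp.common.get("tolerance_da") not in (None, ""):
            tol = float(inp.common["tolerance_da"])  # type: ignore[arg-type]
        tol = tol if tol is not None else DEFAULT_TOLERANCE
        pmol = is_pmol
        if pmol is None and inp.common.get("is_pmol") not in (None, ""):
            pmol = float(inp.common["is_pmol"])  # type: ignore[arg-type]
        if pmol is None:
            raise ValueError(
                f"experiment {inp.experiment!r}: internal-standard pmol not given "
                "(neither argument nor plate common parameter is_pmol)"
            )
        experiments.append(inp.experiment)
        series[inp.experiment] = inp.series_key
        pl = PeakList(inp.experiment, list(inp.peaks))
        is_peak = find_internal_standard(pl, is_mz, tol)
        if is_peak is None or is_peak.area <= 0:
            invalid.append(inp.experiment)
            continue
        is_areas[inp.experiment] = is_peak.area
        is_pmols[inp.experiment] = pmol
        pl = PeakList(inp.experiment, [p for p in inp.peaks if p is not is_peak])
        all_matches.extend(match_peaks(pl, glycan_list, tol))

    tol_cluster = tolerance
    if tol_cluster is None:
        tols = [float(i.common.get("tolerance_da") or DEFAULT_TOLERANCE) for i in inputs]
        tol_cluster = tols[0] if tols else DEFAULT_TOLERANCE
    clusters = cluster_across_experiments(all_matches, tol_cluster)

    rows = []
    for cl in clusters:
        for cand in cl.candidates:
            row: dict[str, object] = {
                "spectral_id": cl.spectral_id,
                "observed_mz": cl.mean_observed_mz,
                "class": cand.class_name,
                "composition_id": cand.composition_id,
                "composition_text": cand.composition_text,
                "theoretical_mz": cand.theoretical_mz,
            }
            for exp in experiments:
                col = f"pmol:{exp}"
                if exp in invalid:
                    row[col] = math.nan
                else:
                    m = cl.members.get(exp)
                    if m is None:
                        row[col] = 0.0
                    else:
                        row[col] = quantify(m.area, is_areas[exp], is_pmols[exp])
            rows.append(row)
    columns = ["spectral_id", "observed_mz", "class", "composition_id",
               "composition_text", "theoretical_mz"] + [f"pmol:{e}" for e in experiments]
    data = pd.DataFrame(rows, columns=columns)
    return ExpressionTable(data, clusters, experiments, series, invalid)


# ------------------------------------------------------------- aggregation


def welch_p(a: Sequence[float], b: Sequence[float]) -> float:
    """Two-sided Welch t-test p-value; 1.0 when both series are constant
    with equal means (no evidence of difference)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least two values per series")
    if np.var(a) == 0 and np.var(b) == 0:
        return 1.0 if a.mean() == b.mean() else 0.0
    return float(stats.ttest_ind(a, b, equal_var=False).pvalue)


#: Alias matching the operation name used in run reports.
test_between_series = welch_p


def benjamini_hochberg(pvalues: Sequence[float]) -> np.ndarray:
    """BH step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    n = len(p)
    order = np.argsort(p)
    adj = np.empty(n)
    running = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        rank = n - rank_from_top
        running = min(running, p[idx] * n / rank)
        adj[idx] = running
    return adj


def aggregate_series(
    table: ExpressionTable, adjust: bool = False
) -> pd.DataFrame:
    """Add per-series mean / SD / CV% and pairwise Welch p-value columns.

    SD is the sample standard deviation (n-1); CV% = 100*SD/mean when the
    mean is positive.  Series with a single experiment get NaN SD and CV.
    """
    df = table.data.copy()
    groups: dict[str, list[str]] = {}
    for exp in table.experiments:
        groups.setdefault(table.series[exp], []).append(exp)

    for key, exps in groups.items():
        block = df[[f"pmol:{e}" for e in exps]]
        mean = block.mean(axis=1)
        sd = block.std(axis=1, ddof=1) if len(exps) > 1 else pd.Series(math.nan, index=df.index)
        df[f"mean:{key}"] = mean
        df[f"sd:{key}"] = sd
        df[f"cv%:{key}"] = np.where(mean > 0, 100.0 * sd / mean, math.nan)

    pair_cols = []
    for ka, kb in combinations(sorted(groups), 2):
        ea = [f"pmol:{e}" for e in groups[ka] if e not in table.invalid_experiments]
        eb = [f"pmol:{e}" for e in groups[kb] if e not in table.invalid_experiments]
        col = f"p:{ka}|{kb}"
        if len(ea) < 2 or len(eb) < 2:
            df[col] = math.nan
        else:
            df[col] = [
                welch_p(row[ea].to_numpy(dtype=float), row[eb].to_numpy(dtype=float))
                for _, row in df.iterrows()
            ]
        pair_cols.append(col)
    if adjust:
        for col in pair_cols:
            mask = df[col].notna()
            if mask.any():
                df.loc[mask, col + ":bh"] = benjamini_hochberg(df.loc[mask, col].to_numpy())
    return df


def zero_cut(df: pd.DataFrame) -> pd.DataFrame:
    """Drop rows whose amounts are zero or missing in every experiment."""
    pmol_cols = [c for c in df.columns if c.startswith("pmol:")]
    keep = (df[pmol_cols].fillna(0.0) > 0).any(axis=1)
    return df.loc[keep].reset_index(drop=True)
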