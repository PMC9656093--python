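# Methods

## Mass model

Theoretical m/z of a composition is the sum of monoisotopic residue masses
(non-core counts plus the M3 core, 3×Hex + 2×HexNAc) and a run constant
K = water + label increment + adduct. Defaults: water 18.010565 Da,
sodium 22.989770 Da, BOA oxime net increment 105.057849 Da (C₇H₉NO − H₂O),
hence K = 146.058184 Da. Only singly charged [M+Na]⁺ monoisotopic masses are
modeled — no isotope patterns, no multiple charging. Other labels and adducts
are supported by constructing a `LabelScheme` (the water term can be dropped
for labels that replace it) and other residue sets by loading a registry CSV
(columns id, name, mass, min, max, category, description). The registry is a
fixed 15-slot table so that the 15-digit composition ID keeps a stable width
and slot order (1 Hex, 2 HexNAc, 3 Fuc, 6 3-8NeuAc, 7 6NeuAc, 8 3-8NeuGc,
9 6NeuGc, 14 GlcA); unused slots are placeholders with max count 0 and can be
assigned to modifications such as acetyl/sulfate/phosphate without changing
the ID format. Counts above 9 cannot be encoded in a single digit and are
rejected.

Full precision is kept internally everywhere; rounding to the 1- or
4-decimal display convention happens only at output. The glycan-list CSV
stores masses at 6 decimals so that a write→read round trip is lossless.

## Candidate-list enumeration

Class rules are the package's own declaration (the biosynthetic rule set of
the original instrument workflows is not fully published); they were chosen
as the smallest set that covers standard serum *N*-glycomics practice and
every composition class we model:

* **HM** (oligomannose): 2–6 non-core hexoses, nothing else (M5–M9).
* **hybrid / hybrid-MR**: more non-core Hex than HexNAc, Hex 2–6,
  HexNAc 1–3 (one or two antennae on the processed arm, plus at most one
  LacDiNAc increment), acidic residues capped by HexNAc; "mannose-rich"
  (`hybrid-MR`) when Hex > 3.
* **complex** (`1_n` … `4_a`): 1–5 non-core HexNAc (up to four antennae,
  plus one LacDiNAc increment), non-core Hex ≤ min(HexNAc, 4) (one
  galactose per antenna), acidic residues capped by HexNAc. Classes are
  named by antenna count with an `_n` (neutral) / `_a` (acidic) suffix.

Global caps in all classes: Fuc ≤ 3, NeuAc + NeuGc + GlcA ≤ 4, GlcA ≤ 1.
LacDiNAc-bearing compositions (HexNAc exceeding Hex by one on an antenna)
arise from the "+1 HexNAc" allowance in the hybrid and complex rules.
Enumeration first runs over *generic* sialic-acid counts, then every entry
is expanded into all (α2,3/α2,8, α2,6) splits — (a+1)(g+1) variants for a
NeuAc and g NeuGc — so SALSA-resolved lists match what the chemistry
produces. The default list has 6,333 entries (1,817 with NeuGc excluded, the
human-serum setting). Entries are sorted by theoretical m/z with the
composition ID as tie-break, which makes generation deterministic
(byte-identical CSV for identical registry and rules). Users can append rows
to the CSV by hand; duplicate composition IDs are rejected on read.

## Annotation and quantitation

* **Matching**: every list entry within |observed − theoretical| ≤ tolerance
  is kept as a candidate; isobaric candidates are never arbitrated at MS1
  (MS/MS would be needed). The default tolerance is 0.2 Da — a conservative
  reflectron-MALDI scale — used only when the plate file does not set one.
* **Internal standard**: the peak nearest the configured IS m/z within
  tolerance. The IS m/z is configurable because the derivatized mass of a
  given commercial standard depends on label and SALSA state; the default is
  the BOA/Na mass of a core-free (Hex)₂(HexNAc)₂(6NeuAc)₂ surrogate
  (1540.639 Da). The IS peak is removed before annotation so the standard
  never appears as a glycan row. An experiment with no usable IS peak is
  flagged invalid and its amounts reported missing (NaN) — distinct from 0,
  which means "peak absent in a valid experiment".
* **Clustering**: matched peaks from all experiments, processed in
  ascending m/z, join the nearest open cluster whose running mean is within
  tolerance and which has no member from the same experiment; otherwise they
  seed a new cluster. Consequences: cluster span ≤ 2×tolerance, at most one
  peak per experiment per cluster, and on well-separated signals the result
  equals the connected components of the |Δm/z| ≤ tolerance graph. Clusters
  are numbered densely from 1 in ascending mean m/z ("spectral IDs").
* **Quantitation**: pmol = area / IS area × IS pmol. No per-glycan response
  factors are applied (none are available at MS1).
* **Statistics**: per series (volume group or category label) the arithmetic
  mean, sample SD (n−1) and CV% = 100·SD/mean; series with one experiment
  get NaN SD/CV. Between-series comparison is a two-sided Welch t-test; when
  both series are constant, p = 1 for equal means and 0 otherwise (the limit
  of the test). Raw p-values are reported by default with an optional
  Benjamini–Hochberg flag, since MS1 screening hypotheses are exploratory.

## Calibration curves

Fits use ordinary least squares through all replicate points (volume µL,
pmol), not per-volume means; plots show per-volume mean ± SD for
readability. R² = 1 − SSres/SStot. When SStot = 0 (constant response) R² is
reported as 1 if the residuals are also zero (a perfect constant is a
perfect fit of a degenerate line) and 0 otherwise; with measured data this
branch is unreachable, and the R² ≥ 0.8 filter is what screens out
volume-independent signals in practice. The threshold comparison is
inclusive (≥ 0.8) and configurable. The slope standard error is the usual
OLS expression √(SSres/(n−2)/Sxx), reported so slope recovery can be judged
in SE units.

**Linked glycans**: detected compositions at L1 distance exactly 1 in
residue-count space (same core state). Because SALSA variants are distinct
residues, a linkage swap (−3-8NeuAc, +6NeuAc) is distance 2 and therefore
*not* linked — only true gains/losses of one residue are, which matches the
biosynthetic-precursor interpretation.

**Glyconnect URLs** are query strings over total counts (core included,
Hex+3 / HexNAc+2), with Fuc emitted as dHex, GlcA as HexA, and the SALSA
linkage variants of each sialic acid summed; segment order is Hex, HexNAc,
dHex, NeuAc, NeuGc, HexA with zero segments omitted. NeuGc's position is
fixed by declaration (no reference example exercises it). The builder never
queries the service.

## Plate files and batch I/O

The plate file mirrors a 384-spot MALDI plate: sheet row 1 holds common
parameters as self-describing `key=value` cells (`is_pmol`, `tolerance_da`,
optional `protein_level`; unknown keys are carried through), rows 2–17 map
to plate rows A–P and sheet columns 1–24 to plate columns. Spot grammar:
`<volume>_<replicate>` for calibration spots (replicate optional, defaulting
to per-volume occurrence order), `<series>#<label>` for category spots, and
a bare integer as a category series with itself as label. Masslist tabs pair
with occupied spots by position (tab i ↔ i-th occupied spot, row-major);
an explicit tab→address map can override this. Every tab is routed to
exactly one of `calibration_line/` or `analysis/`; count mismatches are
errors rather than guesses. Per-spot inputs are plain CSV (a `key,value`
metadata block, then `mz,area` rows), so they remain hand-editable, and
regeneration is byte-identical.

## Synthetic data generator

`SyntheticDesign` emulates the calibration study design: a panel of glycans
at fixed serum concentrations (pmol/µL), spotted at 2/4/6/8/10 µL with 4
replicates (the defaults), an internal standard at 20 pmol per spot, and a
linear detector response (area = pmol × 1000 by default). Noise model:
Gaussian m/z jitter (`mz_sigma`), multiplicative Gaussian area noise
(`area_cv`), and uniformly placed contaminant peaks kept at least
max(2·mz_sigma, `noise_exclusion`=0.3 Da) away from real masses (optionally
from an entire candidate list). A category mode assigns series labels and
per-series concentration scales instead of volumes. Seeded runs are
bit-reproducible.

What the generator does **not** emulate: ionization suppression, per-glycan
response factors, isotope envelopes, baseline/chemical noise continua,
detector saturation, or mass-dependent calibration drift. Passing tests
therefore demonstrate correctness of the analysis chain (matching,
clustering, quantitation, fitting, filtering) under its stated assumptions —
not quantitative accuracy on real spectra, where response factors and
suppression dominate.

## Problem sizes and numerical choices

The test suite runs on the full default candidate list (6,333 entries) and
synthetic plates of 20–384 spots with panels of 1–20 glycans; these sizes
exercise every code path while keeping the suite fast. Ties in clustering
are broken by processing order (ascending m/z, then experiment name), making
all CSV outputs byte-deterministic for identical inputs and configuration;
HTML output embeds matplotlib SVG and is deterministic up to library
versioning. Peak matching uses a sorted-mass binary search; clustering is
O(n·k) in matched peaks × open clusters, ample for 384-spot plates.

## Known limitations

* Composition-level annotation only; isobaric candidates stay unresolved.
* One-point internal-standard quantitation assumes equal response, so
  reported pmol are relative estimates unless calibrated per glycan.
* The enumeration rules are a declared superset heuristic, not a curated
  biosynthetic database; rare structures outside the rules must be appended
  to the list CSV by hand (supported and tested).
* The 15-digit ID caps any single residue count at 9.
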