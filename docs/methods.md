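# Methods

## The assay model

`rcaspot` models cyclic padlock/RCA single-molecule in situ hybridization:
each detected RNA molecule becomes one rolling-circle product, imaged as a
bright, approximately Gaussian dot far above tissue background. Genes are
read out over hybridization cycles × fluorophore channels; a nuclear stain
is re-imaged every cycle and carries the only registration information.
Quantification is per "cell", defined operationally as a segmented nucleus
expanded by a fixed physical distance. All downstream claims therefore
concern dots-per-cell-ROI, not molecules-per-biological-cell: the 2-µm halo
undercounts cytoplasm-rich cells and crowded dots merge (saturation), which
is why the saturation QC exists.

## Synthetic fields

The simulator is a first-class module, not a fixture. It generates:

* **Nuclei** — ellipses with axes drawn uniformly from a configured range
  (default 1.8–2.8 µm), placed by rejection sampling with a mask-level
  overlap test (no bounding-box shortcuts) and a retry cap; failure raises
  an explicit density error. At the default 0.325 µm/px these radii put the
  mean 2-µm-expanded cell area near 45 µm², the regime in which the
  capacity arithmetic (≈80 dots/cell) applies.
* **Types and counts** — each cell draws a type by configured proportions;
  per-gene counts are Poisson with type-specific rates λ(type, gene). The
  marker-structured default (`default_airway_types`) gives each type its
  selective markers at a common rate and all foreign genes at a low
  background rate.
* **Dots** — placed uniformly over the cell's *own* pixels of the expanded
  nearest-nucleus partition (with sub-pixel jitter). Because this is
  exactly the region the counting stage integrates, count recovery is
  limited only by detection, making recovery tests sharp.
* **Rendering** — isotropic Gaussian PSF (default σ = 0.355 µm, chosen so
  the half-maximum footprint is ≈ 4.36 σ² ≈ 0.55 µm²), flat background,
  additive Gaussian read noise, optional autofluorescent clutter rendered
  4× wider and 4× dimmer than dots (so it is rejectable by area, not by
  threshold), per-cycle rigid shift applied after rendering, and clipping
  to a declared bit depth (default 16).
* **Determinism** — one `numpy` Generator keyed by the seed drives both
  truth and rendering; identical config + seed gives bitwise-identical
  images and tables.

What the simulator does **not** emulate: 3D defocus, optical aberrations,
channel bleed-through, photobleaching, tissue-structured background, or
segmentation errors. Passing recovery tests therefore demonstrate the
correctness of the pipeline's arithmetic and its robustness to noise,
drift, and clutter — not performance on real tissue.

## Registration

Translation-only alignment: slides imaged on an automated stage between
chemistry cycles drift but do not rotate or scale appreciably; this is a
documented limitation, and nonrigid correction is out of scope. The shift
of each cycle's nuclear image against the reference cycle maximizes true
normalized cross-correlation over a ±`max_shift` grid (computed with the
fast NCC of `skimage.feature.match_template` on the centre crop), with
confidence = the NCC peak. Offsets are integer by default because dot
counting is integer-raster; an optional separable parabolic refinement
gives sub-pixel offsets. All-constant images return confidence 0 rather
than raising, and cycles with confidence < 0.3 are flagged but still
processed (fail-soft for QC review). On simulated nuclei, integer drifts
up to ±15 px are recovered exactly.

## Segmentation

Nuclear masks are an input (manual or external segmentation); the package
only expands them. Expansion assigns every background pixel within
*d* = 2 µm (Euclidean distance to the nucleus *region*, via per-label
distance transforms on inflated bounding boxes) to its nearest nucleus.
Exact distance ties go to the lower label id — deterministic and
order-independent. The result is a partition: no pixel carries two labels,
every cell contains its nucleus, and no cell pixel is farther than *d*
from its own nucleus. The ROI size filter flags (never deletes) cells
outside mean ± k·SD (population SD, k = 2 default); a degenerate SD of 0
keeps everything. Manual curation enters as an exclusion-list of cell ids,
not an algorithm.

## Dot detection and counting

Candidate dots come from a multi-scale Laplacian of Gaussian
(`skimage.feature.blob_log`, five scales over σ = 0.2–0.6 µm) with a
permissive internal response threshold; candidates are then gated on raw
peak height above background (image median unless supplied). Multi-scale
duplicates within one dot radius collapse to the brightest. Each dot's
area is the pixel count of the connected half-maximum support around its
peak; when several detected peaks share one support (dots crowded inside a
cell), the support area is divided by the number of peaks it contains, so
the area gate (default 0.1–2.0 µm², bracketing the ~0.55 µm² apparent dot
footprint) rejects single-peak clutter blobs without discarding crowded
true dots. Centroids are intensity-weighted over the support for isolated
dots, peak-pixel for shared supports. Thresholds are configuration values,
not automatic: comparisons across conditions should use the same ones.

Assignment is by the cell label under the rounded centroid pixel —
the simplest deterministic rule; background centroids stay unassigned and
are tallied so that assigned + unassigned = detected always holds.
Raw integrated density is a plain pixel sum over the footprint, no
background subtraction, matching the name. Ratio metrics use the
zero-reference convention: a cell with zero reference dots (or zero
reference intensity) gets ratio 0, not NaN.

## Positivity and annotation

The per-gene positivity threshold is `min(fraction · max_dots, cap)` with
defaults fraction = 0.10 and cap = 3, compared with strict `>` and no
rounding: this reproduces the printed behaviour (cap binds exactly for
per-cell maxima over 31, since 0.10 · 31 = 3.1 > 3) without inventing a
rounding rule. Maxima are taken per gene over the size-filtered cells.

Combinatorial typing: a type is satisfied when the cell is positive for at
least `min_positive` (default 2) of its selective markers — or its
single-marker exception holds (e.g. club: Scgb1a1 > 3 dots) — and no other
type contributes more than `max_foreign` (default 1) positive markers.
Exactly one satisfied type labels the cell; zero or several give "NA" with
the competing types recorded, because no tie-break is defined in the
protocol. The alveolar compartment uses fixed-order boolean rules instead
(NE → secretory → AT2 → macrophage → single-marker immune → AT1 → NA).

Saturation QC: capacity = ⌊cell area / mean dot area⌋ by plain division —
44.5/0.55 → 80 — deliberately not a disc-packing density, which plain
division reproduces the printed value without. Counts ≥ fraction·capacity
(and > 0) are flagged.

## Statistics

Expression values are log₂(dots + 1). Clustering is Ward on Euclidean
distances with ward.D2 semantics — distances not pre-squared, squared
criterion inside the Lance–Williams update, heights on the distance scale
(`scipy.cluster.hierarchy.linkage(..., "ward")`, which matches R's
`hclust(..., "ward.D2")`); the test suite verifies the merge sequence
against a brute-force O(n³) agglomerator. Spearman matrices use average
ranks for ties; constant columns yield missing values rather than zeros to
avoid silent artifacts. The reference-profile comparison reports Spearman ρ
as the primary statistic and carries Pearson r alongside, since both appear
in common practice for this comparison and neither is privileged here.
Fluorescence gating takes the maximum control-cell raw integrated density
as threshold with strict `>`, so every control cell is negative against its
own gate by construction.

## Probe design

Target windows of 40–45 nt are enumerated exhaustively, filtered by GC
fraction (default 0.35–0.65) and a homopolymer cap (runs > 4 rejected),
and ranked by |Tm − 70 °C| of the full footprint duplex. Tm is computed
from unified nearest-neighbor DNA/DNA parameters (SantaLucia & Hicks 2004)
with initiation and terminal-A·T terms, the entropic salt correction
ΔS += 0.368·(N−1)·ln[Na⁺], and Tm = ΔH/(ΔS + R·ln(CT/4)); defaults
CT = 0.05 µM and 50 mM monovalent salt match the assay's hybridization
conditions. The implementation is independent of Biopython's and is tested
against it to < 0.1 °C on 1,000 random oligos. Vendor-tool agreement is
not claimed.

Arm split: the window's reverse complement is cut at the midpoint, the
extra base of odd windows going to the 3′ arm; the assembled oligo is
5′arm + backbone + 3′arm, and by construction
revcomp(3′arm ∥ 5′arm) = window. Hybridized, the probe's 5′-phosphate end
abuts the 3′-OH end at the junction, recorded as the target coordinate of
the first base covered by the 3′ arm:

```
mRNA 5'—[ window 5' half ][ window 3' half ]—3'
            ||||||||||        ||||||||||
probe    3'-arm5 ... 5'-P  3'-OH ... arm3-5'   (circularized via backbone)
                        ^nick = junction
```

Detection oligos are center-anchored subsequences of the gene-specific
backbone region, scored at every length from 10 nt up to the full region;
the minimizer of |Tm − 56 °C| wins, ties to the shorter oligo. If the best
candidate misses by > 5 °C a warning is raised and the best effort
returned (an AT-rich region whose full length stays below 56 °C returns
the full region). T→U substitution is applied last; the oligo is a
U-substituted subsequence of its region by construction.

The off-target scan is an exact/near-exact sliding-window Hamming scan:
a hit is any transcript locus where both arm footprints match contiguously
and adjacently with at most `max_mismatches_per_arm` mismatches each; the
intended site is reported but excluded from the off-target count. This is
a desk-scale substitute for an alignment-based (BLAST) specificity search
and will miss gapped or split matches.

## Problem sizes and numerical choices

The test suite exercises the full-scale counting scenario once — a 2048²
field (≈ 443,000 µm²) with 500 cells, 15 genes over five cycles, clutter,
and drifts up to ±12 px — at a per-gene rate of 2 dots/cell for selective
markers, keeping the field below 0.02 dots/µm², where ≥ 95% of
(cell, gene) entries are recovered exactly. Other tests use 256–768-px
fields with 12–120 cells, sizes at which every stage runs in seconds.
Registration recovery uses 20 independently seeded stacks with drifts up
to ±15 px. Annotation recovery uses selective rate 8 vs background 0.2 on
120 cells. Tolerances: analytic disc-area agreement to 3% (discretization),
Tm oracle agreement to 0.1 °C, Ward heights to relative 1e-9, composition
sums to 1e-9.

## Known limitations

Translation-only registration; centroid-based dot assignment (a dot
straddling a boundary is not split); no deconvolution of merged dots into
molecule counts (crowding is flagged, not corrected); the off-target scan
is ungapped; the generative noise model (Gaussian PSF + additive noise) is
a stand-in, not a claim about any particular microscope; nuclear
segmentation quality is entirely the caller's responsibility.
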