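# Methods

## The procedure

`probhab` evaluates a set of pre-existing continuous habitat-suitability
rasters for one species and combines them into two disjoint map products.
The procedure assumes nothing about how the models were built — they are
treated as delivered artifacts with metadata (delivered threshold, full
surface vs. values-above-threshold-only, masked vs. unmasked variant) — and
it never refits a suitability surface.

**Construction audit.** The rubric has 23 topics in five categories. Three
topics are computed from the occurrence records for the model-building
window; the remaining 20 require judgement about contractor documentation
and are supplied as an evidence config (topic → rating + note). A topic
with no evidence defaults to *interpret with caution*: an undocumented
modelling step is not defensible. Three computed topics carry exclusion
gates; all three must pass for the model to be *acceptable*:

| gate | fails when | rating bands |
|---|---|---|
| occurrence count | n < 10 | ideal > 50; acceptable 25–50; caution < 25 (acceptable if the species' very small range is well understood — a manual flag, since no operational test exists) |
| occurrence age | majority (> 50 %) of records ≤ 1950 | ideal: all ≥ 2000; caution: > 20 % ≤ 1980; else acceptable |
| spatial accuracy | majority of records in classes 6–10 | ideal: all precise; acceptable: ≥ 80 % precise; else caution |

"Precise" means accuracy class 1, 2 or 4, or class 3 with equivalent radius
√(area/π) ≤ 150 m. "Majority" is read strictly (> 50 %), "most" as ≥ 80 %,
"substantial portion" as > 20 %. Gates are evaluated on the full
pre-thinning record set for the window, because they judge the data the
model was built from, not the evaluation subset.

**Evaluation points.** Occurrence polygons are filtered to the evaluation
window (inclusive, default 1981–2012) and to precise records, reduced to
internal centroids (the geometric centroid when it lies inside the polygon,
otherwise a deterministic interior representative point), and thinned to a
maximal subset with pairwise separation ≥ 430 m so that no two points share
a pixel in any model under test. Maximum-cardinality thinning is a maximum
independent set on the distance-conflict graph (NP-hard), so the default
solver is a seeded randomized greedy: one deterministic pass with
candidates in record-id order plus 99 random-order restarts, keeping the
largest result. Every greedy result is maximal (each excluded point
conflicts with a retained one) and the deterministic pass bounds the result
from below. An exact branch-and-bound is available for n ≤ 15 and anchors
the tests.

**Calibration.** The capture rate of a binary map is the fraction of
evaluation points whose containing pixel is suitable, with *suitable ⇔
value ≥ threshold* (closed comparison, so a delivered threshold reproduces
the contractor's footprint including boundary values). Candidate
thresholds are the model's values at the evaluation points: the capture
rate only changes at those values, so the search is exact and O(n log n).
Three modes:

* `at_least` — largest threshold with rate ≥ target;
* `closest_above` — threshold with the smallest rate ≥ target
  (the reading of "approximately 80 %" used for per-model calibration:
  never under-capture relative to the stated minimum);
* `closest` — rate nearest the target on either side, ties broken toward
  the rate ≥ target (the single-model "as close as possible" rule).

Evaluation points outside a model's extent or on nodata stay in the
denominator but can never be captured — a model is penalized for not
covering an occurrence. Above-threshold-only deliveries may only have
their threshold raised; if the delivered footprint under-captures, the
model is ineligible.

**Probable habitat.** Gate-passing models calibrated to their per-model
target (0.80 default; 0.78 for contractors flagged as unable to match
rates closely) form the boundary as the union of their binary maps. If the
union captures < 90 % (89 % when a flagged model is included), thresholds
are lowered greedily: repeatedly take the uncaptured point with the
highest suitability in any lowerable (full-surface) model, lower that
model's threshold to that value, recompute. The rule is deterministic,
moves thresholds minimally, and captures at least one new point per
iteration, so it terminates; union capture is asserted non-decreasing at
every step. With exactly one qualifying model, that model is calibrated
directly as close to the boundary target as possible. Inside the boundary,
all gate-passing models are overlaid at their final thresholds
(calibration failures at their delivered threshold) for the per-pixel
model count and mean standardized score. Open water is masked before any
statistics; developed land cover is reported in area tables but never
masked, because mapped occurrences are known to fall in pixels classified
as developed.

**Potential habitat.** Models not used for the boundary — gate failures,
calibration failures — plus unmasked variants of masked boundary models,
each thresholded as close to 0.80 capture as possible (delivered threshold
kept when calibration is impossible). Their union outside the probable
boundary is the potential footprint; the two products are disjoint by
construction. Potential maps are intended only to target future surveys.

**Standardization.** Model scores are rescaled per model by
s = 1 + 99·(x − min)/(max − min) over valid pixels, mapping each model's
range onto 1–100; a constant surface maps to 100. The per-pixel mean score
averages, by default, the standardized scores of every contributing model
valid at the pixel; averaging only the models that predict *suitable*
there is an equally defensible reading and is exposed as
`score_mode="suitable_only"`. No fidelity claim is made for either.

## Grids, projections, formats

Rasters are single-band north-up grids with square pixels in a projected
metre CRS, stored as ESRI ASCII grids (plain text; no raster library is
required). Alignment to the common grid uses nearest-neighbour sampling at
target pixel centers — values are copied, never interpolated, so no
contractor value is invented or lost — on the union extent at the finest
input resolution by default. Products carry a metadata note recommending
use at no resolution finer than the coarsest contributing model.

Vector occurrences are GeoJSON. Geographic (lon/lat) inputs are projected
with a built-in ellipsoidal sinusoidal projection centred on the data: the
sinusoidal projection is equal-area on the ellipsoid, so polygon areas —
the quantity the 150-m radius rule and the area tables depend on — equal
geodesic areas (verified in the tests against an independent geodesic
oracle to < 0.5 %). Shear grows away from the central meridian, so the
projection is for regional windows, not continents.

## The synthetic generator

`probhab.simulate` emulates the study conditions end to end. Covariate
fields are Gaussian-filtered white noise (correlation length 2 km over a
20 km window, 30 m truth grid); truth suitability is the logistic function
of a fixed linear combination, hence strictly in (0, 1). Occurrence
centers are sampled with probability proportional to truth; each becomes a
circular buffer with radius drawn per accuracy class (classes 1, 2, 4:
20–80 m; class 3: 50–400 m, deliberately straddling 150 m; classes 6–10:
0.5–5 km) and a year drawn from a mix spanning 1940–2018 (mostly
1981–2012, with pre-1981 and post-2012 tails so both the QC filter and the
independent-evaluation path are exercised). The default three contractors
mirror the structural quirks the pipeline must handle: a clean 270-m
full-surface model; a noisier 330-m model masked to occupied 4-km
synthetic "watersheds" (unmasked companion attached, capture target 0.78);
and a 210-m above-threshold-only delivery built without one covariate.
All draws come from seeded generators; a fixed seed reproduces every
surface, record and model bit-for-bit.

What the generator does **not** emulate: irregular real occurrence
polygons (buffers suffice because only area and containment matter
downstream), ecological realism of covariates, spatial survey bias, and
contractor models built from genuinely different occurrence sets. Passing
tests therefore demonstrate that the *procedure* satisfies its guarantees
(gate placement, separation bounds, capture-rate floors, disjointness,
score ranges) — not that any real model is well calibrated.

## Numerical choices

* Suitability comparisons are closed (≥); the at-the-limit class-3 polygon
  (area exactly π·150²) is retained via a 10⁻⁹ relative tolerance on the
  radius comparison.
* Greedy thinning breaks ties by record-id lexicographic order; restarts
  are seeded; subset selection down to a fixed evaluation size is a seeded
  draw (any subset of a separated set remains separated).
* Distances are planar Euclidean in the working metre CRS.
* Area conversion uses 1 m² = 0.000247105381 acres.
* Degenerate inputs: empty evaluation sets raise rather than return NaN;
  all-nodata grids cannot be standardized; an empty leftover set yields an
  explicitly empty potential product.

## Problem sizes

The shipped tests and the acceptance script run on a 20 km window (667²
truth grid, three contractor models at 270/330/210 m, 120 occurrence
records, 60 evaluation points) and on 8-km windows for property suites —
sizes chosen so a full run completes in seconds on one core while every
code path (masking, truncation, gate failure, threshold lowering) is
exercised. The pipeline itself is resolution- and extent-agnostic;
production-scale inputs (10-m common grids over ~10⁵ km²) stream through
the same code paths with memory proportional to the common-grid size.

## Known limitations

* The boundary-lowering rule and the per-pixel score averaging are
  documented package choices among several defensible readings of the
  procedure; alternatives are exposed where reasonable (`score_mode`).
* Whether capture-rate denominators should include points outside a
  partial-extent model is a genuine ambiguity; the strict reading
  (include) is implemented, which penalizes non-coverage.
* GeoPackage/shapefile readers and full CRS machinery are out of scope;
  inputs must be GeoJSON/ASCII-grid in metres (or lon/lat GeoJSON via the
  built-in projection).
* The rubric's 20 qualitative topics are config-driven by design: rating
  contractor reports is judgement, and the package keeps the
  computed/judgement boundary explicit rather than pretending to parse
  prose.
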