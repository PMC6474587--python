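# probhab

Evaluate pre-existing habitat-suitability models and combine them into
**probable** and **potential** suitable-habitat map products.

Land-management agencies often receive several habitat-suitability models for
the same rare species from different contractors — built from different
occurrence sets, covariates, algorithms, extents and resolutions, sometimes
delivered only above a chosen threshold or masked to occupied watersheds.
Before such maps can back regulatory decisions (surface-disturbance caps,
project screening, survey planning), the agency must decide which models are
defensible and how to combine them. `probhab` implements a two-pronged
procedure for exactly that:

1. **Construction audit.** Each model is rated against a fixed rubric of 23
   topics in five categories (occurrence data, environmental covariates,
   modelling algorithm, extent/resolution, model selection & thresholds),
   each topic scored *ideal* / *acceptable* / *interpret with caution*.
   Three occurrence-data topics carry hard **exclusion gates** computed
   directly from the records: a model is *acceptable* only if it was built
   from ≥ 10 occurrences, a majority of records post-1950, and a majority
   with precise locational accuracy (heritage-programme accuracy classes
   1, 2, 4, or class 3 within a 150 m equivalent radius).
2. **Performance evaluation and recalibration.** Occurrence polygons are
   QC-filtered, reduced to internal centroids, and spatially thinned to a
   maximal subset with pairwise separation ≥ 430 m. Model performance is the
   **capture rate** — the fraction of evaluation points whose pixel is
   classified suitable,

   C(t) = (1/n) · Σᵢ 1[ s(xᵢ) ≥ t ],

   where s is the continuous suitability surface and t the threshold. Each
   gate-passing model's threshold is recalibrated so that C(t) ≈ 0.80 (0.78
   for contractors whose methods cannot match rates closely). The union of
   these binary maps is the **probable suitable habitat** boundary; if the
   union captures < 90 % (89 % with a relaxed-target model), thresholds of
   full-surface models are greedily lowered until it does. Inside the
   boundary, *every* gate-passing model is overlaid to give a per-pixel
   model count and mean standardized suitability score (1–100). Leftover
   models — gate failures, uncalibratable deliveries, unmasked variants —
   form the disjoint **potential suitable habitat** map used only to target
   future surveys.

Because real contractor rasters and heritage records are proprietary, the
package ships a first-class synthetic-data generator (`probhab.simulate`)
that emulates them: smooth truth surfaces, clustered occurrence polygons
with mixed accuracy classes and dates, and contractor-style model variants
(coarser grids, above-threshold-only delivery, watershed masking).

## Worked example

```sh
$ probhab simulate --seed 7 --out demo/species
workspace written to demo/species (120 records, 3 models)

$ probhab evaluate demo/species
A: acceptable (gates: count=True age=True accuracy=True)
B: acceptable (gates: count=True age=True accuracy=True)
C: acceptable (gates: count=True age=True accuracy=True)

$ probhab calibrate demo/species --seed 7
A,0.3331992788265225,0.24088746,0.8095,True
B,0.3360935585494815,0.31893746,0.7937,True
C,0.3363102367550771,,0.6667,False

$ probhab probable demo/species --out demo/probable --seed 7
probable habitat: capture=0.905 models=['A', 'B', 'C']

$ probhab potential demo/species --out demo/potential --probable-dir demo/probable --seed 7
potential habitat: 186 pixels

$ probhab areas demo/probable
region  pixels      km2       acres
 total    5493 242.2413 59859.12873
```

Reading the output: all three synthetic contractors pass the exclusion
gates. Models A and B can be recalibrated to their capture targets (0.81 at
threshold 0.241; 0.79 ≥ 0.78 for the relaxed-target contractor B) and form
the boundary; contractor C delivered only values above its threshold and
captures 67 % — it cannot be lowered to 80 %, so it is mapped *inside* the
boundary only. The union boundary captures 90.5 % of the 63 evaluation
points (requirement 0.89 because B is included). The potential map — the
unmasked variant of B plus C's footprint outside the boundary — is disjoint
from the probable map by construction. The area table converts the
footprint at the pixel size of the common grid (210 m here) into km² and
acres.

The same pipeline is available as a library (`build_evaluation_set`,
`evaluate_model`, `calibrate_threshold`, `build_probable`,
`build_potential`, `multispecies_count`, `area_summary`).

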