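"""Probable and potential suitable-habitat products, stacks, and area tables.

*Probable* suitable habitat (for land-use decisions) is built only from models
that passed all three occurrence-data exclusion gates AND met (or could be
recalibrated to meet) the per-model capture-rate requirement (80%, relaxed to
78% for flagged contractors).  The union of those models' binary maps is the
outer boundary; if the union captures fewer than 90% (89% when a flagged model
is included) of the evaluation points, thresholds of full-surface models are
greedily lowered until the union does.  Inside the boundary every
gate-passing model is overlaid — including those that failed calibration — to
give a per-pixel model count and a per-pixel mean standardized suitability
score (1-100).

*Potential* suitable habitat (for targeting future surveys only) comes from
the leftovers: models that failed a gate or could not be calibrated, plus
unmasked variants of masked models that were used for the probable boundary.
Each is thresholded as close to an 80% capture rate as possible (delivered
threshold kept when calibration is impossible) and their union *outside* the
probable boundary is the potential footprint, so the two products are disjoint
by construction.

Open water is masked from final products; developed land cover is reported in
the area summaries but never masked, since mapped occurrences are known to
fall in pixels classified as developed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry.base import BaseGeometry

from .calibration import (
    BinaryHabitatMap,
    CalibrationResult,
    SuitabilityModel,
    align_to_common_grid,
    calibrate_threshold,
    capture_rate,
    standardize_scores,
)
from .errors import AlignmentError, ParameterError, ProductNotPossibleError
from .grids import Grid, GridSpec, resample_nearest
from .occurrences import EvaluationSet
from .rubric import RubricEvaluation

__all__ = [
    "ACRES_PER_M2",
    "OverlayLayer",
    "HabitatProduct",
    "build_probable",
    "build_potential",
    "multispecies_count",
    "area_summary",
]

ACRES_PER_M2 = 0.000247105381


@dataclass
class OverlayLayer:
    """A named overlay (managed lands, development focus areas, developed
    land cover, water mask, ...) as polygons or a categorical raster."""

    name: str
    geometry: BaseGeometry | None = None
    grid: Grid | None = None

    def __post_init__(self) -> None:
        if (self.geometry is None) == (self.grid is None):
            raise ParameterError(
                f"overlay {self.name!r}: supply exactly one of geometry or grid"
            )

    def rasterize(self, spec: GridSpec) -> np.ndarray:
        """Boolean membership of each pixel center of ``spec`` in the layer."""
        if self.grid is not None:
            g = resample_nearest(self.grid, spec)
            return np.nan_to_num(g.data, nan=0.0) > 0
        xs, ys = spec.pixel_centers()
        xx, yy = np.meshgrid(xs, ys)
        return shapely.contains_xy(self.geometry, xx, yy)


@dataclass
class HabitatProduct:
    """A probable or potential suitable-habitat map product.

    ``boundary`` holds the product footprint as a 0/1 grid (for probable maps
    this is the outer boundary; for potential maps the potential footprint).
    ``model_count`` and ``mean_score`` are valid only inside the footprint.
    ``use_resolution_m`` records the coarsest contributing model's native
    resolution: the product is emitted on the common (finest) grid so that no
    contributor's detail is lost, but should not be interpreted below the
    coarsest input's resolution.
    """

    species: str
    kind: str  # "probable" | "potential"
    boundary: Grid
    model_count: Grid
    mean_score: Grid
    thresholds_used: dict[str, float]
    capture_eval: float
    boundary_model_ids: tuple[str, ...] = ()
    capture_independent: float | None = None
    compliant: bool = True
    use_resolution_m: float | None = None
    notes: tuple[str, ...] = ()

    @property
    def pixel_size_m(self) -> float:
        return self.boundary.res

    def footprint_mask(self) -> np.ndarray:
        return np.nan_to_num(self.boundary.data, nan=0.0) >= 0.5

    def as_binary_map(self) -> BinaryHabitatMap:
        return BinaryHabitatMap(
            model_id=f"{self.species}:{self.kind}",
            threshold_used=0.5,
            grid=self.boundary,
        )


def _overlay_stats(
    models: Sequence[SuitabilityModel],
    thresholds: dict[str, float],
    footprint: np.ndarray,
    score_mode: str,
) -> tuple[Grid, Grid]:
    """Per-pixel model count and mean standardized score inside ``footprint``.

    ``score_mode`` = ``"all_valid"`` averages the standardized scores of every
    contributing model valid at the pixel; ``"suitable_only"`` averages only
    models predicting suitable there.
    """
    if score_mode not in ("all_valid", "suitable_only"):
        raise ParameterError(f"unknown score_mode {score_mode!r}")
    ref = models[0].grid
    count = np.zeros(ref.data.shape, dtype=float)
    score_sum = np.zeros(ref.data.shape, dtype=float)
    score_n = np.zeros(ref.data.shape, dtype=float)
    for m in models:
        thr = thresholds[m.model_id]
        suitable = m.binary_map(thr).suitable_mask()
        count += suitable
        scores = standardize_scores(m).grid.data
        contributes = np.isfinite(scores) if score_mode == "all_valid" else suitable
        score_sum += np.where(contributes, np.nan_to_num(scores, nan=0.0), 0.0)
        score_n += contributes
    with np.errstate(invalid="ignore"):
        mean = np.where(score_n > 0, score_sum / np.maximum(score_n, 1), np.nan)
    count_grid = ref.like(np.where(footprint, count, 0.0))
    mean_grid = ref.like(np.where(footprint & (score_n > 0), mean, np.nan))
    return count_grid, mean_grid


def _union_mask(
    models: Sequence[SuitabilityModel], thresholds: dict[str, float]
) -> np.ndarray:
    out = np.zeros(models[0].grid.data.shape, dtype=bool)
    for m in models:
        out |= m.binary_map(thresholds[m.model_id]).suitable_mask()
    return out


def _union_capture(
    models: Sequence[SuitabilityModel],
    thresholds: dict[str, float],
    points: EvaluationSet,
) -> float:
    ref = models[0].grid
    mask = _union_mask(models, thresholds)
    return capture_rate(
        BinaryHabitatMap("union", 0.5, ref.like(mask.astype(float))), points
    )


def build_probable(
    models: Sequence[tuple[SuitabilityModel, RubricEvaluation]],
    points: EvaluationSet,
    boundary_target: float = 0.90,
    per_model_target: float | None = None,
    water: OverlayLayer | None = None,
    independent_points: EvaluationSet | None = None,
    target_res_m: float | None = None,
    score_mode: str = "all_valid",
) -> HabitatProduct:
    """Build the probable-suitable-habitat product for one species.

    ``per_model_target`` overrides every model's own ``capture_target`` when
    given (the default honours the per-contractor 0.80 / 0.78 targets).  When
    a relaxed-target (0.78) model ends up in the union, the default 0.90
    boundary requirement relaxes to 0.89.

    Raises :class:`ProductNotPossibleError` when no model passes the gates or
    no gate-passing model can be calibrated (the species gets no probable
    map).  If the boundary target is unreachable even with all lowerable
    thresholds at their minimum, the best-achieved product is returned with
    ``compliant=False`` and a warning.
    """
    accepted = [m for m, ev in models if ev.acceptable]
    if not accepted:
        raise ProductNotPossibleError(
            f"{points.species}: no model passed all three exclusion gates"
        )
    accepted = align_to_common_grid(accepted, target_res_m=target_res_m)

    # (a) per-model calibration at each model's own (or the overridden) target
    calibrations: dict[str, CalibrationResult] = {}
    for m in accepted:
        target = per_model_target if per_model_target is not None else m.capture_target
        calibrations[m.model_id] = calibrate_threshold(
            m, points, target=target, mode="closest_above"
        )
    qualifying = [m for m in accepted if calibrations[m.model_id].eligible]
    if not qualifying:
        raise ProductNotPossibleError(
            f"{points.species}: no gate-passing model met or could be recalibrated "
            "to its capture-rate requirement"
        )
    thresholds: dict[str, float] = {
        m.model_id: calibrations[m.model_id].threshold for m in qualifying
    }

    flagged = any(m.capture_target < 0.80 for m in qualifying)
    eff_boundary_target = (
        0.89 if (flagged and abs(boundary_target - 0.90) < 1e-12) else boundary_target
    )
    notes: list[str] = []
    if flagged:
        notes.append(
            "union includes a relaxed-target contractor model; boundary requirement "
            f"set to {eff_boundary_target:.2f}"
        )

    compliant = True
    if len(qualifying) == 1:
        # (d) single-model rule: threshold as close to the boundary target as possible
        m = qualifying[0]
        res = calibrate_threshold(m, points, target=eff_boundary_target, mode="closest")
        if res.eligible:
            thresholds[m.model_id] = res.threshold
        union_cap = _union_capture(qualifying, thresholds, points)
        if union_cap < eff_boundary_target:
            notes.append(
                f"single-model boundary capture {union_cap:.3f} is the closest "
                f"achievable to {eff_boundary_target:.2f}"
            )
    else:
        # (b) union of calibrated maps; (c) greedy threshold lowering to target
        union_cap = _union_capture(qualifying, thresholds, points)
        lowerable = [m for m in qualifying if m.lowerable]
        while union_cap < eff_boundary_target - 1e-12:
            mask = _union_mask(qualifying, thresholds)
            ref = qualifying[0].grid
            vals = ref.like(mask.astype(float)).sample(
                points.coords[:, 0], points.coords[:, 1]
            )
            uncaptured = np.flatnonzero(~(np.nan_to_num(vals, nan=0.0) >= 0.5))
            # best (point, model) pair: the uncaptured point with the highest
            # suitability in any lowerable model — minimal threshold movement
            best: tuple[float, str] | None = None
            for m in lowerable:
                pv = m.grid.sample(
                    points.coords[uncaptured, 0], points.coords[uncaptured, 1]
                )
                pv = pv[np.isfinite(pv)]
                pv = pv[pv < thresholds[m.model_id]]
                if pv.size and (best is None or pv.max() > best[0]):
                    best = (float(pv.max()), m.model_id)
            if best is None:
                compliant = False
                warnings.warn(
                    f"{points.species}: boundary capture target "
                    f"{eff_boundary_target:.2f} unreachable (best {union_cap:.3f})",
                    stacklevel=2,
                )
                notes.append(
                    f"boundary target {eff_boundary_target:.2f} unreachable; "
                    f"best achieved {union_cap:.3f}"
                )
                break
            thresholds[best[1]] = best[0]
            new_cap = _union_capture(qualifying, thresholds, points)
            assert new_cap >= union_cap - 1e-12, "lowering a threshold reduced capture"
            union_cap = new_cap

    boundary_mask = _union_mask(qualifying, thresholds)

    # (e) inside the boundary, overlay ALL gate-passing models
    for m in accepted:
        if m.model_id not in thresholds:
            res = calibrations[m.model_id]
            if m.delivered_threshold is not None:
                thresholds[m.model_id] = float(m.delivered_threshold)
            else:
                valid = m.grid.data[m.grid.valid_mask()]
                thresholds[m.model_id] = float(valid.min()) if valid.size else np.inf
            notes.append(
                f"{m.model_id} failed calibration ({res.reason}); mapped inside the "
                "boundary at its delivered threshold only"
            )

    # (f) water mask, applied before any statistics
    if water is not None:
        boundary_mask &= ~water.rasterize(accepted[0].grid.spec)

    count_grid, mean_grid = _overlay_stats(accepted, thresholds, boundary_mask, score_mode)
    ref = accepted[0].grid
    boundary = ref.like(boundary_mask.astype(float))

    product = HabitatProduct(
        species=points.species,
        kind="probable",
        boundary=boundary,
        model_count=count_grid,
        mean_score=mean_grid,
        thresholds_used={k: float(v) for k, v in thresholds.items()},
        capture_eval=capture_rate(
            BinaryHabitatMap("probable", 0.5, boundary), points
        ),
        boundary_model_ids=tuple(m.model_id for m in qualifying),
        compliant=compliant,
        use_resolution_m=max(m.native_resolution_m for m in accepted),
        notes=tuple(notes),
    )
    if independent_points is not None and len(independent_points) > 0:
        product.capture_independent = capture_rate(product.as_binary_map(), independent_points)
    return product


def build_potential(
    models: Sequence[tuple[SuitabilityModel, RubricEvaluation]],
    probable: HabitatProduct | None,
    points: EvaluationSet,
    target: float = 0.80,
    water: OverlayLayer | None = None,
    score_mode: str = "all_valid",
) -> HabitatProduct:
    """Build the potential-suitable-habitat product for one species.

    Inputs are the models *not* used for the probable boundary (failed a gate
    or failed calibration) plus the unmasked variants of masked models that
    were used; each is thresholded as close to ``target`` capture as possible
    (delivered threshold kept when calibration is impossible), and the union
    is clipped outside the probable boundary.  With no leftover models and no
    unmasked variants the product is empty.
    """
    used_ids = set(probable.boundary_model_ids) if probable is not None else set()
    inputs: list[SuitabilityModel] = []
    for m, _ev in models:
        if m.model_id in used_ids:
            if m.unmasked_variant is not None:
                inputs.append(m.unmasked_variant)
        else:
            inputs.append(m.unmasked_variant if m.unmasked_variant is not None else m)

    if probable is not None:
        ref_spec = probable.boundary.spec
    elif inputs:
        from .grids import common_spec

        ref_spec = common_spec([m.grid for m in inputs])
    else:
        raise ProductNotPossibleError(f"{points.species}: no models at all")

    if not inputs:
        empty = Grid(
            np.zeros((ref_spec.nrows, ref_spec.ncols)),
            ref_spec.x0,
            ref_spec.y0,
            ref_spec.res,
        )
        return HabitatProduct(
            species=points.species,
            kind="potential",
            boundary=empty,
            model_count=empty.like(np.zeros(empty.data.shape)),
            mean_score=empty.like(np.full(empty.data.shape, np.nan)),
            thresholds_used={},
            capture_eval=0.0,
            notes=("no leftover models and no unmasked variants",),
        )

    inputs = [m.with_grid(resample_nearest(m.grid, ref_spec)) for m in inputs]

    thresholds: dict[str, float] = {}
    notes: list[str] = []
    for m in inputs:
        res = calibrate_threshold(m, points, target=target, mode="closest")
        if res.eligible:
            thresholds[m.model_id] = res.threshold
        elif m.delivered_threshold is not None:
            thresholds[m.model_id] = float(m.delivered_threshold)
            notes.append(
                f"{m.model_id}: calibration impossible ({res.reason}); "
                "delivered threshold kept"
            )
        else:
            valid = m.grid.data[m.grid.valid_mask()]
            thresholds[m.model_id] = float(valid.min()) if valid.size else np.inf
            notes.append(f"{m.model_id}: no threshold available; minimum valid value used")

    footprint = _union_mask(inputs, thresholds)
    if probable is not None:
        footprint &= ~probable.footprint_mask()
    if water is not None:
        footprint &= ~water.rasterize(ref_spec)

    count_grid, mean_grid = _overlay_stats(inputs, thresholds, footprint, score_mode)
    ref = inputs[0].grid
    boundary = ref.like(footprint.astype(float))
    return HabitatProduct(
        species=points.species,
        kind="potential",
        boundary=boundary,
        model_count=count_grid,
        mean_score=mean_grid,
        thresholds_used={k: float(v) for k, v in thresholds.items()},
        capture_eval=capture_rate(BinaryHabitatMap("potential", 0.5, boundary), points),
        use_resolution_m=max(m.native_resolution_m for m in inputs),
        notes=tuple(notes),
    )


def boundary_polygons(product: HabitatProduct) -> BaseGeometry:
    """Product footprint dissolved into a (multi)polygon of pixel squares."""
    mask = product.footprint_mask()
    rows, cols = np.nonzero(mask)
    g = product.boundary
    boxes = [
        shapely.box(
            g.x0 + c * g.res,
            g.y0 - (r + 1) * g.res,
            g.x0 + (c + 1) * g.res,
            g.y0 - r * g.res,
        )
        for r, c in zip(rows.tolist(), cols.tolist())
    ]
    return shapely.union_all(boxes) if boxes else shapely.Polygon()


def multispecies_count(products: Sequence[HabitatProduct]) -> Grid:
    """Per-pixel number of species whose probable footprint covers the pixel."""
    if not products:
        raise ParameterError("no products supplied")
    ref = products[0].boundary
    for p in products[1:]:
        if not ref.same_georeference(p.boundary):
            raise AlignmentError(
                "products must share one grid; resample before stacking"
            )
    count = np.zeros(ref.data.shape, dtype=float)
    for p in products:
        count += p.footprint_mask()
    return ref.like(count)


def area_summary(
    product: HabitatProduct, overlays: Sequence[OverlayLayer] = ()
) -> pd.DataFrame:
    """Suitable area in total and within each overlay, in km^2 and acres.

    Overlays may overlap each other, so overlay rows need not sum to the
    total.
    """
    footprint = product.footprint_mask()
    px_area = product.boundary.pixel_area_m2

    def row(name: str, mask: np.ndarray) -> dict:
        n = int(mask.sum())
        m2 = n * px_area
        return {
            "region": name,
            "pixels": n,
            "km2": m2 / 1e6,
            "acres": m2 * ACRES_PER_M2,
        }

    rows = [row("total", footprint)]
    for layer in overlays:
        rows.append(row(layer.name, footprint & layer.rasterize(product.boundary.spec)))
    return pd.DataFrame(rows, columns=["region", "pixels", "km2", "acres"])
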