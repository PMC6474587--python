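"""Threshold calibration of continuous suitability surfaces by capture rate.

The only performance statistic used anywhere in the pipeline is the *capture
rate*: the fraction of evaluation occurrence points whose containing pixel is
classified suitable (the complement of the omission rate).  A continuous model
is turned binary by a threshold (suitable iff value >= threshold, a closed
comparison so a contractor's delivered threshold reproduces their footprint),
and the threshold is recalibrated so the capture rate hits a target:

* ``at_least`` — the largest threshold whose rate is still >= target (the
  tightest map meeting the minimum);
* ``closest_above`` — the threshold achieving the smallest rate >= target
  (used to pull an over-capturing delivered threshold down to "approximately"
  the target without under-capturing);
* ``closest`` — the threshold whose rate is nearest the target on either side
  (the single-model "as close as possible" rule).

Candidate thresholds are the model's values at the evaluation points: the
capture rate only changes at those values, so the search is exact.  Models
delivered as values-above-threshold-only can never have their threshold
lowered below the delivered value; if the delivered footprint under-captures,
the model is ineligible.  Evaluation points falling outside a model's extent
or on nodata count in the denominator but can never be captured.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .errors import CRSError, ParameterError, UndefinedRateError
from .grids import Grid, GridSpec, common_spec, resample_nearest
from .occurrences import EvaluationSet

__all__ = [
    "DeliveryKind",
    "MaskVariant",
    "SuitabilityModel",
    "BinaryHabitatMap",
    "StandardizedGrid",
    "CalibrationResult",
    "align_to_common_grid",
    "capture_rate",
    "calibrate_threshold",
    "standardize_scores",
]


class DeliveryKind(str, Enum):
    FULL_SURFACE = "full_surface"
    ABOVE_THRESHOLD_ONLY = "above_threshold_only"


class MaskVariant(str, Enum):
    NONE = "none"
    MASKED = "masked"
    UNMASKED = "unmasked"


@dataclass
class SuitabilityModel:
    """One contractor's continuous suitability raster plus delivery metadata.

    ``capture_target`` is the per-model capture-rate requirement for
    probable-habitat mapping: 0.80 by default, relaxed to 0.78 for models from
    organisations whose methodology cannot closely match specific rates (when
    such a model joins the union, the boundary requirement relaxes 0.90 ->
    0.89 in step).
    """

    model_id: str
    contractor: str
    grid: Grid
    delivered_threshold: float | None = None
    delivery_kind: DeliveryKind = DeliveryKind.FULL_SURFACE
    mask_variant: MaskVariant = MaskVariant.NONE
    capture_target: float = 0.80
    native_resolution_m: float | None = None
    unmasked_variant: "SuitabilityModel | None" = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.delivery_kind = DeliveryKind(self.delivery_kind)
        self.mask_variant = MaskVariant(self.mask_variant)
        if self.native_resolution_m is None:
            self.native_resolution_m = self.grid.res
        if self.delivery_kind is DeliveryKind.ABOVE_THRESHOLD_ONLY:
            if self.delivered_threshold is None:
                raise ParameterError(
                    f"{self.model_id}: above_threshold_only delivery requires a "
                    "delivered_threshold"
                )
            valid = self.grid.data[self.grid.valid_mask()]
            if valid.size and valid.min() < self.delivered_threshold - 1e-12:
                raise ParameterError(
                    f"{self.model_id}: above_threshold_only grid contains values "
                    "below the delivered threshold"
                )

    @property
    def lowerable(self) -> bool:
        """Whether the threshold may be moved below its current value."""
        return self.delivery_kind is DeliveryKind.FULL_SURFACE

    def with_grid(self, grid: Grid) -> "SuitabilityModel":
        return SuitabilityModel(
            model_id=self.model_id,
            contractor=self.contractor,
            grid=grid,
            delivered_threshold=self.delivered_threshold,
            delivery_kind=self.delivery_kind,
            mask_variant=self.mask_variant,
            capture_target=self.capture_target,
            native_resolution_m=self.native_resolution_m,
            unmasked_variant=self.unmasked_variant,
        )

    def binary_map(self, threshold: float) -> "BinaryHabitatMap":
        """Suitable iff valid value >= threshold; nodata is unsuitable."""
        suitable = np.where(
            self.grid.valid_mask(), self.grid.data >= threshold, False
        )
        return BinaryHabitatMap(
            model_id=self.model_id,
            threshold_used=float(threshold),
            grid=self.grid.like(suitable.astype(float)),
        )


@dataclass
class BinaryHabitatMap:
    """A thresholded model on its grid; 1.0 = suitable, 0.0 = not."""

    model_id: str
    threshold_used: float
    grid: Grid

    @property
    def pixel_size_m(self) -> float:
        return self.grid.res

    def suitable_mask(self) -> np.ndarray:
        return self.grid.data >= 0.5


@dataclass
class StandardizedGrid:
    """Per-model suitability rescaled to the common 1-100 score scale."""

    model_id: str
    grid: Grid


@dataclass(frozen=True)
class CalibrationResult:
    model_id: str
    eligible: bool
    threshold: float | None
    achieved_rate: float | None
    reason: str = ""


def align_to_common_grid(
    models: list[SuitabilityModel], target_res_m: float | None = None
) -> list[SuitabilityModel]:
    """Resample all models onto one shared grid (union extent, nearest
    neighbour, default resolution = finest native resolution).  Values are
    never interpolated, so each output's value set is a subset of its input's.
    """
    if not models:
        raise ParameterError("no models supplied")
    crss = {m.grid.crs for m in models if m.grid.crs is not None}
    if len(crss) > 1:
        raise CRSError(f"models are in different CRSs: {sorted(crss)}")
    spec = common_spec([m.grid for m in models], res=target_res_m)
    return [m.with_grid(resample_nearest(m.grid, spec)) for m in models]


def capture_rate(bmap: BinaryHabitatMap, points: EvaluationSet) -> float:
    """Fraction of evaluation points whose containing pixel is suitable.

    Points outside the grid or on nodata stay in the denominator: a model
    that does not cover an occurrence has not captured it.
    """
    if len(points) == 0:
        raise UndefinedRateError("capture rate is undefined for an empty evaluation set")
    vals = bmap.grid.sample(points.coords[:, 0], points.coords[:, 1])
    captured = np.nan_to_num(vals, nan=0.0) >= 0.5
    return float(captured.sum()) / len(points)


def _rates_at_candidates(
    model: SuitabilityModel, points: EvaluationSet
) -> tuple[np.ndarray, np.ndarray]:
    """Candidate thresholds (sorted ascending, unique point values) and the
    capture rate at each.  Rate at threshold t = (#points with value >= t)/n,
    counting nodata/outside points only in n."""
    vals = model.grid.sample(points.coords[:, 0], points.coords[:, 1])
    n = len(points)
    finite = vals[np.isfinite(vals)]
    if finite.size == 0:
        return np.array([]), np.array([])
    cand = np.unique(finite)
    rates = np.array([(finite >= t).sum() / n for t in cand])
    return cand, rates


def calibrate_threshold(
    model: SuitabilityModel,
    points: EvaluationSet,
    target: float,
    mode: str = "at_least",
) -> CalibrationResult:
    """Choose a threshold whose capture rate meets ``target`` per ``mode``.

    Returns an ineligible result when the target cannot be met: every point
    sits on nodata, or an above-threshold-only delivery under-captures at its
    delivered threshold (its threshold may only rise).
    """
    if not 0 < target <= 1:
        raise ParameterError(f"target must be in (0, 1], got {target}")
    if mode not in ("at_least", "closest_above", "closest"):
        raise ParameterError(f"unknown calibration mode {mode!r}")
    if len(points) == 0:
        raise UndefinedRateError("cannot calibrate against an empty evaluation set")

    cand, rates = _rates_at_candidates(model, points)
    if cand.size == 0:
        return CalibrationResult(
            model.model_id, False, None, 0.0, "no evaluation point on a valid pixel"
        )
    if not model.lowerable:
        # threshold may only increase from the delivered value
        keep = cand >= model.delivered_threshold - 1e-12
        base_rate = capture_rate(model.binary_map(model.delivered_threshold), points)
        if base_rate < target:
            return CalibrationResult(
                model.model_id,
                False,
                None,
                float(base_rate),
                "delivered footprint under-captures and threshold cannot be lowered",
            )
        cand, rates = cand[keep], rates[keep]
        # the delivered threshold itself is also a candidate
        cand = np.append(cand, model.delivered_threshold)
        rates = np.append(rates, base_rate)
        order = np.argsort(cand)
        cand, rates = cand[order], rates[order]

    meets = rates >= target
    if mode == "closest":
        idx = int(np.argmin(np.abs(rates - target)))
        best = np.abs(rates - target)[idx]
        # tie-break toward the rate >= target (never under-capture on a tie)
        ties = np.flatnonzero(np.abs(np.abs(rates - target) - best) <= 1e-12)
        above = [i for i in ties if rates[i] >= target]
        idx = above[-1] if above else int(ties[-1])
    elif not meets.any():
        return CalibrationResult(
            model.model_id,
            False,
            None,
            float(rates.max()),
            f"best achievable capture rate {rates.max():.3f} < target {target:.2f}",
        )
    elif mode == "at_least":
        idx = int(np.flatnonzero(meets).max())  # largest threshold still meeting target
    else:  # closest_above: smallest rate that is >= target
        cand_idx = np.flatnonzero(meets)
        idx = int(cand_idx[np.argmin(rates[cand_idx])])
    return CalibrationResult(
        model.model_id, True, float(cand[idx]), float(rates[idx])
    )


def standardize_scores(model: SuitabilityModel) -> StandardizedGrid:
    """Linear min-max rescale of the model's valid values to [1, 100].

    ``s = 1 + 99 * (x - min) / (max - min)``; a constant-valued surface maps
    to 100 everywhere valid.  Affine-invariant: rescaling the input does not
    change the output.
    """
    valid = model.grid.valid_mask()
    if not valid.any():
        raise ParameterError(f"{model.model_id}: all-nodata grid cannot be standardized")
    vals = model.grid.data[valid]
    lo, hi = float(vals.min()), float(vals.max())
    out = np.full(model.grid.data.shape, np.nan)
    if hi == lo:
        out[valid] = 100.0
    else:
        out[valid] = 1.0 + 99.0 * (model.grid.data[valid] - lo) / (hi - lo)
    return StandardizedGrid(model.model_id, model.grid.like(out))
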