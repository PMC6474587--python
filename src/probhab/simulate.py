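"""Synthetic landscapes, occurrence records, and contractor-style models.

Real inputs to this pipeline — contractor suitability rasters and natural-
heritage occurrence records — are proprietary, so every stage is exercised
against synthetic data built here:

* a smooth *truth* suitability surface (logistic function of spatially
  autocorrelated covariate fields);
* occurrence polygons whose centers are sampled with probability proportional
  to truth, with heritage-style attributes: accuracy classes drawn from a mix
  (class-3 radii deliberately spanning both sides of the 150-m rule), record
  years from a mix spanning the evaluation window and both its tails, and
  occurrence ranks;
* 2-3 "contractor" model variants per species: the truth surface degraded by
  logit-scale noise and/or a missing covariate, aggregated to a coarser grid,
  optionally masked to occupied synthetic watersheds (with the unmasked
  companion attached), or truncated to values-above-threshold-only delivery.

Default parameters mirror the study conditions the pipeline was designed
around: a regional window with three contractors at distinct native
resolutions in the 200-350 m range, one relaxed-target masked model, one
above-threshold-only delivery, and on the order of a hundred records, most
of them precise and from the 1981-2012 window.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter
from shapely.geometry import Point

from .calibration import DeliveryKind, MaskVariant, SuitabilityModel
from .errors import ParameterError
from .grids import Grid
from .occurrences import OccurrenceRecord

__all__ = [
    "ContractorStyle",
    "SyntheticSpeciesConfig",
    "SyntheticSpecies",
    "default_styles",
    "three_full_surface_styles",
    "simulate_landscape",
    "simulate_occurrences",
    "simulate_contractor_models",
    "sample_truth_points",
    "synthetic_species",
]

#: buffer radius bounds (m) per accuracy class; class 3 straddles 150 m
CLASS_RADIUS_M: dict[int, tuple[float, float]] = {
    1: (20.0, 50.0),
    2: (30.0, 80.0),
    3: (50.0, 400.0),
    4: (40.0, 80.0),
    5: (150.0, 500.0),
    6: (500.0, 1500.0),
    7: (500.0, 2000.0),
    8: (800.0, 3000.0),
    9: (1000.0, 4000.0),
    10: (1500.0, 5000.0),
}

DEFAULT_ACCURACY_MIX = {1: 0.25, 2: 0.20, 3: 0.20, 4: 0.15, 6: 0.10, 8: 0.10}
DEFAULT_YEAR_MIX = {
    (1940, 1950): 0.02,
    (1960, 1980): 0.08,
    (1981, 1999): 0.50,
    (2000, 2012): 0.30,
    (2013, 2018): 0.10,
}
DEFAULT_RANK_MIX = {"Excellent": 0.3, "Good": 0.4, "Fair": 0.2, "Unknown": 0.1}


@dataclass(frozen=True)
class ContractorStyle:
    """How one synthetic contractor degrades and delivers the truth surface."""

    style_id: str
    contractor: str
    resolution_m: float
    noise_sd: float
    delivery_kind: DeliveryKind = DeliveryKind.FULL_SURFACE
    mask_variant: MaskVariant = MaskVariant.NONE
    capture_target: float = 0.80
    delivered_quantile: float = 0.60
    covariate_subset: tuple[str, ...] | None = None
    mask_tile_m: float = 4000.0  # synthetic "watershed" size for masked styles


def default_styles() -> tuple[ContractorStyle, ...]:
    """Three contractors with the structural quirks the pipeline must handle:
    a clean full-surface model, a noisier watershed-masked model from a
    relaxed-target contractor, and an above-threshold-only delivery built
    without one covariate."""
    return (
        ContractorStyle("A", "Contractor A", 270.0, 0.3),
        ContractorStyle(
            "B",
            "Contractor B",
            330.0,
            0.6,
            mask_variant=MaskVariant.MASKED,
            capture_target=0.78,
        ),
        ContractorStyle(
            "C",
            "Contractor C",
            210.0,
            0.5,
            delivery_kind=DeliveryKind.ABOVE_THRESHOLD_ONLY,
            covariate_subset=("cov1", "cov2"),
        ),
    )


def three_full_surface_styles() -> tuple[ContractorStyle, ...]:
    """Three full-surface contractors at distinct resolutions and noise
    levels — the configuration used for end-to-end boundary checks."""
    return (
        ContractorStyle("A", "Contractor A", 270.0, 0.3),
        ContractorStyle("B", "Contractor B", 330.0, 0.6),
        ContractorStyle("C", "Contractor C", 210.0, 0.5),
    )


@dataclass(frozen=True)
class SyntheticSpeciesConfig:
    seed: int
    species: str = "Synthspecies demoensis"
    window_km: float = 20.0
    truth_res_m: float = 30.0
    n_occurrences: int = 120
    accuracy_mix: dict[int, float] = field(default_factory=lambda: dict(DEFAULT_ACCURACY_MIX))
    year_mix: dict[tuple[int, int], float] = field(default_factory=lambda: dict(DEFAULT_YEAR_MIX))
    rank_mix: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_RANK_MIX))
    contractor_styles: tuple[ContractorStyle, ...] = field(default_factory=default_styles)
    correlation_length_m: float = 2000.0

    def __post_init__(self) -> None:
        if self.n_occurrences < 0:
            raise ParameterError("n_occurrences must be >= 0")
        if self.window_km <= 0 or self.truth_res_m <= 0:
            raise ParameterError("window_km and truth_res_m must be positive")
        for name, mix in (("accuracy_mix", self.accuracy_mix), ("year_mix", self.year_mix)):
            total = sum(mix.values())
            if mix and abs(total - 1.0) > 1e-9:
                raise ParameterError(f"{name} weights must sum to 1 (got {total})")


@dataclass
class SyntheticSpecies:
    """Everything one species contributes to the pipeline, in memory."""

    config: SyntheticSpeciesConfig
    truth: Grid
    covariates: dict[str, Grid]
    records: list[OccurrenceRecord]
    models: list[SuitabilityModel]


# coefficients of the covariate combination behind the truth surface
_TRUTH_COEFFS = {"cov1": 1.6, "cov2": 1.0, "cov3": -0.8}
_TRUTH_INTERCEPT = -1.2


def _smooth_field(shape: tuple[int, int], sigma_px: float, rng: np.random.Generator) -> np.ndarray:
    """Gaussian-filtered white noise, restandardized to mean 0 / sd 1."""
    f = gaussian_filter(rng.standard_normal(shape), sigma=sigma_px, mode="reflect")
    return (f - f.mean()) / f.std()


def simulate_landscape(
    config: SyntheticSpeciesConfig,
) -> tuple[Grid, dict[str, Grid]]:
    """Truth suitability surface and its covariate fields (seeded).

    Covariates are spatially autocorrelated (Gaussian-filtered noise with the
    configured correlation length); truth is the logistic function of a fixed
    linear combination of them, so values lie strictly in (0, 1).
    """
    n = int(round(config.window_km * 1000.0 / config.truth_res_m))
    if n <= 0:
        raise ParameterError("window is smaller than one truth pixel")
    rng = np.random.default_rng([config.seed, 0])
    sigma_px = config.correlation_length_m / config.truth_res_m
    covs = {
        name: _smooth_field((n, n), sigma_px, rng) for name in _TRUTH_COEFFS
    }
    eta = _TRUTH_INTERCEPT + sum(_TRUTH_COEFFS[k] * covs[k] for k in covs)
    truth_vals = 1.0 / (1.0 + np.exp(-eta))
    res = config.truth_res_m
    y0 = n * res
    truth = Grid(truth_vals, 0.0, y0, res, crs="local-metre")
    cov_grids = {k: Grid(v, 0.0, y0, res, crs="local-metre") for k, v in covs.items()}
    return truth, cov_grids


def _draw_from_mix(rng: np.random.Generator, mix: dict, size: int) -> list:
    keys = list(mix.keys())
    probs = np.array([mix[k] for k in keys], dtype=float)
    probs = probs / probs.sum()
    idx = rng.choice(len(keys), size=size, p=probs)
    return [keys[i] for i in idx]


def sample_truth_points(truth: Grid, n: int, seed: int) -> np.ndarray:
    """``n`` point coordinates sampled with probability proportional to the
    truth value of the containing pixel, jittered uniformly within it."""
    rng = np.random.default_rng(seed)
    p = truth.data.ravel()
    p = p / p.sum()
    cells = rng.choice(p.size, size=n, p=p)
    rows, cols = np.unravel_index(cells, truth.data.shape)
    xs = truth.x0 + (cols + rng.uniform(0, 1, n)) * truth.res
    ys = truth.y0 - (rows + rng.uniform(0, 1, n)) * truth.res
    return np.column_stack([xs, ys])


def simulate_occurrences(
    truth: Grid, config: SyntheticSpeciesConfig
) -> list[OccurrenceRecord]:
    """Heritage-style occurrence polygons clustered on high-truth areas.

    Each record is a circular buffer around a truth-weighted sample point,
    with radius drawn from its accuracy class's bracket, and year/rank drawn
    from the configured mixes.
    """
    n = config.n_occurrences
    if n == 0:
        return []
    high = int((truth.data > 0.5).sum())
    if n > high:
        warnings.warn(
            f"requested {n} occurrences but only {high} high-truth pixels exist; "
            "records will be strongly clustered",
            stacklevel=2,
        )
    rng = np.random.default_rng([config.seed, 1])
    centers = sample_truth_points(truth, n, seed=int(rng.integers(2**31)))
    classes = _draw_from_mix(rng, config.accuracy_mix, n)
    year_ranges = _draw_from_mix(rng, config.year_mix, n)
    ranks = _draw_from_mix(rng, config.rank_mix, n)
    records = []
    for i in range(n):
        cls = int(classes[i])
        lo, hi = CLASS_RADIUS_M[cls]
        radius = rng.uniform(lo, hi)
        y_lo, y_hi = year_ranges[i]
        year = int(rng.integers(y_lo, y_hi + 1))
        poly = Point(centers[i]).buffer(radius, quad_segs=16)
        records.append(
            OccurrenceRecord(
                record_id=f"occ{i:04d}",
                species=config.species,
                geometry=poly,
                accuracy_class=cls,
                year=year,
                occurrence_rank=str(ranks[i]),
                source="synthetic",
            )
        )
    return records


def _block_aggregate(grid: Grid, factor: int) -> Grid:
    """Mean-aggregate ``factor x factor`` blocks (truncating edge remainder)."""
    nrows, ncols = grid.data.shape
    nr, nc = nrows // factor, ncols // factor
    sub = grid.data[: nr * factor, : nc * factor]
    agg = sub.reshape(nr, factor, nc, factor).mean(axis=(1, 3))
    return Grid(agg, grid.x0, grid.y0, grid.res * factor, grid.crs)


def _watershed_mask(
    grid: Grid, occurrence_xy: np.ndarray | None, tile_m: float = 4000.0
) -> np.ndarray:
    """Synthetic "watersheds": square tiles; keep tiles containing at least
    one occurrence point (or, with no points given, above-average truth)."""
    nrows, ncols = grid.data.shape
    tile_px = max(1, int(round(tile_m / grid.res)))
    trow = np.arange(nrows) // tile_px
    tcol = np.arange(ncols) // tile_px
    ntr, ntc = trow.max() + 1, tcol.max() + 1
    keep_tiles = np.zeros((ntr, ntc), dtype=bool)
    if occurrence_xy is not None and len(occurrence_xy):
        row, col = grid.rowcol(occurrence_xy[:, 0], occurrence_xy[:, 1])
        ok = (row >= 0) & (row < nrows) & (col >= 0) & (col < ncols)
        keep_tiles[row[ok] // tile_px, col[ok] // tile_px] = True
    else:
        mean = np.nanmean(grid.data)
        for r in range(ntr):
            for c in range(ntc):
                block = grid.data[
                    r * tile_px : (r + 1) * tile_px, c * tile_px : (c + 1) * tile_px
                ]
                keep_tiles[r, c] = np.nanmean(block) > mean
    return keep_tiles[trow[:, None], tcol[None, :]]


def simulate_contractor_models(
    truth: Grid,
    styles: tuple[ContractorStyle, ...] | list[ContractorStyle],
    seed: int,
    covariates: dict[str, Grid] | None = None,
    occurrence_xy: np.ndarray | None = None,
) -> list[SuitabilityModel]:
    """One degraded model per style (seeded).

    Degradation = logit-scale autocorrelated noise (``noise_sd``), optionally
    rebuilding the surface from a covariate subset (a contractor missing a
    predictor), then block-mean aggregation to the style's native resolution.
    Masked styles are clipped to occupied synthetic watersheds with the
    unmasked companion attached; above-threshold-only styles are truncated at
    the delivered threshold (a quantile of the aggregated surface).
    """
    if not styles:
        raise ParameterError("at least one contractor style is required")
    models = []
    for k, style in enumerate(styles):
        rng = np.random.default_rng([seed, 2, k])
        if style.covariate_subset is not None:
            if covariates is None:
                raise ParameterError(
                    f"style {style.style_id}: covariate_subset requires covariates"
                )
            eta = _TRUTH_INTERCEPT + sum(
                _TRUTH_COEFFS[name] * covariates[name].data
                for name in style.covariate_subset
            )
        else:
            t = np.clip(truth.data, 1e-9, 1 - 1e-9)
            eta = np.log(t / (1 - t))
        if style.noise_sd > 0:
            sigma_px = 1000.0 / truth.res  # 1-km correlated model error
            noise = gaussian_filter(
                rng.standard_normal(truth.data.shape), sigma=sigma_px, mode="reflect"
            )
            noise = (noise - noise.mean()) / noise.std() * style.noise_sd
            eta = eta + noise
        surface = Grid(1.0 / (1.0 + np.exp(-eta)), truth.x0, truth.y0, truth.res, truth.crs)

        factor = style.resolution_m / truth.res
        if abs(factor - round(factor)) > 1e-9:
            raise ParameterError(
                f"style {style.style_id}: resolution must be a multiple of the "
                f"truth resolution ({truth.res} m)"
            )
        agg = _block_aggregate(surface, int(round(factor)))
        valid = agg.data[np.isfinite(agg.data)]
        delivered = float(np.quantile(valid, style.delivered_quantile))

        if style.delivery_kind is DeliveryKind.ABOVE_THRESHOLD_ONLY:
            data = np.where(agg.data >= delivered, agg.data, np.nan)
            agg = agg.like(data)

        unmasked_variant = None
        mask_variant = style.mask_variant
        if style.mask_variant is MaskVariant.MASKED:
            unmasked_variant = SuitabilityModel(
                model_id=f"{style.style_id}-unmasked",
                contractor=style.contractor,
                grid=agg,
                delivered_threshold=delivered,
                delivery_kind=style.delivery_kind,
                mask_variant=MaskVariant.UNMASKED,
                capture_target=style.capture_target,
                native_resolution_m=style.resolution_m,
            )
            keep = _watershed_mask(agg, occurrence_xy, tile_m=style.mask_tile_m)
            agg = agg.like(np.where(keep, agg.data, np.nan))

        models.append(
            SuitabilityModel(
                model_id=style.style_id,
                contractor=style.contractor,
                grid=agg,
                delivered_threshold=delivered,
                delivery_kind=style.delivery_kind,
                mask_variant=mask_variant,
                capture_target=style.capture_target,
                native_resolution_m=style.resolution_m,
                unmasked_variant=unmasked_variant,
            )
        )
    return models


def synthetic_species(
    config: SyntheticSpeciesConfig | int,
) -> SyntheticSpecies:
    """Full synthetic species: landscape + occurrences + contractor models.

    Accepts a config or a bare seed (all other parameters at their defaults).
    """
    if isinstance(config, int):
        config = SyntheticSpeciesConfig(seed=config)
    truth, covariates = simulate_landscape(config)
    records = simulate_occurrences(truth, config)
    occ_xy = (
        np.array([[r.geometry.centroid.x, r.geometry.centroid.y] for r in records])
        if records
        else None
    )
    models = simulate_contractor_models(
        truth,
        config.contractor_styles,
        seed=config.seed,
        covariates=covariates,
        occurrence_xy=occ_xy,
    )
    return SyntheticSpecies(config, truth, covariates, records, models)
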