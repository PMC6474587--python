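"""Shared synthetic fixtures.

Two scales are used: a *small* landscape (8 km window, 40-m truth grid) for
fast per-module checks, and the *study-scale* landscape (20 km window, 30-m
truth grid, three contractors, 60 evaluation points) for end-to-end checks.
Both are deterministic, built entirely at test time.
"""

from __future__ import annotations

import numpy as np
import pytest

import probhab as ph


def small_styles() -> tuple[ph.ContractorStyle, ...]:
    """Three full-surface contractors commensurate with a 40-m truth grid."""
    return (
        ph.ContractorStyle("A", "Contractor A", 120.0, 0.3),
        ph.ContractorStyle("B", "Contractor B", 160.0, 0.6),
        ph.ContractorStyle("C", "Contractor C", 200.0, 0.5),
    )


def small_mixed_styles() -> tuple[ph.ContractorStyle, ...]:
    """Small-scale version of the default masked / above-threshold mix."""
    return (
        ph.ContractorStyle("A", "Contractor A", 120.0, 0.3),
        ph.ContractorStyle(
            "B",
            "Contractor B",
            160.0,
            0.6,
            mask_variant=ph.MaskVariant.MASKED,
            capture_target=0.78,
            mask_tile_m=1500.0,
        ),
        ph.ContractorStyle(
            "C",
            "Contractor C",
            200.0,
            0.5,
            delivery_kind=ph.DeliveryKind.ABOVE_THRESHOLD_ONLY,
            delivered_quantile=0.75,
        ),
    )


def small_config(seed: int, styles=None, n_occurrences: int = 60) -> ph.SyntheticSpeciesConfig:
    return ph.SyntheticSpeciesConfig(
        seed=seed,
        window_km=8.0,
        truth_res_m=40.0,
        n_occurrences=n_occurrences,
        contractor_styles=tuple(styles if styles is not None else small_styles()),
        correlation_length_m=1500.0,
    )


def pipeline_pieces(sp: ph.SyntheticSpecies, seed: int, max_points: int | None = 60):
    """(model, rubric) pairs and the thinned evaluation set for a species."""
    window = (1981, 2012)
    in_window = [r for r in sp.records if window[0] <= r.year <= window[1]]
    pairs = [
        (m, ph.evaluate_model(m.model_id, in_window, {})) for m in sp.models
    ]
    points = ph.build_evaluation_set(
        sp.records, sp.config.species, window=window, seed=seed, max_points=max_points
    )
    return pairs, points


@pytest.fixture(scope="session")
def small_species() -> ph.SyntheticSpecies:
    return ph.synthetic_species(small_config(seed=11))


@pytest.fixture(scope="session")
def small_mixed_species() -> ph.SyntheticSpecies:
    return ph.synthetic_species(small_config(seed=12, styles=small_mixed_styles()))


@pytest.fixture(scope="session")
def study_species() -> ph.SyntheticSpecies:
    """Study-scale species: three full-surface contractors at distinct
    resolutions and noise levels on a 20-km landscape."""
    cfg = ph.SyntheticSpeciesConfig(
        seed=101, contractor_styles=ph.three_full_surface_styles()
    )
    return ph.synthetic_species(cfg)


@pytest.fixture(scope="session")
def study_probable(study_species):
    """Probable product + its inputs for the study-scale species."""
    pairs, points = pipeline_pieces(study_species, seed=101)
    product = ph.build_probable(pairs, points)
    return product, pairs, points


def flat_grid(values, res: float = 10.0, x0: float = 0.0, y0: float | None = None) -> ph.Grid:
    """Grid from a nested list; y0 defaults to nrows*res so bounds start at 0."""
    data = np.asarray(values, dtype=float)
    if y0 is None:
        y0 = data.shape[0] * res
    return ph.Grid(data, x0, y0, res, crs="local-metre")


def eval_points(coords, species: str = "sp", **kw) -> ph.EvaluationSet:
    coords = np.asarray(coords, dtype=float)
    ids = tuple(f"p{i}" for i in range(len(coords)))
    kw.setdefault("min_separation_m", 0.0)
    return ph.EvaluationSet(
        species=species, window=(1981, 2012), record_ids=ids, coords=coords, **kw
    )
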