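"""On-disk species workspace: the file layout the CLI reads and writes.

A workspace directory holds everything needed to run the pipeline for one
species::

    workspace/
      occurrences.geojson       # occurrence polygons with QC attributes
      models/<id>.asc           # continuous suitability rasters (ESRI ASCII)
      models.yaml               # per-model delivery metadata
      evidence.yaml             # rubric evidence config (topic -> rating/note)
      truth.asc                 # synthetic workspaces only

All files are plain text.
"""

from __future__ import annotations

import json
from pathlib import Path

import yaml
from shapely.geometry import mapping

from .calibration import DeliveryKind, MaskVariant, SuitabilityModel
from .errors import SchemaError
from .grids import Grid
from .occurrences import OccurrenceRecord, read_occurrences
from .simulate import SyntheticSpecies

__all__ = ["write_workspace", "load_models", "load_records", "load_evidence"]


def _records_to_geojson(records: list[OccurrenceRecord], path: Path) -> None:
    features = []
    for r in records:
        features.append(
            {
                "type": "Feature",
                "geometry": mapping(r.geometry),
                "properties": {
                    "record_id": r.record_id,
                    "species": r.species,
                    "accuracy_class": r.accuracy_class,
                    "year": r.year,
                    "occ_rank": r.occurrence_rank,
                    "source": r.source,
                },
            }
        )
    path.write_text(json.dumps({"type": "FeatureCollection", "features": features}))


def _model_meta(m: SuitabilityModel, raster: str, unmasked_raster: str | None) -> dict:
    meta = {
        "model_id": m.model_id,
        "contractor": m.contractor,
        "raster": raster,
        "delivered_threshold": m.delivered_threshold,
        "delivery_kind": m.delivery_kind.value,
        "mask_variant": m.mask_variant.value,
        "capture_target": m.capture_target,
        "native_resolution_m": m.native_resolution_m,
    }
    if unmasked_raster is not None:
        meta["unmasked_raster"] = unmasked_raster
    return meta


def write_workspace(species: SyntheticSpecies, outdir: str | Path) -> Path:
    """Write a complete synthetic species workspace; returns its path."""
    outdir = Path(outdir)
    (outdir / "models").mkdir(parents=True, exist_ok=True)
    species.truth.write_asc(outdir / "truth.asc")
    _records_to_geojson(species.records, outdir / "occurrences.geojson")

    metas = []
    for m in species.models:
        raster = f"models/{m.model_id}.asc"
        m.grid.write_asc(outdir / raster)
        unmasked = None
        if m.unmasked_variant is not None:
            unmasked = f"models/{m.unmasked_variant.model_id}.asc"
            m.unmasked_variant.grid.write_asc(outdir / unmasked)
        metas.append(_model_meta(m, raster, unmasked))
    (outdir / "models.yaml").write_text(
        yaml.safe_dump({"species": species.config.species, "models": metas})
    )
    # synthetic contractors document nothing beyond their rasters, so the
    # evidence config starts empty (every qualitative topic defaults to caution)
    if not (outdir / "evidence.yaml").exists():
        (outdir / "evidence.yaml").write_text(yaml.safe_dump({}))
    return outdir


def load_models(workspace: str | Path) -> tuple[str, list[SuitabilityModel]]:
    """Read models.yaml and its rasters; returns (species, models)."""
    workspace = Path(workspace)
    doc = yaml.safe_load((workspace / "models.yaml").read_text())
    models = []
    for meta in doc["models"]:
        grid = Grid.read_asc(workspace / meta["raster"], crs="local-metre")
        unmasked = None
        if meta.get("unmasked_raster"):
            unmasked = SuitabilityModel(
                model_id=f"{meta['model_id']}-unmasked",
                contractor=meta["contractor"],
                grid=Grid.read_asc(workspace / meta["unmasked_raster"], crs="local-metre"),
                delivered_threshold=meta["delivered_threshold"],
                delivery_kind=DeliveryKind(meta["delivery_kind"]),
                mask_variant=MaskVariant.UNMASKED,
                capture_target=meta["capture_target"],
                native_resolution_m=meta["native_resolution_m"],
            )
        models.append(
            SuitabilityModel(
                model_id=meta["model_id"],
                contractor=meta["contractor"],
                grid=grid,
                delivered_threshold=meta["delivered_threshold"],
                delivery_kind=DeliveryKind(meta["delivery_kind"]),
                mask_variant=MaskVariant(meta["mask_variant"]),
                capture_target=meta["capture_target"],
                native_resolution_m=meta["native_resolution_m"],
                unmasked_variant=unmasked,
            )
        )
    return doc["species"], models


def load_records(workspace: str | Path, species: str | None = None) -> list[OccurrenceRecord]:
    return read_occurrences(Path(workspace) / "occurrences.geojson", species=species)


def load_evidence(workspace: str | Path) -> dict:
    path = Path(workspace) / "evidence.yaml"
    if not path.exists():
        return {}
    doc = yaml.safe_load(path.read_text()) or {}
    if not isinstance(doc, dict):
        raise SchemaError("evidence.yaml must map topic keys to ratings")
    return doc
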