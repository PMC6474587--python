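"""Occurrence-record QC: reading, accuracy/date filtering, internal centroids,
and maximal spatial thinning into evaluation point sets.

Occurrence records are natural-heritage-style element occurrences: polygons
with an ordinal locational-accuracy class (1-10, lower is more precise), a
record year, and an occurrence rank.  The pipeline reduces them to evaluation
points in three steps:

1. ``filter_records`` keeps records inside a date window whose mapped location
   is precise — accuracy classes 1, 2, 4, plus class-3 polygons no larger than
   a 150-m-radius circle (equivalent radius ``sqrt(area / pi)``).
2. ``internal_centroid`` reduces each polygon to a point guaranteed to lie
   inside it.
3. ``thin_maximal`` keeps the largest subset of centroids with all pairwise
   distances >= 430 m, so no two evaluation points can fall in the same pixel
   of any model being tested.

Finding the largest such subset is a maximum-independent-set problem on the
distance-conflict graph and is NP-hard in general; the default solver is a
seeded randomized greedy with restarts (always maximal, reproducible), with an
exact branch-and-bound available for small n.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial.distance import pdist
from shapely.geometry import Point, mapping, shape
from shapely.geometry.base import BaseGeometry
from shapely.ops import transform as shp_transform

from .errors import CRSError, GeometryError, ParameterError, SchemaError
from .projection import LocalSinusoidal, looks_geographic

__all__ = [
    "OccurrenceRecord",
    "EvaluationSet",
    "read_occurrences",
    "filter_records",
    "internal_centroid",
    "thin_maximal",
    "build_evaluation_set",
]

REQUIRED_COLUMNS = ("record_id", "species", "accuracy_class", "year", "occ_rank", "source")
OCC_RANKS = frozenset({"Excellent", "Good", "Fair", "Poor", "X", "Unknown"})

#: accuracy classes whose mapped location is precise regardless of polygon size
PRECISE_CLASSES = frozenset({1, 2, 4})
#: class-3 polygons count as precise only up to this equivalent radius (m)
CLASS3_MAX_RADIUS_M = 150.0
#: minimum separation between evaluation points (m)
MIN_SEPARATION_M = 430.0

#: relative float tolerance for the at-the-limit radius comparison, so a
#: polygon whose area is exactly pi * 150^2 is retained despite rounding
_RADIUS_RTOL = 1e-9


def _radius_within(radius_m: float, limit_m: float) -> bool:
    return radius_m <= limit_m * (1.0 + _RADIUS_RTOL)


@dataclass(frozen=True)
class OccurrenceRecord:
    """One occurrence polygon with its QC attributes (projected metre CRS)."""

    record_id: str
    species: str
    geometry: BaseGeometry
    accuracy_class: int
    year: int
    occurrence_rank: str = "Unknown"
    source: str = ""

    def __post_init__(self) -> None:
        if not 1 <= self.accuracy_class <= 10:
            raise SchemaError(
                f"record {self.record_id}: accuracy_class must be in [1, 10], "
                f"got {self.accuracy_class}"
            )
        if self.year < 1800:
            raise SchemaError(f"record {self.record_id}: year {self.year} < 1800")
        if self.geometry.is_empty or not self.geometry.is_valid:
            raise GeometryError(f"record {self.record_id}: empty or invalid geometry")
        if self.geometry.area < 0:
            raise GeometryError(f"record {self.record_id}: negative area")

    @property
    def equivalent_radius_m(self) -> float:
        """Radius of the circle with the same area as the polygon."""
        return math.sqrt(self.geometry.area / math.pi)

    @property
    def is_precise(self) -> bool:
        return self.accuracy_class in PRECISE_CLASSES or (
            self.accuracy_class == 3
            and _radius_within(self.equivalent_radius_m, CLASS3_MAX_RADIUS_M)
        )


@dataclass(frozen=True)
class EvaluationSet:
    """Thinned internal-centroid points for one species and date window."""

    species: str
    window: tuple[int, int]
    record_ids: tuple[str, ...]
    coords: np.ndarray  # (n, 2) metres
    min_separation_m: float = MIN_SEPARATION_M
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "coords", np.asarray(self.coords, dtype=float).reshape(-1, 2))
        if len(self.record_ids) != len(self.coords):
            raise ParameterError("record_ids and coords lengths differ")

    def __len__(self) -> int:
        return len(self.coords)

    def min_pairwise_distance(self) -> float:
        if len(self) < 2:
            return math.inf
        return float(pdist(self.coords).min())

    def to_geojson(self, path: str | Path) -> None:
        features = [
            {
                "type": "Feature",
                "geometry": mapping(Point(*xy)),
                "properties": {"record_id": rid, "species": self.species},
            }
            for rid, xy in zip(self.record_ids, self.coords)
        ]
        Path(path).write_text(
            json.dumps({"type": "FeatureCollection", "features": features})
        )

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["record_id", "x", "y"])
            for rid, (x, y) in zip(self.record_ids, self.coords):
                writer.writerow([rid, f"{x:.3f}", f"{y:.3f}"])


def read_occurrences(
    path: str | Path,
    species: str | None = None,
    projection: LocalSinusoidal | str | None = None,
) -> list[OccurrenceRecord]:
    """Read occurrence polygons from a GeoJSON file.

    Coordinates must be in a projected metre CRS, or ``projection`` must be
    supplied (``"local-sinusoidal"`` or a :class:`LocalSinusoidal`) to project
    geographic lon/lat coordinates into metres.
    """
    with open(path) as fh:
        doc = json.load(fh)
    features = doc.get("features", [])
    geoms, props = [], []
    for feat in features:
        prop = feat.get("properties") or {}
        for col in REQUIRED_COLUMNS:
            if col not in prop:
                raise SchemaError(f"missing required attribute column: {col!r}")
        geoms.append(shape(feat["geometry"]))
        props.append(prop)

    all_x = [v for g in geoms for v in (g.bounds[0], g.bounds[2])]
    all_y = [v for g in geoms for v in (g.bounds[1], g.bounds[3])]
    if looks_geographic(all_x, all_y):
        if projection is None:
            raise CRSError(
                "coordinates appear to be geographic (degrees); supply a working "
                "projection to obtain metre units"
            )
        if isinstance(projection, str):
            if projection != "local-sinusoidal":
                raise CRSError(f"unknown projection {projection!r}")
            projection = LocalSinusoidal.for_lon(all_x)
        proj = projection
        geoms = [shp_transform(lambda x, y: proj.forward(x, y), g) for g in geoms]

    records = []
    for g, prop in zip(geoms, props):
        if species is not None and prop["species"] != species:
            continue
        records.append(
            OccurrenceRecord(
                record_id=str(prop["record_id"]),
                species=str(prop["species"]),
                geometry=g,
                accuracy_class=int(prop["accuracy_class"]),
                year=int(prop["year"]),
                occurrence_rank=str(prop["occ_rank"]),
                source=str(prop["source"]),
            )
        )
    return records


def filter_records(
    records: Iterable[OccurrenceRecord],
    window: tuple[int, int] = (1981, 2012),
    precise_classes: frozenset[int] | set[int] = PRECISE_CLASSES,
    class3_max_radius_m: float = CLASS3_MAX_RADIUS_M,
) -> list[OccurrenceRecord]:
    """Keep records inside the (inclusive) year window whose location is
    precise: accuracy class in ``precise_classes``, or class 3 with equivalent
    radius <= ``class3_max_radius_m``."""
    lo, hi = window
    out = []
    for rec in records:
        if not lo <= rec.year <= hi:
            continue
        precise = rec.accuracy_class in precise_classes or (
            rec.accuracy_class == 3
            and _radius_within(rec.equivalent_radius_m, class3_max_radius_m)
        )
        if precise:
            out.append(rec)
    return out


def internal_centroid(polygon: BaseGeometry) -> Point:
    """Representative point guaranteed inside the polygon.

    Returns the geometric centroid whenever it lies inside; otherwise a
    deterministic interior point (the widest-chord representative point at the
    polygon's median latitude)."""
    if polygon is None or polygon.is_empty or not polygon.is_valid:
        raise GeometryError("empty or invalid polygon")
    c = polygon.centroid
    if polygon.contains(c):
        return c
    return polygon.representative_point()


# ---------------------------------------------------------------------------
# maximal thinning


def _conflict_lists(coords: np.ndarray, min_dist: float) -> list[np.ndarray]:
    """For each point, indices of points strictly closer than ``min_dist``."""
    n = len(coords)
    d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1)
    thr = min_dist * min_dist
    return [np.flatnonzero((d2[i] < thr) & (np.arange(n) != i)) for i in range(n)]


def _greedy(order: np.ndarray, conflicts: list[np.ndarray]) -> list[int]:
    kept: list[int] = []
    blocked = np.zeros(len(conflicts), dtype=bool)
    for i in order:
        if not blocked[i]:
            kept.append(int(i))
            blocked[conflicts[i]] = True
    return kept


def _exact_mis(conflicts: list[np.ndarray]) -> list[int]:
    """Maximum independent set by branch and bound (small n only)."""
    n = len(conflicts)
    adj = [0] * n
    for i, nb in enumerate(conflicts):
        for j in nb:
            adj[i] |= 1 << int(j)
    best: list[int] = []

    def recurse(candidates: int, chosen: list[int]) -> None:
        nonlocal best
        if len(chosen) + bin(candidates).count("1") <= len(best):
            return
        if candidates == 0:
            if len(chosen) > len(best):
                best = list(chosen)
            return
        # branch on the candidate with most remaining conflicts
        v = max(
            (i for i in range(n) if candidates >> i & 1),
            key=lambda i: bin(adj[i] & candidates).count("1"),
        )
        recurse(candidates & ~(1 << v) & ~adj[v], chosen + [v])  # take v
        recurse(candidates & ~(1 << v), chosen)  # skip v
    recurse((1 << n) - 1, [])
    return sorted(best)


def thin_maximal(
    points: Sequence[tuple[str, float, float]],
    min_dist_m: float = MIN_SEPARATION_M,
    seed: int = 0,
    exact: bool = False,
    restarts: int = 100,
) -> tuple[tuple[str, ...], np.ndarray]:
    """Largest-found subset of points with pairwise distances >= ``min_dist_m``.

    ``points`` is a sequence of ``(record_id, x, y)`` in metres.  The heuristic
    mode runs a deterministic greedy pass (candidates in record_id order) plus
    ``restarts - 1`` seeded random-order greedy passes and returns the best;
    every greedy result is maximal.  ``exact=True`` (n <= 15 only) returns a
    true maximum-cardinality subset via branch and bound.

    Returns ``(record_ids, coords)`` of the retained subset, in record_id order.
    """
    if min_dist_m <= 0:
        raise ParameterError(f"min_dist_m must be positive, got {min_dist_m}")
    pts = sorted(points, key=lambda p: p[0])  # record_id order for determinism
    ids = [p[0] for p in pts]
    coords = np.array([[p[1], p[2]] for p in pts], dtype=float).reshape(-1, 2)
    n = len(ids)
    if n == 0:
        return (), coords
    conflicts = _conflict_lists(coords, min_dist_m)

    if exact:
        if n > 15:
            raise ParameterError(f"exact mode is limited to n <= 15 (got {n})")
        kept = _exact_mis(conflicts)
    else:
        kept = _greedy(np.arange(n), conflicts)
        rng = np.random.default_rng(seed)
        for _ in range(max(0, restarts - 1)):
            cand = _greedy(rng.permutation(n), conflicts)
            if len(cand) > len(kept):
                kept = cand
    kept = sorted(kept)
    return tuple(ids[i] for i in kept), coords[kept]


def build_evaluation_set(
    records: Iterable[OccurrenceRecord],
    species: str,
    window: tuple[int, int] = (1981, 2012),
    min_separation_m: float = MIN_SEPARATION_M,
    seed: int = 0,
    exact: bool = False,
    max_points: int | None = None,
) -> EvaluationSet:
    """Filter -> internal centroid -> maximal thinning, in one call.

    ``max_points`` optionally subsamples the thinned set (seeded) to a fixed
    evaluation size; any subset of a separated set remains separated.
    """
    kept = filter_records(records, window=window)
    pts = []
    for rec in kept:
        c = internal_centroid(rec.geometry)
        pts.append((rec.record_id, c.x, c.y))
    ids, coords = thin_maximal(pts, min_dist_m=min_separation_m, seed=seed, exact=exact)
    if max_points is not None and len(ids) > max_points:
        rng = np.random.default_rng(seed)
        sel = np.sort(rng.choice(len(ids), size=max_points, replace=False))
        ids = tuple(ids[i] for i in sel)
        coords = coords[sel]
    return EvaluationSet(
        species=species,
        window=window,
        record_ids=ids,
        coords=coords,
        min_separation_m=min_separation_m,
        seed=seed,
    )
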