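"""Coordinate-vs-country validation with neighbour and coastline tolerance.

Two checks are applied to every georeferenced record:

1. **Country check.** If the point falls inside the documented country the
   record is a ``Match``. If it falls inside a country that shares a border
   with the documented one it is a ``Neighbour``: the nearest great-circle
   distance to the documented country's border is computed and the record
   is kept only when that distance does not exceed the tolerance (default
   5 km) — border maps and coordinates are both imprecise at that scale.
   If it falls inside a non-adjacent country it is an ``Error`` and is
   discarded.

2. **Coastline check.** If the point falls in no country polygon (ocean),
   the nearest distance to the documented country's coastline is computed
   and the record is kept only within the same tolerance. An offshore
   point with no documented country cannot be rescued and is discarded.

Distances are great-circle on a sphere of radius 6371.0088 km (the WGS84
mean radius); at a 5 km tolerance the difference from ellipsoidal distance
is immaterial. Boundaries are densified to a maximum segment length of
~1 km and the point-to-boundary distance is the minimum great-circle
(cross-track) distance to the segment arcs.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Point, shape
from shapely.geometry.base import BaseGeometry
from shapely.validation import make_valid

from occurclean.datamodel import Action, AuditLog, OccurrenceRecord, Stage

__all__ = [
    "EARTH_RADIUS_KM",
    "Classification",
    "Verdict",
    "GeoValidationResult",
    "CountryPolygonSet",
    "haversine_km",
    "nearest_border_distance_km",
    "validate_country",
    "validate_coastline",
    "validate_records",
    "density_grid",
]

#: WGS84 mean Earth radius, km.
EARTH_RADIUS_KM = 6371.0088

#: Densification target for boundary polylines, km.
_DENSIFY_KM = 1.0


class Classification(str, enum.Enum):
    Match = "Match"
    Neighbour = "Neighbour"
    Sea = "Sea"
    Error = "Error"
    NoCoordinates = "NoCoordinates"
    NoCountry = "NoCountry"


class Verdict(str, enum.Enum):
    keep = "keep"
    discard = "discard"


@dataclass(frozen=True)
class GeoValidationResult:
    record_id: str
    classification: Classification
    distance_km: float | None
    verdict: Verdict

    @property
    def keep(self) -> bool:
        return self.verdict is Verdict.keep


def haversine_km(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Great-circle distance in km between two WGS84 points."""
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dphi = p2 - p1
    dlam = math.radians(lon2 - lon1)
    a = math.sin(dphi / 2.0) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dlam / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(a)))


def _haversine_km_vec(lat: float, lon: float, lats: np.ndarray, lons: np.ndarray) -> np.ndarray:
    p1 = math.radians(lat)
    p2 = np.radians(lats)
    dphi = p2 - p1
    dlam = np.radians(lons - lon)
    a = np.sin(dphi / 2.0) ** 2 + math.cos(p1) * np.cos(p2) * np.sin(dlam / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.minimum(1.0, np.sqrt(a)))


def _boundary_segments(geom: BaseGeometry, densify_km: float = _DENSIFY_KM) -> tuple[np.ndarray, np.ndarray]:
    """Endpoint arrays (each (n, 2) lon/lat) of the densified boundary segments.

    Multi-part boundaries contribute their parts separately, so no phantom
    segment bridges disjoint rings.
    """
    boundary = geom.boundary if geom.geom_type in ("Polygon", "MultiPolygon") else geom
    if boundary.is_empty:
        raise ValueError("degenerate geometry: empty boundary")
    # ~1 km in degrees of latitude; longitude spacing is finer off the
    # equator, which only helps the approximation.
    max_seg_deg = densify_km / 111.19492664455873
    dense = boundary.segmentize(max_seg_deg)
    starts, ends = [], []
    for part in getattr(dense, "geoms", [dense]):
        coords = np.asarray(part.coords)
        if len(coords) >= 2:
            starts.append(coords[:-1])
            ends.append(coords[1:])
        else:
            starts.append(coords)
            ends.append(coords)
    return np.vstack(starts), np.vstack(ends)


def _point_to_segments_km(lat: float, lon: float, seg_a: np.ndarray, seg_b: np.ndarray) -> float:
    """Min great-circle distance from a point to great-circle arc segments.

    Uses the spherical cross-track distance when the point projects onto an
    arc, and the nearer endpoint distance otherwise.
    """
    d_a = _haversine_km_vec(lat, lon, seg_a[:, 1], seg_a[:, 0])  # A -> P
    d_b = _haversine_km_vec(lat, lon, seg_b[:, 1], seg_b[:, 0])  # B -> P
    best = float(min(d_a.min(), d_b.min()))
    if best == 0.0:
        return 0.0

    phi1 = np.radians(seg_a[:, 1])
    lam1 = np.radians(seg_a[:, 0])
    phi2 = np.radians(seg_b[:, 1])
    lam2 = np.radians(seg_b[:, 0])
    phi3, lam3 = math.radians(lat), math.radians(lon)

    def bearing(p1, l1, p2, l2):
        dl = l2 - l1
        return np.arctan2(
            np.sin(dl) * np.cos(p2), np.cos(p1) * np.sin(p2) - np.sin(p1) * np.cos(p2) * np.cos(dl)
        )

    theta12 = bearing(phi1, lam1, phi2, lam2)
    theta13 = bearing(phi1, lam1, np.full_like(phi1, phi3), np.full_like(lam1, lam3))
    delta13 = d_a / EARTH_RADIUS_KM
    delta12 = (
        2.0
        * np.arcsin(
            np.sqrt(
                np.sin((phi2 - phi1) / 2) ** 2
                + np.cos(phi1) * np.cos(phi2) * np.sin((lam2 - lam1) / 2) ** 2
            )
        )
    )
    dxt = np.arcsin(np.clip(np.sin(delta13) * np.sin(theta13 - theta12), -1.0, 1.0))
    with np.errstate(invalid="ignore", divide="ignore"):
        dat = np.arccos(np.clip(np.cos(delta13) / np.maximum(np.cos(dxt), 1e-300), -1.0, 1.0))
    # projection falls inside the arc?
    inside = (np.cos(theta13 - theta12) >= 0.0) & (dat <= delta12)
    if inside.any():
        best = min(best, float(np.abs(dxt[inside]).min() * EARTH_RADIUS_KM))
    return best


class CountryPolygonSet:
    """Country multipolygons (WGS84 lon/lat) with precomputed adjacency.

    Two countries are adjacent when their boundaries share a line segment
    (1-dimensional intersection); corner-touching does not count.
    """

    def __init__(self, polygons: Mapping[str, BaseGeometry]) -> None:
        self.polygons: dict[str, BaseGeometry] = {}
        for code, geom in polygons.items():
            if not geom.is_valid:
                geom = make_valid(geom)
            self.polygons[code.upper()] = geom
        self.adjacency: dict[str, set[str]] = {c: set() for c in self.polygons}
        codes = sorted(self.polygons)
        for i, a in enumerate(codes):
            for b in codes[i + 1 :]:
                shared = self.polygons[a].boundary.intersection(self.polygons[b].boundary)
                if shared.length > 0:
                    self.adjacency[a].add(b)
                    self.adjacency[b].add(a)
        self._boundary_cache: dict[str, tuple[np.ndarray, np.ndarray]] = {}

    @classmethod
    def from_geojson(cls, path: str | Path, code_property: str = "iso_a3") -> "CountryPolygonSet":
        """Load a polygon set from a GeoJSON FeatureCollection (RFC 7946).

        Each feature must carry its country code in ``properties[code_property]``.
        """
        with open(path, encoding="utf-8") as fh:
            gj = json.load(fh)
        polygons: dict[str, BaseGeometry] = {}
        for feat in gj["features"]:
            code = feat["properties"][code_property]
            polygons[code] = shape(feat["geometry"])
        return cls(polygons)

    def to_geojson(self, path: str | Path, code_property: str = "iso_a3") -> None:
        from shapely.geometry import mapping

        features = [
            {"type": "Feature", "properties": {code_property: code}, "geometry": mapping(geom)}
            for code, geom in sorted(self.polygons.items())
        ]
        with open(path, "w", encoding="utf-8") as fh:
            json.dump({"type": "FeatureCollection", "features": features}, fh)

    def __contains__(self, code: str) -> bool:
        return code.upper() in self.polygons

    def containing_country(self, lat: float, lon: float) -> str | None:
        """Code of the country whose polygon covers the point, or None (ocean).

        A point exactly on a border is assigned to the documented country by
        the callers' covers-first check, so the iteration order here only
        matters for points on borders between two *other* countries.
        """
        pt = Point(lon, lat)
        for code in sorted(self.polygons):
            if self.polygons[code].covers(pt):
                return code
        return None

    def boundary_segments(self, code: str) -> tuple[np.ndarray, np.ndarray]:
        code = code.upper()
        if code not in self._boundary_cache:
            self._boundary_cache[code] = _boundary_segments(self.polygons[code])
        return self._boundary_cache[code]


def nearest_border_distance_km(
    point: tuple[float, float],
    country_boundary: BaseGeometry | tuple[np.ndarray, np.ndarray] | np.ndarray,
) -> float:
    """Minimum great-circle distance (km) from ``(lat, lon)`` to a boundary.

    The boundary polyline is densified to ~1 km segments; each segment is
    treated as a great-circle arc and the point-to-arc (cross-track)
    distance is minimized over segments. The result is >= 0, and 0 iff the
    point lies on the boundary.
    """
    lat, lon = point
    if isinstance(country_boundary, tuple):
        seg_a, seg_b = country_boundary
    elif isinstance(country_boundary, np.ndarray):
        if country_boundary.size == 0:
            raise ValueError("degenerate boundary: no vertices")
        seg_a, seg_b = country_boundary[:-1], country_boundary[1:]
        if len(seg_a) == 0:
            seg_a = seg_b = country_boundary
    else:
        seg_a, seg_b = _boundary_segments(country_boundary)
    return _point_to_segments_km(lat, lon, seg_a, seg_b)


def _result(rid, cls_, dist, keep):
    return GeoValidationResult(rid, cls_, dist, Verdict.keep if keep else Verdict.discard)


def validate_country(
    record: OccurrenceRecord,
    polygons: CountryPolygonSet,
    tolerance_km: float = 5.0,
    keep_no_country: bool = True,
) -> GeoValidationResult:
    """Classify a record against its documented country (Match / Neighbour / Error).

    A point on the documented country's border counts as inside (Match) —
    the tie-break favours retention. Neighbour records are kept iff their
    distance to the documented border is <= ``tolerance_km``.
    """
    rid = record.record_id
    if not record.has_coordinates:
        return _result(rid, Classification.NoCoordinates, None, False)
    if not record.country_code or record.country_code not in polygons:
        return _result(rid, Classification.NoCountry, None, keep_no_country)
    documented = record.country_code.upper()
    lat, lon = record.latitude, record.longitude
    if polygons.polygons[documented].covers(Point(lon, lat)):
        return _result(rid, Classification.Match, None, True)
    containing = polygons.containing_country(lat, lon)
    if containing is None:
        return validate_coastline(record, polygons, tolerance_km)
    if containing in polygons.adjacency[documented]:
        dist = nearest_border_distance_km((lat, lon), polygons.boundary_segments(documented))
        return _result(rid, Classification.Neighbour, dist, dist <= tolerance_km)
    return _result(rid, Classification.Error, None, False)


def validate_coastline(
    record: OccurrenceRecord,
    polygons: CountryPolygonSet,
    tolerance_km: float = 5.0,
) -> GeoValidationResult:
    """Classify an offshore record (Sea): keep iff within tolerance of the
    documented country's coastline; discard if no country is documented."""
    rid = record.record_id
    if not record.has_coordinates:
        return _result(rid, Classification.NoCoordinates, None, False)
    if not record.country_code or record.country_code not in polygons:
        return _result(rid, Classification.Sea, None, False)
    dist = nearest_border_distance_km(
        (record.latitude, record.longitude),
        polygons.boundary_segments(record.country_code),
    )
    return _result(rid, Classification.Sea, dist, dist <= tolerance_km)


def validate_records(
    records: Iterable[OccurrenceRecord],
    polygons: CountryPolygonSet,
    tolerance_km: float = 5.0,
    keep_no_country: bool = True,
    audit: AuditLog | None = None,
) -> dict[str, GeoValidationResult]:
    """Run the full georeferencing check on a collection of records.

    Every record receives exactly one classification; keep/discard verdicts
    partition the input. Discards are logged to ``audit`` when given.
    """
    results: dict[str, GeoValidationResult] = {}
    for rec in records:
        res = validate_country(rec, polygons, tolerance_km, keep_no_country)
        results[rec.record_id] = res
        if audit is not None:
            audit.add(
                rec.record_id,
                Stage.geo,
                Action.kept if res.keep else Action.discarded,
                res.classification.value,
            )
    return results


def density_grid(
    records: Iterable[OccurrenceRecord], cell_degrees: float = 2.0
) -> pd.DataFrame:
    """Count records per ``cell_degrees`` x ``cell_degrees`` cell.

    Cells are half-open ``[lower, upper)`` in both axes; a record exactly on
    a cell edge belongs to the cell whose lower edge it sits on. Records
    without coordinates are ignored; the returned counts sum to the number
    of records with coordinates.

    Returns a DataFrame with columns ``lon_min``, ``lat_min``, ``count``.
    """
    if cell_degrees <= 0:
        raise ValueError("cell_degrees must be positive")
    counts: dict[tuple[float, float], int] = {}
    for rec in records:
        if not rec.has_coordinates:
            continue
        key = (
            math.floor(rec.longitude / cell_degrees) * cell_degrees,
            math.floor(rec.latitude / cell_degrees) * cell_degrees,
        )
        counts[key] = counts.get(key, 0) + 1
    rows = [(lon, lat, n) for (lon, lat), n in sorted(counts.items())]
    return pd.DataFrame(rows, columns=["lon_min", "lat_min", "count"])
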