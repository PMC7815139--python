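"""Region geometry: GeoJSON reading, parent dissolve, representative points,
great-circle distances.

Polygons stay in geographic lon/lat degrees throughout; all metric distances
are great-circle kilometres on a sphere of radius 6371.0088 km (no planar
projection is ever applied, so there is a single distance convention).
"""
from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from shapely.geometry import MultiPolygon, Polygon, mapping, shape
from shapely.ops import unary_union

from .exceptions import GeometryError, ParameterError, SchemaError

EARTH_RADIUS_KM = 6371.0088


@dataclass
class Region:
    """One areal unit: identifier, optional parent identifier, polygon."""

    region_id: str
    parent_id: Optional[str]
    geometry: Polygon | MultiPolygon


@dataclass
class RegionSet:
    """An ordered collection of regions forming one layer of a two-level
    (child area -> parent area) hierarchy."""

    regions: list[Region] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self):
        return iter(self.regions)

    def ids(self) -> list[str]:
        return [r.region_id for r in self.regions]

    def get(self, region_id: str) -> Region:
        for r in self.regions:
            if r.region_id == region_id:
                return r
        raise KeyError(region_id)

    def total_area(self) -> float:
        """Sum of planar polygon areas in squared degrees (used only for
        conservation checks, never as a physical area)."""
        return float(sum(r.geometry.area for r in self.regions))

    def representative_points(self) -> dict[str, tuple[float, float]]:
        return {r.region_id: representative_point(r.geometry) for r in self.regions}


def read_regions(path: str, id_field: str, parent_field: str = "") -> RegionSet:
    """Read a polygon layer from a GeoJSON FeatureCollection.

    Parameters
    ----------
    path : str
        Path to a GeoJSON file (RFC 7946). ESRI Shapefiles are not supported.
    id_field : str
        Property carrying the region identifier.
    parent_field : str
        Property carrying the parent identifier; empty string means the layer
        has no parent level.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if path.lower().endswith((".shp", ".dbf", ".shx")):
        raise SchemaError(
            "ESRI Shapefile input is not supported; convert the layer to GeoJSON"
        )
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    if doc.get("type") != "FeatureCollection":
        raise SchemaError(f"{path}: not a GeoJSON FeatureCollection")
    regions: list[Region] = []
    for feat in doc.get("features", []):
        props = feat.get("properties") or {}
        if id_field not in props:
            raise SchemaError(f"{path}: feature is missing id field '{id_field}'")
        if parent_field and parent_field not in props:
            raise SchemaError(f"{path}: feature is missing parent field '{parent_field}'")
        geom = shape(feat["geometry"])
        if geom.geom_type not in ("Polygon", "MultiPolygon"):
            raise GeometryError(
                f"{path}: feature '{props[id_field]}' has non-polygon geometry "
                f"({geom.geom_type})"
            )
        parent = str(props[parent_field]) if parent_field else None
        regions.append(Region(str(props[id_field]), parent, geom))
    return RegionSet(regions)


def write_regions(rs: RegionSet, path: str, id_field: str = "id",
                  parent_field: str = "parent") -> None:
    """Write a RegionSet as a GeoJSON FeatureCollection."""
    features = []
    for r in rs:
        props = {id_field: r.region_id}
        if r.parent_id is not None:
            props[parent_field] = r.parent_id
        features.append(
            {"type": "Feature", "properties": props, "geometry": mapping(r.geometry)}
        )
    with open(path, "w", encoding="utf-8") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def dissolve_to_parent(rs: RegionSet) -> RegionSet:
    """Union child polygons sharing a parent identifier into one region per
    parent. Total area is conserved (children are assumed non-overlapping)."""
    for r in rs:
        if not r.parent_id:
            raise ParameterError(
                f"region '{r.region_id}' has no parent_id; cannot dissolve"
            )
    order: list[str] = []
    groups: dict[str, list] = {}
    for r in rs:
        if r.parent_id not in groups:
            groups[r.parent_id] = []
            order.append(r.parent_id)
        groups[r.parent_id].append(r.geometry)
    out = [
        Region(pid, None, unary_union(groups[pid]))
        for pid in order
    ]
    return RegionSet(out)


def representative_point(geom: Polygon | MultiPolygon) -> tuple[float, float]:
    """A point representing a polygon: its area centroid when that falls
    inside, otherwise a guaranteed-interior point (point on surface).

    Multi-part polygons are represented by their largest part.
    """
    if geom.is_empty or geom.area == 0:
        raise GeometryError("degenerate (zero-area) polygon")
    if isinstance(geom, MultiPolygon):
        geom = max(geom.geoms, key=lambda g: g.area)
    c = geom.centroid
    if geom.covers(c):
        return (c.x, c.y)
    p = geom.representative_point()
    return (p.x, p.y)


def _check_lonlat(lon: np.ndarray, lat: np.ndarray) -> None:
    if np.any(np.abs(lon) > 180) or np.any(np.abs(lat) > 90):
        raise ParameterError("lon/lat out of range [-180,180] x [-90,90]")


def cross_distance_km(
    lon1: Sequence[float], lat1: Sequence[float],
    lon2: Sequence[float], lat2: Sequence[float],
) -> np.ndarray:
    """Haversine great-circle distance matrix (km) between two point sets."""
    lon1 = np.asarray(lon1, float)
    lat1 = np.asarray(lat1, float)
    lon2 = np.asarray(lon2, float)
    lat2 = np.asarray(lat2, float)
    _check_lonlat(lon1, lat1)
    _check_lonlat(lon2, lat2)
    p1, l1 = np.radians(lat1)[:, None], np.radians(lon1)[:, None]
    p2, l2 = np.radians(lat2)[None, :], np.radians(lon2)[None, :]
    a = (
        np.sin((p2 - p1) / 2) ** 2
        + np.cos(p1) * np.cos(p2) * np.sin((l2 - l1) / 2) ** 2
    )
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def pairwise_distance_km(coords: Sequence[tuple[float, float]]) -> np.ndarray:
    """Symmetric haversine distance matrix (km) for (lon, lat) pairs."""
    if len(coords) < 1:
        raise ParameterError("need at least one coordinate")
    lon = np.array([c[0] for c in coords], float)
    lat = np.array([c[1] for c in coords], float)
    d = cross_distance_km(lon, lat, lon, lat)
    np.fill_diagonal(d, 0.0)
    return (d + d.T) / 2.0


def representative_points_table(rs: RegionSet):
    """Rows of (region_id, parent_id, lon, lat) ready for CSV export."""
    import pandas as pd

    rows = []
    for r in rs:
        lon, lat = representative_point(r.geometry)
        rows.append({"region_id": r.region_id, "parent_id": r.parent_id or "",
                     "lon": lon, "lat": lat})
    return pd.DataFrame(rows)
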