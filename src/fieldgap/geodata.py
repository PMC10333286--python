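"""Field geometry: polygons from GPS points, zonal raster summaries, GeoJSON I/O.

Field boundaries are captured in the field as five GPS points — the field
center and the four corners. :func:`build_polygon` turns the four corners
into a simple quadrilateral; :func:`extract_mean` computes the mean of a
raster over the pixels whose centers fall inside a polygon (the zonal
statistic used both for per-field GCVI features and for per-field
satellite yields).
"""

from __future__ import annotations

import json
import warnings

import numpy as np
import shapely
from shapely.geometry import Point, Polygon, mapping, shape

from .georef import GridGeoref

__all__ = [
    "DegenerateGeometryError",
    "build_polygon",
    "extract_mean",
    "extract_means",
    "write_geojson",
    "read_geojson",
]


class DegenerateGeometryError(ValueError):
    """Raised when GPS corner points cannot form a simple quadrilateral."""


def build_polygon(center, corners) -> Polygon:
    """Order four corner points into a simple quadrilateral ring.

    Corners are sorted by angle about their centroid, which yields the
    unique simple (non-self-intersecting) quadrilateral through four points
    in convex position, regardless of the order they were recorded in.
    The center point is not used in construction; it validates the result
    (it must fall inside the ring).

    Raises :class:`DegenerateGeometryError` for duplicate corners, three
    collinear corners, or a center outside the resulting ring.
    """
    pts = np.asarray([(p.x, p.y) if isinstance(p, Point) else tuple(p) for p in corners], dtype=float)
    if pts.shape != (4, 2):
        raise DegenerateGeometryError(f"need exactly 4 corner points, got {pts.shape[0]}")
    if len({tuple(p) for p in pts.tolist()}) < 4:
        raise DegenerateGeometryError("duplicate corner points")
    centroid = pts.mean(axis=0)
    ang = np.arctan2(pts[:, 1] - centroid[1], pts[:, 0] - centroid[0])
    ring = pts[np.argsort(ang, kind="stable")]
    poly = Polygon(ring)
    if not poly.is_valid or poly.area <= 0:
        raise DegenerateGeometryError("corners are collinear or otherwise degenerate")
    # cross products of consecutive edges detect three-collinear corners
    edges = np.diff(np.vstack([ring, ring[:2]]), axis=0)
    cross = edges[:-1, 0] * edges[1:, 1] - edges[:-1, 1] * edges[1:, 0]
    if np.any(np.isclose(cross, 0.0)):
        raise DegenerateGeometryError("three corner points are collinear")
    if center is not None:
        c = center if isinstance(center, Point) else Point(center)
        if not poly.covers(c):
            raise DegenerateGeometryError("center point falls outside the corner ring")
    return poly


def extract_mean(raster: np.ndarray, georef: GridGeoref, polygon: Polygon) -> float:
    """Mean raster value over pixels whose centers fall inside the polygon.

    NaN pixels are excluded. Returns NaN (with a warning, not an
    exception) when no finite pixel center lies inside — e.g. a polygon
    outside the raster extent.
    """
    raster = np.asarray(raster, dtype=float)
    rows, cols = raster.shape
    px = georef.pixel_size
    # clip the candidate window to the polygon's bounding box
    minx, miny, maxx, maxy = polygon.bounds
    c0 = max(0, int(np.floor((minx - georef.origin_x) / px - 0.5)))
    c1 = min(cols, int(np.ceil((maxx - georef.origin_x) / px + 0.5)) + 1)
    r0 = max(0, int(np.floor((georef.origin_y - maxy) / px - 0.5)))
    r1 = min(rows, int(np.ceil((georef.origin_y - miny) / px + 0.5)) + 1)
    if c1 <= c0 or r1 <= r0:
        warnings.warn("polygon does not overlap the raster extent")
        return float("nan")
    rr, cc = np.mgrid[r0:r1, c0:c1]
    xs, ys = georef.pixel_center(rr, cc)
    inside = shapely.contains_xy(polygon, xs.ravel(), ys.ravel()).reshape(xs.shape)
    vals = raster[r0:r1, c0:c1][inside]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        warnings.warn("no finite pixel center inside polygon; returning NaN")
        return float("nan")
    return float(vals.mean())


def extract_means(raster, georef, polygons) -> np.ndarray:
    """Vector of :func:`extract_mean` over many polygons."""
    return np.array([extract_mean(raster, georef, p) for p in polygons])


def write_geojson(path, polygons, properties=None, crs_id: str = "local-metric") -> None:
    """Write polygons (+ per-feature property dicts) as a GeoJSON FeatureCollection."""
    properties = properties or [{} for _ in polygons]
    features = [
        {"type": "Feature", "geometry": mapping(poly), "properties": props}
        for poly, props in zip(polygons, properties)
    ]
    doc = {"type": "FeatureCollection", "crs_id": crs_id, "features": features}
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)


def read_geojson(path):
    """Read a FeatureCollection back into (polygons, properties) lists."""
    with open(path) as fh:
        doc = json.load(fh)
    polys = [shape(f["geometry"]) for f in doc["features"]]
    props = [f.get("properties", {}) for f in doc["features"]]
    return polys, props
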