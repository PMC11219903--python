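"""Per-segment learning database: zonal statistics and polygon shape indices.

Zonal mean/sd use the population (divide-by-n) convention. Pixel membership
for polygon zones is cell-center containment, with boundary centers assigned
to the polygon (shapely ``covers``). Shape indices follow the 9-column list:
A, P, P/A, P/sqrt(A), Sphericity, ShapeIndex, Dmax, Dmax/A, Dmax/sqrt(A),
with Sphericity = 2·sqrt(πA)/P and ShapeIndex its exact reciprocal.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import MultiPolygon, Polygon
from shapely.geometry.base import BaseGeometry

from .rasters import GridSpec, RasterStack
from .segment import SegmentMap

logger = logging.getLogger(__name__)

__all__ = [
    "zonal_stats_labels",
    "zonal_stats_polygons",
    "shape_indices",
    "SHAPE_INDEX_COLUMNS",
    "build_feature_table",
]

SHAPE_INDEX_COLUMNS = [
    "A", "P", "P_A", "P_sqrtA", "Sphericity", "ShapeIndex",
    "Dmax", "Dmax_A", "Dmax_sqrtA",
]


def zonal_stats_labels(labels: np.ndarray, stack: RasterStack) -> pd.DataFrame:
    """Population mean/sd of every band per label-grid zone (label 0 skipped)."""
    labels = np.asarray(labels)
    if labels.shape != stack.grid.shape:
        raise ValueError("label grid and stack are not co-registered")
    valid = (labels > 0) & ~stack.nodata_mask
    zone = labels[valid]
    ids, inv = np.unique(zone, return_inverse=True)
    counts = np.bincount(inv)
    data: dict[str, np.ndarray] = {}
    for name in stack.band_names:
        vals = stack[name][valid]
        s1 = np.bincount(inv, weights=vals)
        s2 = np.bincount(inv, weights=vals * vals)
        mean = s1 / counts
        var = np.maximum(s2 / counts - mean**2, 0.0)
        data[f"{name}_mean"] = mean
        data[f"{name}_sd"] = np.sqrt(var)
    out = pd.DataFrame(data)
    out.insert(0, "segment_id", ids)
    return out


def zonal_stats_polygons(
    polygons: dict[int, BaseGeometry] | list[BaseGeometry],
    stack: RasterStack,
) -> pd.DataFrame:
    """Population mean/sd per polygon using cell-center membership."""
    if isinstance(polygons, dict):
        items = list(polygons.items())
    else:
        items = list(enumerate(polygons, start=1))
    xs, ys = stack.grid.cell_centers()
    pts = shapely.points(xs.ravel(), ys.ravel())
    ok_mask = (~stack.nodata_mask).ravel()
    rows = []
    for pid, geom in items:
        inside = shapely.covers(geom, pts) & ok_mask
        if not inside.any():
            logger.warning("zone %s covers no pixels; dropped", pid)
            continue
        rec: dict[str, float] = {"polygon_id": pid}
        for name in stack.band_names:
            vals = stack[name].ravel()[inside]
            rec[f"{name}_mean"] = float(vals.mean())
            rec[f"{name}_sd"] = float(vals.std())  # population sd
        rows.append(rec)
    return pd.DataFrame(rows)


def _all_vertices(geom: BaseGeometry) -> np.ndarray:
    parts = [geom] if isinstance(geom, Polygon) else list(geom.geoms)
    coords = []
    for p in parts:
        coords.append(np.asarray(p.exterior.coords))
        for ring in p.interiors:
            coords.append(np.asarray(ring.coords))
    return np.vstack(coords)


def max_diameter(geom: BaseGeometry) -> float:
    """Max pairwise vertex distance (computed on the convex hull vertices)."""
    hull = geom.convex_hull
    if hull.geom_type == "Point":
        return 0.0
    if hull.geom_type == "LineString":
        pts = np.asarray(hull.coords)
    else:
        pts = np.asarray(hull.exterior.coords)[:-1]
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(axis=-1)
    return float(np.sqrt(d2.max()))


def shape_indices(geom: BaseGeometry) -> dict[str, float]:
    """A, P (outer+inner boundary), compactness ratios, and Dmax ratios."""
    if not isinstance(geom, (Polygon, MultiPolygon)):
        raise ValueError("shape indices require a polygonal geometry")
    a = geom.area
    if a <= 0:
        raise ValueError("zero-area polygon")
    p = geom.length  # shapely includes interior-ring length
    dmax = max_diameter(geom)
    sqrt_a = math.sqrt(a)
    sphericity = 2.0 * math.sqrt(math.pi * a) / p
    return {
        "A": a,
        "P": p,
        "P_A": p / a,
        "P_sqrtA": p / sqrt_a,
        "Sphericity": sphericity,
        "ShapeIndex": 1.0 / sphericity,
        "Dmax": dmax,
        "Dmax_A": dmax / a,
        "Dmax_sqrtA": dmax / sqrt_a,
    }


def build_feature_table(
    segmap: SegmentMap,
    stack: RasterStack,
    plot_lookup=None,
) -> pd.DataFrame:
    """One row per segment: zonal mean/sd for every band + shape indices.

    ``plot_lookup`` optionally maps a segment's representative point to
    (plot_id, replicate); it receives a shapely point and returns a dict of
    key columns to attach.
    """
    table = zonal_stats_labels(segmap.labels, stack)
    shape_rows = []
    for sid in table["segment_id"]:
        geom = segmap.polygons.get(int(sid))
        if geom is None:
            raise KeyError(f"segment {sid} has no polygon; run vectorize first")
        shape_rows.append(shape_indices(geom))
    shapes = pd.DataFrame(shape_rows)
    out = pd.concat([table.reset_index(drop=True), shapes.reset_index(drop=True)], axis=1)
    if plot_lookup is not None:
        keys = []
        for sid in out["segment_id"]:
            geom = segmap.polygons[int(sid)]
            keys.append(plot_lookup(geom.representative_point()))
        out = pd.concat([out, pd.DataFrame(keys).reset_index(drop=True)], axis=1)
    return out
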