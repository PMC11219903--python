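"""Per-sensor analysis stack construction.

Terrain interpolation (TIN), canopy height models, the HIS (HSL-convention)
color transform, vegetation-index computation for the RGB and multispectral
band sets, and nearest-neighbor raster alignment/stacking.

VI formulas live in one registry (``RGB_VI_FORMULAS`` / ``MS_VI_FORMULAS``)
so alternates can be swapped without touching callers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import LinearNDInterpolator
from scipy.spatial import Delaunay, QhullError
from shapely.geometry import MultiPoint, Point

from .rasters import GridSpec, RasterStack

logger = logging.getLogger(__name__)

__all__ = [
    "GroundPointSet",
    "compute_dtm_tin",
    "compute_chm",
    "rgb_to_his",
    "his_to_rgb",
    "compute_vis_rgb",
    "compute_vis_ms",
    "align_rasters",
    "build_analysis_stack",
]


@dataclass(frozen=True)
class GroundPointSet:
    """(x, y, z) ground elevations in map units / meters."""

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "x", np.asarray(self.x, dtype=float))
        object.__setattr__(self, "y", np.asarray(self.y, dtype=float))
        object.__setattr__(self, "z", np.asarray(self.z, dtype=float))
        if not (len(self.x) == len(self.y) == len(self.z)):
            raise ValueError("x, y, z must have equal length")
        if len(self.x) < 3:
            raise ValueError("need at least 3 ground points")


def compute_dtm_tin(
    points: GroundPointSet, target_grid: GridSpec
) -> tuple[np.ndarray, np.ndarray]:
    """TIN (Delaunay + barycentric-linear) terrain interpolation.

    Returns ``(dtm, extrapolated_mask)``. Cells inside the convex hull get
    exact linear interpolation on the containing triangle; cells outside are
    filled by evaluating the interpolant at the nearest point of the hull
    boundary (nudged inward) and flagged True in the mask.
    """
    xy = np.column_stack([points.x, points.y])
    try:
        tri = Delaunay(xy)
    except QhullError as exc:
        raise ValueError("degenerate triangulation (collinear points?)") from exc
    if tri.simplices.size == 0:
        raise ValueError("degenerate triangulation (collinear points?)")
    interp = LinearNDInterpolator(tri, points.z)
    xs, ys = target_grid.cell_centers()
    dtm = interp(xs, ys)
    outside = ~np.isfinite(dtm)
    if outside.any():
        import shapely

        hull = MultiPoint([Point(p) for p in xy]).convex_hull
        boundary = hull.boundary
        centroid = hull.centroid
        pts = shapely.points(xs[outside], ys[outside])
        along = shapely.line_locate_point(boundary, pts)
        q = shapely.line_interpolate_point(boundary, along)
        # nudge toward the hull centroid so the interpolant is defined
        qx = shapely.get_x(q)
        qy = shapely.get_y(q)
        qx = qx + 1e-9 * (centroid.x - qx)
        qy = qy + 1e-9 * (centroid.y - qy)
        filled = interp(qx, qy)
        bad = ~np.isfinite(filled)
        if bad.any():  # numerical residue on the hull edge: nudge further in
            qx2 = qx[bad] + 1e-6 * (centroid.x - qx[bad])
            qy2 = qy[bad] + 1e-6 * (centroid.y - qy[bad])
            filled[bad] = interp(qx2, qy2)
        dtm[outside] = filled
    return dtm, outside


def compute_chm(dsm: np.ndarray, dtm: np.ndarray, clamp_negative: bool = True) -> np.ndarray:
    """Canopy height model: ``dsm − dtm`` elementwise, negatives clamped to 0."""
    dsm = np.asarray(dsm, dtype=float)
    dtm = np.asarray(dtm, dtype=float)
    if dsm.shape != dtm.shape:
        raise ValueError("dsm and dtm grids do not match")
    chm = dsm - dtm
    if clamp_negative:
        chm = np.where(np.isnan(chm), np.nan, np.maximum(chm, 0.0))
    return chm


def rgb_to_his(
    red: np.ndarray, green: np.ndarray, blue: np.ndarray, scale_255: bool = False
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """RGB (DN 0–255) → hue / intensity / saturation, HSL convention.

    Hue is in degrees [0, 360) with achromatic pixels assigned hue 0;
    intensity is HSL lightness ``(max+min)/2 / 255``; saturation follows the
    HSL definition. With ``scale_255`` all three outputs are rescaled to
    0–255 (the convention of GIS HIS tools).
    """
    chans = []
    for name, band in (("red", red), ("green", green), ("blue", blue)):
        band = np.asarray(band, dtype=float)
        if np.nanmin(band) < 0 or np.nanmax(band) > 255:
            logger.warning("%s band outside 0-255; clipping", name)
            band = np.clip(band, 0, 255)
        chans.append(band / 255.0)
    r, g, b = chans
    cmax = np.maximum(np.maximum(r, g), b)
    cmin = np.minimum(np.minimum(r, g), b)
    delta = cmax - cmin
    intensity = (cmax + cmin) / 2.0

    sat = np.zeros_like(intensity)
    chromatic = delta > 0
    denom = 1.0 - np.abs(2.0 * intensity - 1.0)
    np.divide(delta, denom, out=sat, where=chromatic & (denom > 0))

    hue = np.zeros_like(intensity)
    with np.errstate(invalid="ignore", divide="ignore"):
        hr = np.mod((g - b) / delta, 6.0)
        hg = (b - r) / delta + 2.0
        hb = (r - g) / delta + 4.0
    hue = np.where(chromatic & (cmax == r), hr, hue)
    hue = np.where(chromatic & (cmax == g) & (cmax != r), hg, hue)
    hue = np.where(chromatic & (cmax == b) & (cmax != r) & (cmax != g), hb, hue)
    hue = hue * 60.0
    if scale_255:
        return hue / 360.0 * 255.0, intensity * 255.0, sat * 255.0
    return hue, intensity, sat


def his_to_rgb(
    hue: np.ndarray, intensity: np.ndarray, sat: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Inverse HSL transform (hue degrees, intensity/saturation 0–1) → DN."""
    h = np.asarray(hue, dtype=float) / 60.0
    li = np.asarray(intensity, dtype=float)
    s = np.asarray(sat, dtype=float)
    c = (1.0 - np.abs(2.0 * li - 1.0)) * s
    x = c * (1.0 - np.abs(np.mod(h, 2.0) - 1.0))
    m = li - c / 2.0
    zeros = np.zeros_like(h)
    conds = [(h < 1), (h < 2), (h < 3), (h < 4), (h < 5), (h >= 5)]
    r = np.select(conds, [c, x, zeros, zeros, x, c])
    g = np.select(conds, [x, c, c, x, zeros, zeros])
    b = np.select(conds, [zeros, zeros, x, c, c, x])
    return (r + m) * 255.0, (g + m) * 255.0, (b + m) * 255.0


# ---------------------------------------------------------------------------
# vegetation indices


def _safe_divide(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    """Elementwise division; zero denominators yield NaN (nodata)."""
    out = np.full(np.broadcast(num, den).shape, np.nan)
    np.divide(num, den, out=out, where=den != 0)
    return out


def _exg(r, g, b):
    tot = r + g + b
    rn, gn, bn = _safe_divide(r, tot), _safe_divide(g, tot), _safe_divide(b, tot)
    return 2.0 * gn - rn - bn


def _exr(r, g, b):
    tot = r + g + b
    return 1.4 * _safe_divide(r, tot) - _safe_divide(g, tot)


RGB_VI_FORMULAS = {
    "ExG": _exg,
    "ExR": _exr,
    "ExGR": lambda r, g, b: _exg(r, g, b) - _exr(r, g, b),
    "NGRDI": lambda r, g, b: _safe_divide(g - r, g + r),
}

# band-role mapping for the 10-band sensor (see module docstring); the
# wavelengths closest to each index's canonical definition are used.
MS_ROLES = {
    "blue": "blue475",
    "green": "green560",
    "red": "red668",
    "re705": "re705",
    "re717": "re717",
    "nir": "nir840",
}

MS_VI_FORMULAS = {
    "CIg": lambda B: _safe_divide(B["nir"], B["green"]) - 1.0,
    "EVI": lambda B: 2.5 * _safe_divide(
        B["nir"] - B["red"], B["nir"] + 6.0 * B["red"] - 7.5 * B["blue"] + 1.0
    ),
    "GARI": lambda B: _safe_divide(
        B["nir"] - (B["green"] - 1.7 * (B["blue"] - B["red"])),
        B["nir"] + (B["green"] - 1.7 * (B["blue"] - B["red"])),
    ),
    "GNDVI": lambda B: _safe_divide(B["nir"] - B["green"], B["nir"] + B["green"]),
    "MCARI": lambda B: (
        (B["re705"] - B["red"]) - 0.2 * (B["re705"] - B["green"])
    ) * _safe_divide(B["re705"], B["red"]),
    "MSAVI": lambda B: (
        2.0 * B["nir"] + 1.0
        - np.sqrt(np.maximum((2.0 * B["nir"] + 1.0) ** 2 - 8.0 * (B["nir"] - B["red"]), 0.0))
    ) / 2.0,
    "NDVI": lambda B: _safe_divide(B["nir"] - B["red"], B["nir"] + B["red"]),
    "SR_717": lambda B: _safe_divide(B["nir"], B["re717"]),
}


def compute_vis_rgb(stack: RasterStack) -> RasterStack:
    """ExG / ExR / ExGR / NGRDI from the red/green/blue bands."""
    for name in ("red", "green", "blue"):
        if name not in stack:
            raise ValueError(f"missing band {name!r}")
    r, g, b = stack["red"], stack["green"], stack["blue"]
    out = RasterStack(stack.grid, nodata_mask=stack.nodata_mask.copy(),
                      value_domain="index")
    for name, fn in RGB_VI_FORMULAS.items():
        out.add_band(name, fn(r, g, b))
    return out


def compute_vis_ms(stack: RasterStack, roles: dict[str, str] | None = None) -> RasterStack:
    """The eight multispectral indices from the 10-band reflectance stack."""
    roles = roles or MS_ROLES
    bands = {}
    for role, band_name in roles.items():
        if band_name not in stack:
            raise ValueError(f"missing band {band_name!r} for role {role!r}")
        bands[role] = stack[band_name]
    out = RasterStack(stack.grid, nodata_mask=stack.nodata_mask.copy(),
                      value_domain="index")
    for name, fn in MS_VI_FORMULAS.items():
        out.add_band(name, fn(bands))
    return out


# ---------------------------------------------------------------------------
# alignment


def align_rasters(
    rasters: list[tuple[str, np.ndarray, GridSpec]], target_grid: GridSpec
) -> RasterStack:
    """Nearest-neighbor resample each (name, values, grid) onto target_grid.

    Ties in nearest-neighbor distance are broken toward the upper-left
    source cell (via floor on half-open cell intervals). Already-aligned
    inputs pass through unchanged. Cells whose center falls outside a source
    raster become nodata.
    """
    out = RasterStack(target_grid, value_domain="index")
    xs, ys = target_grid.cell_centers()
    names = [name for name, _, _ in rasters]
    if len(set(names)) != len(names):
        raise ValueError("duplicate band names")
    for name, values, grid in rasters:
        values = np.asarray(values, dtype=float)
        if values.shape != grid.shape:
            raise ValueError(f"raster {name!r} shape does not match its grid")
        xmin, ymin, xmax, ymax = grid.bounds
        txmin, tymin, txmax, tymax = target_grid.bounds
        if txmax <= xmin or txmin >= xmax or tymax <= ymin or tymin >= ymax:
            raise ValueError(f"raster {name!r} does not overlap the target grid")
        if grid.same_grid(target_grid):
            out.add_band(name, values.copy())
            continue
        row, col = grid.xy_to_rowcol(xs, ys)
        inside = (row >= 0) & (row < grid.n_rows) & (col >= 0) & (col < grid.n_cols)
        resampled = np.full(target_grid.shape, np.nan)
        resampled[inside] = values[row[inside], col[inside]]
        out.add_band(name, resampled)
    return out


def build_analysis_stack(
    spectral: RasterStack,
    dsm: np.ndarray,
    dtm: np.ndarray,
    sensor: str,
    scale_his_255: bool = False,
) -> RasterStack:
    """Full per-sensor stack: bands (+HIS for RGB), CHM, and the sensor's VIs."""
    out = spectral.subset(spectral.band_names)
    if sensor == "rgb":
        h, i, s = rgb_to_his(spectral["red"], spectral["green"], spectral["blue"],
                             scale_255=scale_his_255)
        out.add_band("hue", h)
        out.add_band("intensity", i)
        out.add_band("saturation", s)
        vis = compute_vis_rgb(spectral)
    elif sensor == "ms":
        vis = compute_vis_ms(spectral)
    else:
        raise ValueError(f"unknown sensor {sensor!r}")
    out.add_band("CHM", compute_chm(dsm, dtm))
    return out.merge(vis)


#: bands used for segmentation (vs the full classification feature set)
SEGMENTATION_BANDS = {
    "rgb": ["red", "green", "blue", "hue", "intensity", "saturation", "CHM"],
    "ms": list(
        ("blue444", "blue475", "green531", "green560", "red650",
         "red668", "re705", "re717", "re740", "nir840", "CHM")
    ),
}
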