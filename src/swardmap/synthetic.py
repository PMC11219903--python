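"""Synthetic mixed-sward scene generator with known ground truth.

Produces everything the downstream analysis consumes: a patchy 4-class
ground-cover map (grass=1, clover=2, plantain=3, weed=4), co-registered
spectral imagery for an RGB-like (3 DN bands, 2 mm) or MS-like (10
reflectance bands, 2 cm) sensor, surface/terrain elevation grids, plot and
subplot vector layers, labeled reference polygons, ground points for terrain
interpolation, and a dry-matter-yield table whose clover weight fraction is a
distorted, noisy function of true clover cover.

All randomness flows from a single integer seed; identical configs produce
bit-identical scenes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml
from scipy.ndimage import gaussian_filter
from shapely.geometry import box

from .rasters import GridSpec, RasterStack, write_ascii_grid
from .vectors import Feature, write_geojson

logger = logging.getLogger(__name__)

__all__ = [
    "CLASS_CODES",
    "CLASS_NAMES",
    "SceneConfig",
    "SceneLayout",
    "SyntheticScene",
    "generate_class_map",
    "render_scene",
    "generate_reference_polygons",
    "generate_dmy",
    "generate_scene",
]

CLASS_CODES = {"grass": 1, "clover": 2, "plantain": 3, "weed": 4}
CLASS_NAMES = {v: k for k, v in CLASS_CODES.items()}

RGB_BANDS = ("red", "green", "blue")
MS_BANDS = (
    "blue444", "blue475", "green531", "green560", "red650",
    "red668", "re705", "re717", "re740", "nir840",
)

# Per-class band means. Grass is darker than clover in nearly every band;
# plantain and weed sit close to clover so they stay confusable.
DEFAULT_SPECTRAL = {
    "rgb": {
        "bands": RGB_BANDS,
        "means": {
            1: [62.0, 95.0, 40.0],
            2: [82.0, 120.0, 55.0],
            3: [78.0, 114.0, 60.0],
            4: [86.0, 118.0, 50.0],
        },
        "sd": 4.0,         # smooth (patch-level) variability
        "sd_texture": 4.5,  # blocky leaf/sub-patch variability
        "range": (0.0, 255.0),
        "value_domain": "dn_0_255",
    },
    "ms": {
        "bands": MS_BANDS,
        "means": {
            1: [0.040, 0.045, 0.080, 0.090, 0.055, 0.050, 0.180, 0.250, 0.330, 0.420],
            2: [0.045, 0.052, 0.095, 0.110, 0.065, 0.060, 0.210, 0.290, 0.370, 0.500],
            3: [0.044, 0.050, 0.092, 0.106, 0.068, 0.064, 0.200, 0.280, 0.360, 0.480],
            4: [0.046, 0.053, 0.090, 0.104, 0.063, 0.059, 0.210, 0.283, 0.362, 0.490],
        },
        "sd": 0.012,
        "sd_texture": 0.0135,
        "range": (0.0, 1.0),
        "value_domain": "reflectance_0_1",
    },
}

# Canopy heights (m): near-identical medians across classes on purpose.
DEFAULT_HEIGHTS = {
    1: (0.20, 0.02),
    2: (0.21, 0.02),
    3: (0.22, 0.02),
    4: (0.20, 0.02),
}


@dataclass(frozen=True)
class SceneLayout:
    """Plot / subplot layout: replicates as columns, mixtures as rows."""

    n_replicates: int = 4
    n_mixtures: int = 2
    plot_size_m: float = 5.12
    n_subplots: int = 10
    subplot_size_m: float = 0.55

    @property
    def n_plots(self) -> int:
        return self.n_replicates * self.n_mixtures

    @property
    def extent_m(self) -> tuple[float, float]:
        """(width, height) of the full scene in meters."""
        return (self.n_replicates * self.plot_size_m, self.n_mixtures * self.plot_size_m)


@dataclass
class SceneConfig:
    extent_m: tuple[float, float] = (4.0, 4.0)
    pixel_size_m: float = 0.02
    class_priors: tuple[float, ...] = (0.45, 0.45, 0.07, 0.03)
    patch_scale_m: float = 0.35
    noise_corr_m: float = 0.35
    texture_scale_m: float = 0.15
    separation_scale: float = 1.0
    spectral_model: dict[str, Any] = field(default_factory=lambda: DEFAULT_SPECTRAL)
    height_model: dict[int, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_HEIGHTS)
    )
    dmy_beta: float = 0.5
    dmy_noise_sd: float = 0.05
    dmy_total_mean_g: float = 60.0
    dmy_total_sd: float = 0.15
    label_coverage_target: float = 0.17
    layout: SceneLayout = field(default_factory=SceneLayout)
    seed: int = 0

    def __post_init__(self) -> None:
        priors = np.asarray(self.class_priors, dtype=float)
        if priors.ndim != 1 or len(priors) != 4:
            raise ValueError("class_priors must list 4 fractions")
        if (priors < 0).any() or abs(priors.sum() - 1.0) > 1e-9:
            raise ValueError("class_priors must be non-negative and sum to 1")
        if self.pixel_size_m <= 0:
            raise ValueError("pixel_size_m must be positive")
        if not (0.0 <= self.label_coverage_target < 1.0):
            raise ValueError("label_coverage_target must be in [0, 1)")
        if self.dmy_beta <= 0:
            raise ValueError("dmy_beta must be positive")
        if min(self.extent_m) < self.pixel_size_m:
            raise ValueError("extent smaller than one pixel")

    def class_means(self, sensor: str) -> dict[int, np.ndarray]:
        """Per-class band means after applying separation_scale."""
        model = self.spectral_model[sensor]
        means = {c: np.asarray(m, dtype=float) for c, m in model["means"].items()}
        grand = np.mean(list(means.values()), axis=0)
        return {c: grand + self.separation_scale * (m - grand) for c, m in means.items()}


def _spawn(seed: int, stream: str) -> np.random.Generator:
    """Independent deterministic substream keyed by name."""
    import hashlib

    digest = hashlib.blake2s(stream.encode(), digest_size=4).digest()
    key = int.from_bytes(digest, "little")
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(key,)))


def _correlated_noise(shape: tuple[int, int], sigma_px: float,
                      rng: np.random.Generator) -> np.ndarray:
    """Unit-variance spatially correlated Gaussian field."""
    white = rng.standard_normal(shape)
    if sigma_px <= 0:
        return white
    smooth = gaussian_filter(white, sigma_px, mode="reflect")
    sd = smooth.std()
    if sd < 1e-12:
        return np.zeros(shape)
    return smooth / sd


def _voronoi_cells(shape: tuple[int, int], cell_px: float,
                   rng: np.random.Generator) -> tuple[np.ndarray, int]:
    """Partition the grid into ~cell_px-sized Voronoi cells of random seeds."""
    from scipy.spatial import cKDTree

    h, w = shape
    n_cells = max(1, int(round(h * w / cell_px**2)))
    seeds = np.column_stack([rng.uniform(0, h, n_cells), rng.uniform(0, w, n_cells)])
    tree = cKDTree(seeds)
    rr, cc = np.meshgrid(np.arange(h) + 0.5, np.arange(w) + 0.5, indexing="ij")
    _, cell = tree.query(np.column_stack([rr.ravel(), cc.ravel()]))
    return cell.reshape(shape).astype(np.int32), n_cells


def _patchy_argmax(shape: tuple[int, int], priors: np.ndarray, sigma_px: float,
                   rng: np.random.Generator, n_calib: int = 150) -> np.ndarray:
    """Argmax of offset-calibrated smoothed Gaussian fields → class codes 1..K.

    Offsets are fitted by damped, clamped log-proportional steps with Laplace
    smoothing, which stays stable even on tiny grids where a rare class's
    realized count can drop to zero; the best-matching iterate is kept.
    """
    k = len(priors)
    fields = np.stack(
        [_correlated_noise(shape, sigma_px, rng) for _ in range(k)], axis=0
    )
    offsets = np.zeros(k)
    active = priors > 0
    offsets[~active] = -np.inf
    n = shape[0] * shape[1]
    best_labels = None
    best_err = np.inf
    labels = np.argmax(fields + offsets[:, None, None], axis=0)
    for _ in range(n_calib):
        counts = (np.bincount(labels.ravel(), minlength=k) + 1.0) / (n + k)
        err = np.abs(counts[active] - priors[active]).max()
        if err < best_err:
            best_err = err
            best_labels = labels
        if err < 2e-3:
            break
        step = np.clip(np.log(priors + 1.0 / n) - np.log(counts), -1.0, 1.0)
        offsets[active] += 0.4 * step[active]
        labels = np.argmax(fields + offsets[:, None, None], axis=0)
    return best_labels.astype(np.int32) + 1


def generate_class_map(
    cfg: SceneConfig,
    shape: tuple[int, int] | None = None,
    priors: tuple[float, ...] | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Generate a patchy class-code grid (codes 1..4).

    Patches are spatially contiguous at roughly ``patch_scale_m``; realized
    class fractions approach ``class_priors`` as the extent grows.
    """
    if shape is None:
        w, h = cfg.extent_m
        shape = (int(round(h / cfg.pixel_size_m)), int(round(w / cfg.pixel_size_m)))
    if shape[0] < 1 or shape[1] < 1:
        raise ValueError("extent smaller than one pixel")
    pr = np.asarray(priors if priors is not None else cfg.class_priors, dtype=float)
    if (pr < 0).any() or abs(pr.sum() - 1.0) > 1e-9:
        raise ValueError("priors must be non-negative and sum to 1")
    if rng is None:
        rng = _spawn(cfg.seed, "class_map")
    if np.count_nonzero(pr) == 1:
        return np.full(shape, int(np.argmax(pr)) + 1, dtype=np.int32)
    sigma_px = cfg.patch_scale_m / cfg.pixel_size_m / 2.0
    return _patchy_argmax(shape, pr, sigma_px, rng)


def _dtm_surface(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Deterministic gentle terrain: low-frequency sinusoids (meters)."""
    return (
        10.0
        + 0.15 * np.sin(2 * np.pi * x / 23.0)
        + 0.10 * np.cos(2 * np.pi * y / 31.0)
        + 0.01 * (x + y) / 10.0
    )


def render_scene(
    class_map: np.ndarray,
    cfg: SceneConfig,
    sensor: str,
    grid: GridSpec | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[RasterStack, np.ndarray, np.ndarray]:
    """Render spectral bands plus DSM/DTM for a class map.

    Returns (stack, dsm, dtm). Band values are the class spectral mean plus
    spatially correlated Gaussian noise, clipped to the sensor's valid range;
    ``dsm = dtm + class height + noise``; the DTM is a deterministic surface.
    """
    if sensor not in cfg.spectral_model:
        raise ValueError(f"unknown sensor {sensor!r}")
    model = cfg.spectral_model[sensor]
    class_map = np.asarray(class_map)
    codes = np.unique(class_map)
    if not np.isin(codes, list(CLASS_NAMES)).all():
        raise ValueError("class_map contains invalid codes")
    if grid is None:
        grid = GridSpec(0.0, class_map.shape[0] * cfg.pixel_size_m,
                        cfg.pixel_size_m, *class_map.shape)
    if rng is None:
        rng = _spawn(cfg.seed, f"render_{sensor}")

    means = cfg.class_means(sensor)
    bands = list(model["bands"])
    sd = model["sd"]
    sds = np.full(len(bands), sd, dtype=float) if np.isscalar(sd) else np.asarray(sd, float)
    lo, hi = model["range"]
    sigma_px = cfg.noise_corr_m / grid.pixel_size

    mean_lut = np.zeros((5, len(bands)))
    for c, m in means.items():
        mean_lut[c] = m
    sd_tex = model.get("sd_texture", 0.0)
    tex_sds = (np.full(len(bands), sd_tex, dtype=float)
               if np.isscalar(sd_tex) else np.asarray(sd_tex, float))
    cells = None
    if (tex_sds > 0).any():
        cells, n_cells = _voronoi_cells(
            class_map.shape, cfg.texture_scale_m / grid.pixel_size, rng)
        tex_offsets = rng.standard_normal((n_cells, len(bands)))
    stack = RasterStack(grid, value_domain=model["value_domain"])
    for bi, name in enumerate(bands):
        vals = mean_lut[class_map, bi]
        if sds[bi] > 0:
            vals = vals + sds[bi] * _correlated_noise(class_map.shape, sigma_px, rng)
        if cells is not None and tex_sds[bi] > 0:
            vals = vals + tex_sds[bi] * tex_offsets[cells, bi]
        stack.add_band(name, np.clip(vals, lo, hi))

    xs, ys = grid.cell_centers()
    dtm = _dtm_surface(xs, ys)
    h_mean = np.zeros(5)
    h_sd = np.zeros(5)
    for c, (m, s) in cfg.height_model.items():
        h_mean[c], h_sd[c] = m, s
    heights = h_mean[class_map]
    noise_sd = h_sd[class_map]
    if (noise_sd > 0).any():
        heights = heights + noise_sd * _correlated_noise(class_map.shape, sigma_px, rng)
    dsm = dtm + np.maximum(heights, 0.0)
    return stack, dsm, dtm


def generate_reference_polygons(
    class_map: np.ndarray,
    cfg: SceneConfig,
    grid: GridSpec | None = None,
    rng: np.random.Generator | None = None,
    min_side_px: int = 4,
    max_side_px: int | None = None,
    purity: float = 0.95,
) -> list[Feature]:
    """Draw labeled rectangles inside single-class patches.

    Rectangles are snapped to pixel boundaries; each candidate is accepted
    only if at least ``purity`` of its pixels carry its class, and rectangles
    accumulate until total area reaches ``label_coverage_target`` of the
    scene. Counts naturally reflect class prevalence because candidate
    centers are sampled uniformly.
    """
    class_map = np.asarray(class_map)
    n_rows, n_cols = class_map.shape
    if grid is None:
        grid = GridSpec(0.0, n_rows * cfg.pixel_size_m, cfg.pixel_size_m, n_rows, n_cols)
    if rng is None:
        rng = _spawn(cfg.seed, "refpolys")
    target_px = cfg.label_coverage_target * class_map.size
    if target_px <= 0:
        return []
    if max_side_px is None:
        max_side_px = max(min_side_px + 1, int(cfg.patch_scale_m / grid.pixel_size * 0.8))
    present = set(np.unique(class_map).tolist())
    for code in CLASS_NAMES:
        if code not in present:
            logger.warning("class %s absent from class map; no reference polygons",
                           CLASS_NAMES[code])

    features: list[Feature] = []
    covered = np.zeros_like(class_map, dtype=bool)
    area_px = 0
    attempts = 0
    max_attempts = int(50 * target_px / (min_side_px**2) + 1000)
    pid = 0
    while area_px < target_px and attempts < max_attempts:
        attempts += 1
        r = int(rng.integers(0, n_rows))
        c = int(rng.integers(0, n_cols))
        code = int(class_map[r, c])
        h = int(rng.integers(min_side_px, max_side_px + 1))
        w = int(rng.integers(min_side_px, max_side_px + 1))
        r0, r1 = max(0, r - h // 2), min(n_rows, r + (h + 1) // 2)
        c0, c1 = max(0, c - w // 2), min(n_cols, c + (w + 1) // 2)
        block = class_map[r0:r1, c0:c1]
        if block.size < min_side_px**2:
            continue
        if covered[r0:r1, c0:c1].any():
            continue
        if np.mean(block == code) < purity:
            continue
        covered[r0:r1, c0:c1] = True
        area_px += block.size
        pid += 1
        x0 = grid.origin_x + c0 * grid.pixel_size
        x1 = grid.origin_x + c1 * grid.pixel_size
        y0 = grid.origin_y - r1 * grid.pixel_size
        y1 = grid.origin_y - r0 * grid.pixel_size
        features.append({
            "geometry": box(x0, y0, x1, y1),
            "polygon_id": pid,
            "class": code,
            "class_name": CLASS_NAMES[code],
        })
    return features


def true_cover_table(
    class_map: np.ndarray, grid: GridSpec, subplots: list[Feature]
) -> pd.DataFrame:
    """Per-subplot per-class pixel-fraction ground truth (fractions sum to 1)."""
    rows = []
    for sp in subplots:
        minx, miny, maxx, maxy = sp["geometry"].bounds
        r0, c0 = grid.xy_to_rowcol(np.array([minx]), np.array([maxy]))
        r1, c1 = grid.xy_to_rowcol(np.array([maxx - 1e-9]), np.array([miny + 1e-9]))
        block = class_map[max(0, r0[0]): r1[0] + 1, max(0, c0[0]): c1[0] + 1]
        counts = np.bincount(block.ravel(), minlength=5)[1:5]
        fracs = counts / counts.sum()
        for code, f in zip(range(1, 5), fracs):
            rows.append({
                "subplot_id": sp["subplot_id"],
                "class": code,
                "class_name": CLASS_NAMES[code],
                "cover_fraction": float(f),
            })
    return pd.DataFrame(rows)


def generate_dmy(
    true_cover: pd.DataFrame,
    cfg: SceneConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Dry-matter-yield table with a distorted clover weight fraction.

    The clover weight fraction follows ``w = β·c / (β·c + (1 − c))`` with
    ``c`` the true clover cover and ``β = dmy_beta`` (β < 1 makes visible
    clover over-represent its weight), multiplied by lognormal noise; the
    non-clover remainder is split among the other classes in proportion to
    their cover. Total subplot weight is lognormal around
    ``dmy_total_mean_g``.
    """
    if cfg.dmy_beta <= 0:
        raise ValueError("dmy_beta must be positive")
    if rng is None:
        rng = _spawn(cfg.seed, "dmy")
    rows = []
    for sid, grp in true_cover.groupby("subplot_id", sort=True):
        cover = dict(zip(grp["class"], grp["cover_fraction"]))
        total_cover = sum(cover.values())
        if abs(total_cover - 1.0) > 1e-6:
            raise ValueError("per-subplot cover fractions must sum to 1")
        c = cover.get(CLASS_CODES["clover"], 0.0)
        beta = cfg.dmy_beta
        w = beta * c / (beta * c + (1.0 - c)) if c > 0 else 0.0
        if cfg.dmy_noise_sd > 0:
            w = min(w * float(rng.lognormal(0.0, cfg.dmy_noise_sd)), 0.999)
        rest_cover = {k: v for k, v in cover.items() if k != CLASS_CODES["clover"]}
        rest_total = sum(rest_cover.values())
        total_g = cfg.dmy_total_mean_g * float(rng.lognormal(0.0, cfg.dmy_total_sd))
        for code in range(1, 5):
            if code == CLASS_CODES["clover"]:
                frac = w
            elif rest_total > 0:
                frac = (1.0 - w) * rest_cover.get(code, 0.0) / rest_total
            else:
                frac = 0.0
            rows.append({
                "subplot_id": sid,
                "class": code,
                "class_name": CLASS_NAMES[code],
                "dry_weight_g": total_g * frac,
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# full-scene assembly


REPLICATE_LETTERS = "ABCDEFGH"
MIXTURE_CODES = (2, 3)  # grass-clover, grass-clover-plantain


def _mixture_priors(cfg: SceneConfig, mixture: int) -> np.ndarray:
    """Plot-level priors: mixture 2 has no plantain; mixture 3 has all four."""
    pr = np.asarray(cfg.class_priors, dtype=float).copy()
    if mixture == 2:
        pr[CLASS_CODES["plantain"] - 1] = 0.0
    return pr / pr.sum()


@dataclass
class SyntheticScene:
    """Bundle of all generated layers plus ground truth."""

    cfg: SceneConfig
    sensor: str
    grid: GridSpec
    stack: RasterStack
    dsm: np.ndarray
    dtm: np.ndarray
    class_map: np.ndarray
    plots: list[Feature]
    subplots: list[Feature]
    ref_polygons: list[Feature]
    ground_points: pd.DataFrame
    true_cover: pd.DataFrame
    dmy: pd.DataFrame

    def write(self, outdir: str | Path) -> Path:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.stack.write(outdir / "stack")
        write_ascii_grid(outdir / "dsm.asc", self.dsm, self.grid)
        write_ascii_grid(outdir / "dtm.asc", self.dtm, self.grid)
        write_ascii_grid(outdir / "class_map.asc", self.class_map.astype(float), self.grid)
        write_geojson(self.plots, outdir / "plots.geojson")
        write_geojson(self.subplots, outdir / "subplots.geojson")
        write_geojson(self.ref_polygons, outdir / "reference_polygons.geojson")
        self.ground_points.to_csv(outdir / "ground_points.csv", index=False)
        self.true_cover.to_csv(outdir / "true_cover.csv", index=False)
        self.dmy.to_csv(outdir / "dmy.csv", index=False)
        cfg = asdict(self.cfg)
        cfg["sensor"] = self.sensor
        (outdir / "scene_config.yaml").write_text(yaml.safe_dump(cfg))
        return outdir


def generate_scene(cfg: SceneConfig, sensor: str = "ms") -> SyntheticScene:
    """Generate the full 8-plot scene for one sensor.

    Plots tile the extent (replicates as columns, mixtures as rows); each
    plot's class map is generated with mixture-specific priors; subplot
    frames are placed inside plots without overlap; reference polygons and a
    DMY table provide ground truth for the downstream stages.
    """
    if sensor not in cfg.spectral_model:
        raise ValueError(f"unknown sensor {sensor!r}")
    lay = cfg.layout
    px = cfg.pixel_size_m
    plot_px = int(round(lay.plot_size_m / px))
    n_rows = lay.n_mixtures * plot_px
    n_cols = lay.n_replicates * plot_px
    grid = GridSpec(0.0, n_rows * px, px, n_rows, n_cols)

    class_map = np.zeros((n_rows, n_cols), dtype=np.int32)
    plots: list[Feature] = []
    for mi in range(lay.n_mixtures):
        mixture = MIXTURE_CODES[mi % len(MIXTURE_CODES)]
        for ri in range(lay.n_replicates):
            replicate = REPLICATE_LETTERS[ri]
            plot_id = f"{replicate}{mixture}"
            rng = _spawn(cfg.seed, f"plot_{plot_id}")
            pr = _mixture_priors(cfg, mixture)
            sub = generate_class_map(cfg, shape=(plot_px, plot_px), priors=tuple(pr),
                                     rng=rng)
            r0, c0 = mi * plot_px, ri * plot_px
            class_map[r0:r0 + plot_px, c0:c0 + plot_px] = sub
            x0 = grid.origin_x + c0 * px
            y1 = grid.origin_y - r0 * px
            plots.append({
                "geometry": box(x0, y1 - lay.plot_size_m, x0 + lay.plot_size_m, y1),
                "plot_id": plot_id,
                "replicate": replicate,
                "mixture": mixture,
            })

    stack, dsm, dtm = render_scene(class_map, cfg, sensor, grid=grid)

    # 20 ground points on a near-regular 5x4 lattice with exact terrain z
    gp_rng = _spawn(cfg.seed, "groundpoints")
    xmin, ymin, xmax, ymax = grid.bounds
    gxs, gys, gzs = [], [], []
    for iy in range(4):
        for ix in range(5):
            # jitter keeps the triangulation non-degenerate; points stay inside
            gx = xmin + (ix + 0.5) / 5 * (xmax - xmin) + gp_rng.uniform(-0.1, 0.1) * px * 10
            gy = ymin + (iy + 0.5) / 4 * (ymax - ymin) + gp_rng.uniform(-0.1, 0.1) * px * 10
            gxs.append(gx)
            gys.append(gy)
            gzs.append(float(_dtm_surface(np.array(gx), np.array(gy))))
    ground_points = pd.DataFrame({"x": gxs, "y": gys, "z": gzs})

    # subplot frames: round-robin over plots, rejection-placed without overlap
    sp_rng = _spawn(cfg.seed, "subplots")
    subplots: list[Feature] = []
    placed: list[Any] = []
    size = lay.subplot_size_m
    for si in range(lay.n_subplots):
        plot = plots[si % len(plots)]
        pxmin, pymin, pxmax, pymax = plot["geometry"].bounds
        for _ in range(200):
            ox = sp_rng.uniform(pxmin + 0.05, pxmax - size - 0.05)
            oy = sp_rng.uniform(pymin + 0.05, pymax - size - 0.05)
            # snap to pixel boundaries so pixel-count truth is exact
            ox = round(ox / px) * px
            oy = round(oy / px) * px
            frame = box(ox, oy, ox + size, oy + size)
            if all(not frame.intersects(p) for p in placed):
                placed.append(frame)
                subplots.append({
                    "geometry": frame,
                    "subplot_id": si + 1,
                    "plot_id": plot["plot_id"],
                })
                break
        else:  # pragma: no cover - layout always has room
            raise RuntimeError("could not place subplot without overlap")

    refs = generate_reference_polygons(class_map, cfg, grid=grid)
    for f in refs:
        pt = f["geometry"].centroid
        for p in plots:
            if p["geometry"].intersects(pt):
                f["plot_id"] = p["plot_id"]
                f["replicate"] = p["replicate"]
                break

    cover = true_cover_table(class_map, grid, subplots)
    dmy = generate_dmy(cover, cfg)
    return SyntheticScene(
        cfg=cfg, sensor=sensor, grid=grid, stack=stack, dsm=dsm, dtm=dtm,
        class_map=class_map, plots=plots, subplots=subplots, ref_polygons=refs,
        ground_points=ground_points, true_cover=cover, dmy=dmy,
    )
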