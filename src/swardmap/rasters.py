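"""Georeferenced raster grids and multi-band stacks.

Coordinate convention (used throughout the package): pixel (row, col) with the
origin at the grid's upper-left corner, half-open cell intervals, and map y
*decreasing* with row.  Cell centers sit at ``x = origin_x + (col + 0.5) * px``
and ``y = origin_y - (row + 0.5) * px``.

Rasters are persisted as ESRI ASCII grids (one ``.asc`` file per band) with a
JSON manifest describing band order and value domain, so every artifact on
disk is plain text.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "GridSpec",
    "RasterStack",
    "read_ascii_grid",
    "write_ascii_grid",
]

#: valid value-domain tags for a band / stack
VALUE_DOMAINS = ("dn_0_255", "reflectance_0_1", "meters", "index")


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a regular raster grid.

    Parameters
    ----------
    origin_x, origin_y:
        Map coordinates of the grid's *upper-left corner*.
    pixel_size:
        Cell edge length in map units (meters).
    n_rows, n_cols:
        Grid shape.
    """

    origin_x: float
    origin_y: float
    pixel_size: float
    n_rows: int
    n_cols: int

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must contain at least one cell")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the grid footprint."""
        return (
            self.origin_x,
            self.origin_y - self.n_rows * self.pixel_size,
            self.origin_x + self.n_cols * self.pixel_size,
            self.origin_y,
        )

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (x, y) center coordinate arrays of shape (n_rows, n_cols)."""
        cols = np.arange(self.n_cols)
        rows = np.arange(self.n_rows)
        x = self.origin_x + (cols + 0.5) * self.pixel_size
        y = self.origin_y - (rows + 0.5) * self.pixel_size
        return np.meshgrid(x, y)

    def rowcol_to_xy(self, rows: np.ndarray, cols: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Cell-center map coordinates for (row, col) indices."""
        rows = np.asarray(rows, dtype=float)
        cols = np.asarray(cols, dtype=float)
        return (
            self.origin_x + (cols + 0.5) * self.pixel_size,
            self.origin_y - (rows + 0.5) * self.pixel_size,
        )

    def xy_to_rowcol(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Indices of the half-open cells containing map points (x, y)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.origin_x) / self.pixel_size).astype(int)
        row = np.floor((self.origin_y - y) / self.pixel_size).astype(int)
        return row, col

    def same_grid(self, other: "GridSpec", tol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and abs(self.origin_x - other.origin_x) <= tol
            and abs(self.origin_y - other.origin_y) <= tol
            and abs(self.pixel_size - other.pixel_size) <= tol
        )


class RasterStack:
    """Named co-registered 2-D bands sharing one :class:`GridSpec`.

    Bands are stored as float64 arrays; the nodata mask is shared across all
    bands (True = invalid) and propagates to every derived band.
    """

    def __init__(
        self,
        grid: GridSpec,
        bands: Mapping[str, np.ndarray] | None = None,
        nodata_mask: np.ndarray | None = None,
        value_domain: str = "index",
    ) -> None:
        if value_domain not in VALUE_DOMAINS:
            raise ValueError(f"unknown value_domain {value_domain!r}")
        self.grid = grid
        self.value_domain = value_domain
        self._bands: dict[str, np.ndarray] = {}
        if nodata_mask is None:
            nodata_mask = np.zeros(grid.shape, dtype=bool)
        else:
            nodata_mask = np.asarray(nodata_mask, dtype=bool)
            if nodata_mask.shape != grid.shape:
                raise ValueError("nodata mask shape does not match grid")
        self.nodata_mask = nodata_mask
        if bands:
            for name, arr in bands.items():
                self.add_band(name, arr)

    # -- mapping-ish access -------------------------------------------------
    @property
    def band_names(self) -> list[str]:
        return list(self._bands)

    def __contains__(self, name: str) -> bool:
        return name in self._bands

    def __getitem__(self, name: str) -> np.ndarray:
        return self._bands[name]

    def __len__(self) -> int:
        return len(self._bands)

    def add_band(self, name: str, values: np.ndarray) -> None:
        if name in self._bands:
            raise ValueError(f"duplicate band name {name!r}")
        values = np.asarray(values, dtype=float)
        if values.shape != self.grid.shape:
            raise ValueError(
                f"band {name!r} shape {values.shape} does not match grid {self.grid.shape}"
            )
        self._bands[name] = values
        self.nodata_mask |= ~np.isfinite(values)

    def as_array(self, band_names: Iterable[str] | None = None) -> np.ndarray:
        """Stack bands into an (n_rows, n_cols, n_bands) array."""
        names = list(band_names) if band_names is not None else self.band_names
        return np.stack([self._bands[n] for n in names], axis=-1)

    def subset(self, band_names: Iterable[str]) -> "RasterStack":
        out = RasterStack(self.grid, nodata_mask=self.nodata_mask.copy(),
                          value_domain=self.value_domain)
        for n in band_names:
            out.add_band(n, self._bands[n])
        return out

    def window(self, r0: int, r1: int, c0: int, c1: int) -> "RasterStack":
        """Sub-stack for rows [r0, r1) and cols [c0, c1), origin adjusted."""
        sub_grid = GridSpec(
            origin_x=self.grid.origin_x + c0 * self.grid.pixel_size,
            origin_y=self.grid.origin_y - r0 * self.grid.pixel_size,
            pixel_size=self.grid.pixel_size,
            n_rows=r1 - r0,
            n_cols=c1 - c0,
        )
        out = RasterStack(sub_grid, nodata_mask=self.nodata_mask[r0:r1, c0:c1].copy(),
                          value_domain=self.value_domain)
        for n in self.band_names:
            out.add_band(n, self._bands[n][r0:r1, c0:c1])
        return out

    def merge(self, other: "RasterStack") -> "RasterStack":
        """Union of bands of two stacks on the same grid (names must not clash)."""
        if not self.grid.same_grid(other.grid):
            raise ValueError("cannot merge stacks on different grids")
        out = RasterStack(self.grid, value_domain=self.value_domain,
                          nodata_mask=self.nodata_mask | other.nodata_mask)
        for n in self.band_names:
            out.add_band(n, self[n])
        for n in other.band_names:
            out.add_band(n, other[n])
        return out

    # -- persistence --------------------------------------------------------
    def write(self, directory: str | Path) -> Path:
        """Write one ``.asc`` per band plus ``stack.json`` into *directory*."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name in self.band_names:
            arr = self._bands[name].copy()
            arr[self.nodata_mask] = np.nan
            write_ascii_grid(directory / f"{name}.asc", arr, self.grid)
        manifest = {
            "bands": self.band_names,
            "value_domain": self.value_domain,
            "pixel_size": self.grid.pixel_size,
            "origin": [self.grid.origin_x, self.grid.origin_y],
            "shape": [self.grid.n_rows, self.grid.n_cols],
        }
        (directory / "stack.json").write_text(json.dumps(manifest, indent=2))
        return directory

    @classmethod
    def read(cls, directory: str | Path) -> "RasterStack":
        directory = Path(directory)
        manifest = json.loads((directory / "stack.json").read_text())
        stack: RasterStack | None = None
        for name in manifest["bands"]:
            arr, grid = read_ascii_grid(directory / f"{name}.asc")
            if stack is None:
                stack = cls(grid, value_domain=manifest["value_domain"])
            stack.add_band(name, arr)
        assert stack is not None
        return stack


NODATA_SENTINEL = -99999.0


def write_ascii_grid(path: str | Path, values: np.ndarray, grid: GridSpec) -> Path:
    """Write a single band as an ESRI ASCII grid (NaN → NODATA)."""
    path = Path(path)
    values = np.asarray(values, dtype=float)
    if values.shape != grid.shape:
        raise ValueError("value shape does not match grid")
    xmin, ymin, _, _ = grid.bounds
    header = (
        f"ncols {grid.n_cols}\n"
        f"nrows {grid.n_rows}\n"
        f"xllcorner {xmin!r}\n"
        f"yllcorner {ymin!r}\n"
        f"cellsize {grid.pixel_size!r}\n"
        f"NODATA_value {NODATA_SENTINEL!r}\n"
    )
    body = values.copy()
    body[~np.isfinite(body)] = NODATA_SENTINEL
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, body, fmt="%.10g")
    return path


def read_ascii_grid(path: str | Path) -> tuple[np.ndarray, GridSpec]:
    """Read an ESRI ASCII grid; NODATA cells become NaN."""
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        values = np.loadtxt(fh)
    n_rows, n_cols = int(header["nrows"]), int(header["ncols"])
    values = values.reshape(n_rows, n_cols)
    nodata = header.get("nodata_value")
    if nodata is not None:
        values[values == nodata] = np.nan
    px = header["cellsize"]
    grid = GridSpec(
        origin_x=header["xllcorner"],
        origin_y=header["yllcorner"] + n_rows * px,
        pixel_size=px,
        n_rows=n_rows,
        n_cols=n_cols,
    )
    return values, grid
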