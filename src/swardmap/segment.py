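"""Mean-shift segmentation under the spatialr / ranger / minsize contract.

Pipeline: per-pixel mean-shift filtering (square spatial window of radius
``spatialr`` in pixels, spectral radius ``ranger`` in radiometry units) →
4-connected clustering of converged modes → iterative merging of regions
smaller than ``minsize`` into their spectrally nearest neighbor →
vectorization of the label grid into map-unit polygons.

The filter inner loop is numba-jitted; an optional tiling mode runs the
filter on overlapping tiles (margin ``spatialr × max_iter``, capped at half
the tile size) so memory stays bounded on large scenes, while clustering and
merging operate on the assembled mode grid — tiled and untiled runs produce
identical partitions whenever the margin covers the filter's spatial reach.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from numba import njit
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from shapely.geometry import MultiPolygon, Polygon
from shapely.geometry.base import BaseGeometry

from .rasters import GridSpec, RasterStack

__all__ = [
    "SegmentationParams",
    "SegmentMap",
    "meanshift_filter",
    "cluster_modes",
    "merge_small_regions",
    "vectorize",
    "segment_image",
]


@dataclass(frozen=True)
class SegmentationParams:
    spatialr: int
    ranger: float
    minsize: int
    max_iter: int = 100
    conv_threshold: float = 0.1
    tile_size: Optional[int] = None
    connectivity: int = 4
    standardize_bands: bool = False

    def __post_init__(self) -> None:
        if self.spatialr < 1:
            raise ValueError("spatialr must be >= 1")
        if self.ranger <= 0:
            raise ValueError("ranger must be > 0")
        if self.minsize < 1:
            raise ValueError("minsize must be >= 1")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")


@dataclass
class SegmentMap:
    """Integer label grid (0 = nodata) plus per-label polygons in map units."""

    labels: np.ndarray
    grid: GridSpec
    params: SegmentationParams
    polygons: dict[int, BaseGeometry] = field(default_factory=dict)

    @property
    def n_segments(self) -> int:
        return len(np.setdiff1d(np.unique(self.labels), [0]))

    def segment_ids(self) -> np.ndarray:
        return np.setdiff1d(np.unique(self.labels), [0])


# ---------------------------------------------------------------------------
# mean-shift filter


@njit(cache=True)
def _meanshift_kernel(img, spatialr, ranger, max_iter, conv_threshold):
    h, w, nb = img.shape
    out = np.empty_like(img)
    r2 = ranger * ranger
    val = np.empty(nb)
    acc = np.empty(nb)
    for i in range(h):
        for j in range(w):
            py = float(i)
            px = float(j)
            for b in range(nb):
                val[b] = img[i, j, b]
            for _ in range(max_iter):
                r0 = int(np.ceil(py - spatialr))
                r1 = int(np.floor(py + spatialr))
                c0 = int(np.ceil(px - spatialr))
                c1 = int(np.floor(px + spatialr))
                if r0 < 0:
                    r0 = 0
                if c0 < 0:
                    c0 = 0
                if r1 > h - 1:
                    r1 = h - 1
                if c1 > w - 1:
                    c1 = w - 1
                cnt = 0
                sy = 0.0
                sx = 0.0
                for b in range(nb):
                    acc[b] = 0.0
                for y in range(r0, r1 + 1):
                    for x in range(c0, c1 + 1):
                        d2 = 0.0
                        for b in range(nb):
                            diff = img[y, x, b] - val[b]
                            d2 += diff * diff
                        if d2 <= r2:
                            cnt += 1
                            sy += y
                            sx += x
                            for b in range(nb):
                                acc[b] += img[y, x, b]
                if cnt == 0:
                    break
                movement = 0.0
                for b in range(nb):
                    nv = acc[b] / cnt
                    diff = nv - val[b]
                    movement += diff * diff
                    val[b] = nv
                py = sy / cnt
                px = sx / cnt
                if np.sqrt(movement) < conv_threshold:
                    break
            for b in range(nb):
                out[i, j, b] = val[b]
    return out


#: fill value for masked pixels during filtering: far outside any radiometry
#: range, so masked cells never fall within `ranger` of valid data
_MASK_SENTINEL = 1e30


def _band_array(stack: "RasterStack | np.ndarray",
                valid: np.ndarray | None = None) -> np.ndarray:
    if isinstance(stack, RasterStack):
        arr = stack.as_array()
    else:
        arr = np.asarray(stack, dtype=float)
        if arr.ndim == 2:
            arr = arr[..., None]
    arr = np.ascontiguousarray(arr, dtype=np.float64)
    if valid is not None:
        arr = arr.copy()
        arr[~valid] = _MASK_SENTINEL
        check = arr[valid]
    else:
        check = arr
    if not np.isfinite(check).all():
        raise ValueError("stack contains non-finite values")
    return arr


def meanshift_filter(
    stack: "RasterStack | np.ndarray", params: SegmentationParams
) -> np.ndarray:
    """Per-pixel mean-shift: returns the converged spectral mode grid.

    Each pixel iterates: gather pixels within Chebyshev spatial distance
    ``spatialr`` of the current (floating) position whose Euclidean spectral
    distance to the current value is ≤ ``ranger``; replace value and
    position by their means; stop when the value moves less than
    ``conv_threshold`` or after ``max_iter`` iterations.
    """
    arr = _band_array(stack)
    if params.standardize_bands:
        mu = arr.reshape(-1, arr.shape[-1]).mean(axis=0)
        sd = arr.reshape(-1, arr.shape[-1]).std(axis=0)
        sd[sd == 0] = 1.0
        arr = (arr - mu) / sd
    return _meanshift_kernel(
        arr, float(params.spatialr), float(params.ranger),
        int(params.max_iter), float(params.conv_threshold),
    )


def _tiled_meanshift(arr: np.ndarray, params: SegmentationParams) -> np.ndarray:
    """Filter on overlapping tiles; interior outputs match the untiled run."""
    ts = int(params.tile_size)  # type: ignore[arg-type]
    margin = min(params.spatialr * params.max_iter, ts // 2)
    h, w, _ = arr.shape
    out = np.empty_like(arr)
    sub_params = SegmentationParams(
        spatialr=params.spatialr, ranger=params.ranger, minsize=params.minsize,
        max_iter=params.max_iter, conv_threshold=params.conv_threshold,
        tile_size=None, connectivity=params.connectivity,
        standardize_bands=False,
    )
    for r0 in range(0, h, ts):
        for c0 in range(0, w, ts):
            r1 = min(r0 + ts, h)
            c1 = min(c0 + ts, w)
            pr0, pc0 = max(0, r0 - margin), max(0, c0 - margin)
            pr1, pc1 = min(h, r1 + margin), min(w, c1 + margin)
            block = np.ascontiguousarray(arr[pr0:pr1, pc0:pc1])
            modes = _meanshift_kernel(
                block, float(sub_params.spatialr), float(sub_params.ranger),
                sub_params.max_iter, sub_params.conv_threshold,
            )
            out[r0:r1, c0:c1] = modes[r0 - pr0: r1 - pr0, c0 - pc0: c1 - pc0]
    return out


# ---------------------------------------------------------------------------
# clustering


def cluster_modes(
    modes: np.ndarray,
    params: SegmentationParams,
    valid: np.ndarray | None = None,
) -> np.ndarray:
    """Label 4-connected components of spectrally close modes.

    Adjacent valid pixels whose mode vectors differ by at most ``ranger``
    (Euclidean, pairwise along each 4-connection) share a label; labels are
    numbered 1..K in row-major discovery order. Invalid pixels get 0.
    """
    modes = np.asarray(modes, dtype=float)
    if modes.ndim == 2:
        modes = modes[..., None]
    h, w, _ = modes.shape
    if valid is None:
        valid = np.ones((h, w), dtype=bool)
    idx = np.arange(h * w).reshape(h, w)
    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []

    def _link(sl_a, sl_b):
        a_valid = valid[sl_a] & valid[sl_b]
        dist = np.sqrt(((modes[sl_a] - modes[sl_b]) ** 2).sum(axis=-1))
        ok = a_valid & (dist <= params.ranger)
        rows.append(idx[sl_a][ok])
        cols.append(idx[sl_b][ok])

    _link((slice(None), slice(0, w - 1)), (slice(None), slice(1, w)))
    _link((slice(0, h - 1), slice(None)), (slice(1, h), slice(None)))
    if params.connectivity == 8:
        _link((slice(0, h - 1), slice(0, w - 1)), (slice(1, h), slice(1, w)))
        _link((slice(0, h - 1), slice(1, w)), (slice(1, h), slice(0, w - 1)))

    n = h * w
    if rows:
        ri = np.concatenate(rows)
        ci = np.concatenate(cols)
    else:
        ri = np.empty(0, dtype=int)
        ci = np.empty(0, dtype=int)
    graph = sparse.coo_matrix((np.ones(len(ri)), (ri, ci)), shape=(n, n))
    _, comp = connected_components(graph, directed=False)
    comp = comp.reshape(h, w)
    return _relabel_rowmajor(comp, valid)


def _relabel_rowmajor(comp: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Renumber component ids 1..K in row-major first-appearance order."""
    flat = comp.ravel()
    vflat = valid.ravel()
    labels = np.zeros_like(flat, dtype=np.int32)
    vals = flat[vflat]
    if vals.size:
        uniq, first_idx = np.unique(vals, return_index=True)
        rank = np.empty(len(uniq), dtype=np.int32)
        rank[np.argsort(first_idx, kind="stable")] = np.arange(1, len(uniq) + 1)
        mapping = np.zeros(int(vals.max()) + 1, dtype=np.int32)
        mapping[uniq] = rank
        labels[vflat] = mapping[vals]
    return labels.reshape(comp.shape)


# ---------------------------------------------------------------------------
# small-region merging


def merge_small_regions(
    labels: np.ndarray,
    values: "RasterStack | np.ndarray",
    minsize: int,
) -> np.ndarray:
    """Merge regions smaller than ``minsize`` into spectrally nearest neighbors.

    Repeatedly, the smallest under-size region (ties: lowest label id) is
    merged into the 4-adjacent region whose mean spectral vector is nearest
    in Euclidean distance (ties: lowest label id); region means are updated
    after every merge. Stops when all regions reach ``minsize`` or one
    region remains. Label ids are renumbered 1..K in row-major order.
    """
    labels = np.asarray(labels)
    arr = _band_array(values)
    if arr.shape[:2] != labels.shape:
        raise ValueError("label grid and value grid shapes differ")
    valid = labels > 0
    ids, inv = np.unique(labels[valid], return_inverse=True)
    k = len(ids)
    if k <= 1:
        return _relabel_rowmajor(labels.astype(np.int64), valid)
    nb = arr.shape[-1]
    sizes = np.bincount(inv, minlength=k).astype(np.int64)
    sums = np.zeros((k, nb))
    flatvals = arr[valid]
    for b in range(nb):
        sums[:, b] = np.bincount(inv, weights=flatvals[:, b], minlength=k)

    # adjacency between compact region indices
    comp = np.zeros(labels.shape, dtype=np.int64)
    comp[valid] = inv
    adj: list[set[int]] = [set() for _ in range(k)]

    def _pairs(a_sl, b_sl):
        m = valid[a_sl] & valid[b_sl]
        a = comp[a_sl][m]
        b = comp[b_sl][m]
        diff = a != b
        return np.unique(np.stack([np.minimum(a[diff], b[diff]),
                                   np.maximum(a[diff], b[diff])], axis=1), axis=0)

    h, w = labels.shape
    pair_sets = []
    if w > 1:
        pair_sets.append(_pairs((slice(None), slice(0, w - 1)), (slice(None), slice(1, w))))
    if h > 1:
        pair_sets.append(_pairs((slice(0, h - 1), slice(None)), (slice(1, h), slice(None))))
    for ps in pair_sets:
        for a, b in ps:
            adj[a].add(int(b))
            adj[b].add(int(a))

    parent = np.arange(k)

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    alive = np.ones(k, dtype=bool)
    heap = [(int(sizes[i]), int(ids[i]), i) for i in range(k) if sizes[i] < minsize]
    heapq.heapify(heap)
    n_alive = k
    while heap and n_alive > 1:
        size, _, i = heapq.heappop(heap)
        if not alive[i] or sizes[i] != size or sizes[i] >= minsize:
            continue
        mean_i = sums[i] / sizes[i]
        best = -1
        best_d = np.inf
        best_label = None
        for jn in adj[i]:
            if not alive[jn]:
                continue
            mean_j = sums[jn] / sizes[jn]
            d = float(np.sqrt(((mean_i - mean_j) ** 2).sum()))
            lbl = int(ids[jn])
            if d < best_d - 1e-15 or (abs(d - best_d) <= 1e-15 and
                                      (best_label is None or lbl < best_label)):
                best_d = d
                best = jn
                best_label = lbl
        if best < 0:
            continue  # isolated under-size region: nothing to merge into
        # absorb i into best
        sums[best] += sums[i]
        sizes[best] += sizes[i]
        alive[i] = False
        n_alive -= 1
        parent[i] = best
        adj[best].update(x for x in adj[i] if x != best)
        for x in adj[i]:
            if x != best:
                adj[x].discard(i)
                adj[x].add(best)
        adj[best].discard(i)
        adj[i] = set()
        if sizes[best] < minsize:
            heapq.heappush(heap, (int(sizes[best]), int(ids[best]), best))

    root = np.array([find(i) for i in range(k)])
    merged = np.zeros_like(labels, dtype=np.int64)
    merged[valid] = root[comp[valid]] + 1
    return _relabel_rowmajor(merged, valid)


# ---------------------------------------------------------------------------
# vectorization

# outgoing-direction preference: at pinch vertices take the most
# counterclockwise turn relative to the incoming direction (keeps loops
# simple with the interior-on-left edge orientation)


def _trace_label_rings(edges: list[tuple[int, int, int, int]]):
    """Assemble directed unit edges into closed rings of (x, y) vertices."""
    from collections import defaultdict

    out_edges: dict[tuple[int, int], list[int]] = defaultdict(list)
    for i, (x0, y0, x1, y1) in enumerate(edges):
        out_edges[(x0, y0)].append(i)
    used = [False] * len(edges)
    rings = []
    for start in range(len(edges)):
        if used[start]:
            continue
        ring = []
        ei = start
        sx, sy = edges[start][0], edges[start][1]
        while True:
            used[ei] = True
            x0, y0, x1, y1 = edges[ei]
            ring.append((x0, y0))
            if (x1, y1) == (sx, sy):
                break
            cand = [j for j in out_edges[(x1, y1)] if not used[j]]
            if not cand:  # pragma: no cover - closed boundaries always continue
                break
            if len(cand) == 1:
                ei = cand[0]
            else:
                din = (x1 - x0, y1 - y0)
                best, best_cross = cand[0], -2
                for j in cand:
                    jx0, jy0, jx1, jy1 = edges[j]
                    dout = (jx1 - jx0, jy1 - jy0)
                    cross = din[0] * dout[1] - din[1] * dout[0]
                    if cross > best_cross:
                        best_cross = cross
                        best = j
                ei = best
        rings.append(ring)
    return rings


def _ring_signed_area(ring: list[tuple[int, int]]) -> float:
    a = 0.0
    n = len(ring)
    for i in range(n):
        x0, y0 = ring[i]
        x1, y1 = ring[(i + 1) % n]
        a += x0 * y1 - x1 * y0
    return a / 2.0


def vectorize(labels: np.ndarray, grid: GridSpec) -> dict[int, BaseGeometry]:
    """Trace each label's 4-connected pixel-block boundary into polygons.

    Boundary edges are collected with the region interior on the left and
    chained into closed rings; positive-area rings become shells, negative
    ones holes (matched to their containing shell). Output geometries are in
    map coordinates. Label 0 (nodata) is skipped.
    """
    labels = np.asarray(labels)
    h, w = labels.shape
    padded = np.zeros((h + 2, w + 2), dtype=labels.dtype)
    padded[1:-1, 1:-1] = labels

    per_label: dict[int, list[tuple[int, int, int, int]]] = {}

    def _collect(nb_sl, edge_fn):
        core = padded[1:-1, 1:-1]
        nb = padded[nb_sl]
        m = (core > 0) & (core != nb)
        rr, cc = np.nonzero(m)
        ll = core[rr, cc]
        for r, c, lab in zip(rr.tolist(), cc.tolist(), ll.tolist()):
            per_label.setdefault(lab, []).append(edge_fn(r, c))

    # directed so the pixel interior stays on the left of travel
    _collect((slice(0, h), slice(1, w + 1)),
             lambda r, c: (c, r, c + 1, r))            # top edge
    _collect((slice(2, h + 2), slice(1, w + 1)),
             lambda r, c: (c + 1, r + 1, c, r + 1))    # bottom edge
    _collect((slice(1, h + 1), slice(0, w)),
             lambda r, c: (c, r + 1, c, r))            # left edge
    _collect((slice(1, h + 1), slice(2, w + 2)),
             lambda r, c: (c + 1, r, c + 1, r + 1))    # right edge

    ox, oy, px = grid.origin_x, grid.origin_y, grid.pixel_size

    def _to_map(ring):
        return [(ox + x * px, oy - y * px) for x, y in ring]

    polygons: dict[int, BaseGeometry] = {}
    for lab, edges in per_label.items():
        rings = _trace_label_rings(edges)
        shells = []
        holes = []
        for ring in rings:
            if _ring_signed_area(ring) > 0:
                shells.append(ring)
            else:
                holes.append(ring)
        if len(shells) == 1:
            poly = Polygon(_to_map(shells[0]), [_to_map(hq) for hq in holes])
            polygons[lab] = poly
            continue
        shell_polys = [Polygon(_to_map(s)) for s in shells]
        hole_assign: list[list[list[tuple[float, float]]]] = [[] for _ in shells]
        for hq in holes:
            hp = Polygon(_to_map(hq)).representative_point()
            for si, sp in enumerate(shell_polys):
                if sp.contains(hp):
                    hole_assign[si].append(_to_map(hq))
                    break
        parts = [Polygon(_to_map(s), hs) for s, hs in zip(shells, hole_assign)]
        polygons[lab] = parts[0] if len(parts) == 1 else MultiPolygon(parts)
    return polygons


# ---------------------------------------------------------------------------
# composition


def segment_image(
    stack: "RasterStack | np.ndarray",
    params: SegmentationParams,
    grid: GridSpec | None = None,
    valid: np.ndarray | None = None,
    vectorize_output: bool = True,
) -> SegmentMap:
    """filter → cluster → merge → vectorize."""
    if valid is None:
        if isinstance(stack, RasterStack):
            valid = ~stack.nodata_mask
        else:
            tmp = np.asarray(stack, dtype=float)
            if tmp.ndim == 2:
                tmp = tmp[..., None]
            valid = np.isfinite(tmp).all(axis=-1)
    arr = _band_array(stack, valid=valid)
    if grid is None:
        if isinstance(stack, RasterStack):
            grid = stack.grid
        else:
            grid = GridSpec(0.0, float(arr.shape[0]), 1.0, arr.shape[0], arr.shape[1])
    if params.standardize_bands:
        flat = arr[valid]
        mu = flat.mean(axis=0)
        sd = flat.std(axis=0)
        sd[sd == 0] = 1.0
        arr = (arr - mu) / sd
        arr[~valid] = _MASK_SENTINEL
    if params.tile_size:
        modes = _tiled_meanshift(arr, params)
    else:
        modes = _meanshift_kernel(
            arr, float(params.spatialr), float(params.ranger),
            params.max_iter, params.conv_threshold,
        )
    labels = cluster_modes(modes, params, valid=valid)
    labels = merge_small_regions(labels, modes, params.minsize)
    polygons = vectorize(labels, grid) if vectorize_output else {}
    return SegmentMap(labels=labels, grid=grid, params=params, polygons=polygons)
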