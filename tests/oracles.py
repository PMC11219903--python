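"""Independent brute-force reference implementations used by the tests.

These deliberately share no code with the package: plain Python loops and
lists, written from the operation definitions, so agreement is meaningful.
"""

from __future__ import annotations

import math

import numpy as np


def meanshift_oracle(img, spatialr, ranger, max_iter, conv_threshold):
    """Per-pixel iterative mean shift, pure-Python."""
    img = np.asarray(img, dtype=float)
    h, w, nb = img.shape
    out = np.empty_like(img)
    for i in range(h):
        for j in range(w):
            py, px = float(i), float(j)
            val = [img[i, j, b] for b in range(nb)]
            for _ in range(max_iter):
                members = []
                for y in range(h):
                    for x in range(w):
                        if max(abs(y - py), abs(x - px)) > spatialr:
                            continue
                        d2 = sum((img[y, x, b] - val[b]) ** 2 for b in range(nb))
                        if d2 <= ranger * ranger:
                            members.append((y, x))
                if not members:
                    break
                n = len(members)
                new_val = [sum(img[y, x, b] for y, x in members) / n
                           for b in range(nb)]
                py = sum(y for y, _ in members) / n
                px = sum(x for _, x in members) / n
                movement = math.sqrt(sum((new_val[b] - val[b]) ** 2
                                         for b in range(nb)))
                val = new_val
                if movement < conv_threshold:
                    break
            out[i, j] = val
    return out


def cluster_oracle(modes, ranger):
    """BFS flood fill linking 4-adjacent modes within ranger; labels in
    row-major discovery order starting at 1."""
    modes = np.asarray(modes, dtype=float)
    if modes.ndim == 2:
        modes = modes[..., None]
    h, w, nb = modes.shape
    labels = np.zeros((h, w), dtype=int)
    nxt = 0
    for i in range(h):
        for j in range(w):
            if labels[i, j]:
                continue
            nxt += 1
            stack = [(i, j)]
            labels[i, j] = nxt
            while stack:
                y, x = stack.pop()
                for dy, dx in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                    ny, nx_ = y + dy, x + dx
                    if not (0 <= ny < h and 0 <= nx_ < w) or labels[ny, nx_]:
                        continue
                    d = math.sqrt(sum((modes[y, x, b] - modes[ny, nx_, b]) ** 2
                                      for b in range(nb)))
                    if d <= ranger:
                        labels[ny, nx_] = nxt
                        stack.append((ny, nx_))
    return labels


def merge_oracle(labels, values, minsize):
    """Direct simulation of smallest-region merging with mean updates."""
    labels = np.asarray(labels).copy()
    values = np.asarray(values, dtype=float)
    if values.ndim == 2:
        values = values[..., None]
    h, w, nb = values.shape

    def regions():
        regs = {}
        for i in range(h):
            for j in range(w):
                lab = labels[i, j]
                if lab > 0:
                    regs.setdefault(lab, []).append((i, j))
        return regs

    while True:
        regs = regions()
        if len(regs) <= 1:
            break
        small = [(len(px), lab) for lab, px in regs.items() if len(px) < minsize]
        if not small:
            break
        _, lab = min(small)
        pixels = regs[lab]
        neighbors = set()
        for i, j in pixels:
            for dy, dx in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                ni, nj = i + dy, j + dx
                if 0 <= ni < h and 0 <= nj < w:
                    nl = labels[ni, nj]
                    if nl > 0 and nl != lab:
                        neighbors.add(nl)
        if not neighbors:
            break
        mean_lab = np.mean([values[i, j] for i, j in pixels], axis=0)
        best, best_d = None, None
        for nl in sorted(neighbors):
            mean_n = np.mean([values[i, j] for i, j in regs[nl]], axis=0)
            d = math.sqrt(float(((mean_lab - mean_n) ** 2).sum()))
            if best is None or d < best_d - 1e-15:
                best, best_d = nl, d
        for i, j in pixels:
            labels[i, j] = best
    # renumber 1..K in row-major first-appearance order
    remap = {}
    out = np.zeros_like(labels)
    for i in range(h):
        for j in range(w):
            lab = labels[i, j]
            if lab > 0:
                if lab not in remap:
                    remap[lab] = len(remap) + 1
                out[i, j] = remap[lab]
    return out


def zonal_oracle(labels, band):
    """Per-zone mean and population sd via per-pixel grouping."""
    groups: dict[int, list[float]] = {}
    labels = np.asarray(labels)
    band = np.asarray(band, dtype=float)
    for i in range(labels.shape[0]):
        for j in range(labels.shape[1]):
            if labels[i, j] > 0:
                groups.setdefault(int(labels[i, j]), []).append(band[i, j])
    out = {}
    for lab, vals in groups.items():
        n = len(vals)
        mean = sum(vals) / n
        var = sum((v - mean) ** 2 for v in vals) / n
        out[lab] = (mean, math.sqrt(var))
    return out


def metrics_oracle(confusion):
    """Definition-by-definition OA / precision / recall / F1."""
    m = np.asarray(confusion, dtype=float)
    k = m.shape[0]
    oa = sum(m[i, i] for i in range(k)) / m.sum()
    per = {}
    for i in range(k):
        tp = m[i, i]
        col = sum(m[r, i] for r in range(k))
        row = sum(m[i, c] for c in range(k))
        p = tp / col if col > 0 else 0.0
        r = tp / row if row > 0 else 0.0
        f1 = 2 * p * r / (p + r) if p + r > 0 else 0.0
        per[i] = (p, r, f1)
    return oa, per


def tin_oracle(points_xyz, query_xy, triangles):
    """Barycentric interpolation: locate each query in a triangle by
    explicit point-in-triangle tests, then weight vertex z values."""
    out = []
    for qx, qy in query_xy:
        val = math.nan
        for tri in triangles:
            (x1, y1, z1), (x2, y2, z2), (x3, y3, z3) = [points_xyz[t] for t in tri]
            det = (y2 - y3) * (x1 - x3) + (x3 - x2) * (y1 - y3)
            if abs(det) < 1e-15:
                continue
            l1 = ((y2 - y3) * (qx - x3) + (x3 - x2) * (qy - y3)) / det
            l2 = ((y3 - y1) * (qx - x3) + (x1 - x3) * (qy - y3)) / det
            l3 = 1.0 - l1 - l2
            if min(l1, l2, l3) >= -1e-12:
                val = l1 * z1 + l2 * z2 + l3 * z3
                break
        out.append(val)
    return np.array(out)


def nearest_neighbor_oracle(values, src_grid, dst_grid):
    """Per-destination-cell nearest source-center selection with
    upper-left tie break (reproduced via half-open floor indexing)."""
    out = np.full(dst_grid.shape, np.nan)
    for r in range(dst_grid.n_rows):
        for c in range(dst_grid.n_cols):
            x = dst_grid.origin_x + (c + 0.5) * dst_grid.pixel_size
            y = dst_grid.origin_y - (r + 0.5) * dst_grid.pixel_size
            sc = math.floor((x - src_grid.origin_x) / src_grid.pixel_size)
            sr = math.floor((src_grid.origin_y - y) / src_grid.pixel_size)
            if 0 <= sr < src_grid.n_rows and 0 <= sc < src_grid.n_cols:
                out[r, c] = values[sr, sc]
    return out
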