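"""Full-scene species mapping and cover-fraction / dry-matter quantification.

Cover fractions clip the classified segment polygons with each subplot frame
(exact polygon intersection, so both sensor resolutions share one code
path): ``cover % = class area / subplot area × 100``. DMY proportions are
``class dry weight / total subplot dry weight × 100``. The cover-vs-DMY link
is summarized by ordinary least squares with R² (squared Pearson r), a
two-sided t-test on the slope, and a pointwise 95 % confidence band.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from shapely.strtree import STRtree

from .classify import feature_columns
from .segment import SegmentMap
from .synthetic import CLASS_NAMES
from .vectors import Feature

__all__ = [
    "predict_map",
    "cover_fractions",
    "dmy_proportions",
    "RegressionResult",
    "regress_cover_vs_dmy",
]


def predict_map(model, segments: SegmentMap, features: pd.DataFrame) -> list[Feature]:
    """Annotate every segment polygon with its predicted class."""
    ids = segments.segment_ids()
    feats = features.set_index("segment_id")
    missing = [int(i) for i in ids if int(i) not in feats.index]
    if missing:
        raise KeyError(f"features missing for segments {missing[:5]}...")
    cols = [c for c in feature_columns(features) if c in features.columns]
    x = feats.loc[ids, cols].to_numpy()
    pred = model.predict(x)
    out: list[Feature] = []
    for sid, cls in zip(ids, pred):
        out.append({
            "geometry": segments.polygons[int(sid)],
            "segment_id": int(sid),
            "class": int(cls),
            "class_name": CLASS_NAMES.get(int(cls), str(int(cls))),
        })
    return out


SLIVER_AREA = 1e-9  # m²; smaller unclassified residue is ignored


def cover_fractions(
    class_map: list[Feature],
    subplots: list[Feature],
    class_codes: tuple[int, ...] = (1, 2, 3, 4),
) -> pd.DataFrame:
    """Per-subplot per-class clipped area and cover percentage."""
    geoms = [f["geometry"] for f in class_map]
    tree = STRtree(geoms)
    scene_bounds = None
    if geoms:
        xs = [g.bounds for g in geoms]
        scene_bounds = (min(b[0] for b in xs), min(b[1] for b in xs),
                        max(b[2] for b in xs), max(b[3] for b in xs))
    rows = []
    for sp in subplots:
        frame = sp["geometry"]
        if scene_bounds is not None:
            minx, miny, maxx, maxy = frame.bounds
            if (minx < scene_bounds[0] - 1e-9 or miny < scene_bounds[1] - 1e-9
                    or maxx > scene_bounds[2] + 1e-9 or maxy > scene_bounds[3] + 1e-9):
                raise ValueError(f"subplot {sp.get('subplot_id')} outside mapped extent")
        areas = dict.fromkeys(class_codes, 0.0)
        for gi in tree.query(frame, predicate="intersects"):
            f = class_map[int(gi)]
            a = f["geometry"].intersection(frame).area
            if a > 0:
                areas[int(f["class"])] = areas.get(int(f["class"]), 0.0) + a
        total = frame.area
        classified = sum(areas.values())
        for code in class_codes:
            rows.append({
                "subplot_id": sp.get("subplot_id"),
                "class": code,
                "class_name": CLASS_NAMES.get(code, str(code)),
                "subplot_area_m2": total,
                "cover_area_m2": areas[code],
                "cover_pct": 100.0 * areas[code] / total,
            })
        gap = total - classified
        if gap > SLIVER_AREA and gap / total > 1e-6:
            rows[-1]["unclassified_area_m2"] = gap
    return pd.DataFrame(rows)


def dmy_proportions(dmy_table: pd.DataFrame) -> pd.DataFrame:
    """Per-subplot weight-% per class from the dry-weight table."""
    if (dmy_table["dry_weight_g"] < 0).any():
        raise ValueError("negative dry weights")
    out = []
    for sid, grp in dmy_table.groupby("subplot_id", sort=True):
        total = grp["dry_weight_g"].sum()
        if total <= 0:
            raise ValueError(f"zero total dry weight in subplot {sid}")
        for _, row in grp.iterrows():
            out.append({
                "subplot_id": sid,
                "class": row["class"],
                "dmy_pct": 100.0 * row["dry_weight_g"] / total,
            })
    return pd.DataFrame(out)


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int
    x_mean: float
    ss_x: float
    residual_se: float

    def confidence_band(self, x: np.ndarray, level: float = 0.95):
        """Pointwise CI for the mean response at x: (fit, lower, upper)."""
        x = np.asarray(x, dtype=float)
        fit = self.intercept + self.slope * x
        tcrit = stats.t.ppf(0.5 + level / 2.0, self.n - 2)
        se = self.residual_se * np.sqrt(1.0 / self.n + (x - self.x_mean) ** 2 / self.ss_x)
        return fit, fit - tcrit * se, fit + tcrit * se


def regress_cover_vs_dmy(cover_pct: np.ndarray, dmy_pct: np.ndarray) -> RegressionResult:
    """OLS of DMY proportion on cover percentage with slope t-test."""
    x = np.asarray(cover_pct, dtype=float)
    y = np.asarray(dmy_pct, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need >= 3 paired observations")
    if np.allclose(x, x[0]):
        raise ValueError("zero variance in x")
    res = stats.linregress(x, y)
    rvalue = res.rvalue
    if np.var(y) == 0:  # flat response: slope 0, no explained variance
        rvalue = 0.0
    n = len(x)
    resid = y - (res.intercept + res.slope * x)
    dof = n - 2
    residual_se = float(np.sqrt((resid**2).sum() / dof)) if dof > 0 else np.nan
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(rvalue**2),
        p_value=float(res.pvalue),
        n=n,
        x_mean=float(x.mean()),
        ss_x=float(((x - x.mean()) ** 2).sum()),
        residual_se=residual_se,
    )
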