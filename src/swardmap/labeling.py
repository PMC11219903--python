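"""Ground-truth attachment: spatial join of segments to labeled polygons,
reference-polygon summary tables, and correlation-matrix PCA.

Join semantics: ``within_overlap`` selects segments entirely inside a
labeled polygon *or* whose interior intersects one with positive area;
``within_only`` keeps only the entirely-inside segments. A segment touching
several labeled polygons takes the class of the largest intersection area;
exact ties exclude the segment (with a warning).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from shapely.strtree import STRtree

from .features import build_feature_table
from .rasters import RasterStack
from .segment import SegmentMap
from .synthetic import CLASS_NAMES
from .vectors import Feature

logger = logging.getLogger(__name__)

__all__ = [
    "count_polygons_by_class",
    "spatial_join_labels",
    "reference_summary",
    "pca_reference",
]

JOIN_MODES = ("within_overlap", "within_only")


def count_polygons_by_class(refs: list[Feature] | pd.DataFrame) -> pd.Series:
    """Per-class polygon counts (and total) for a labeled polygon set."""
    if isinstance(refs, pd.DataFrame):
        classes = refs["class"]
    else:
        classes = pd.Series([f["class"] for f in refs])
    counts = classes.value_counts().sort_index()
    counts.loc["total"] = counts.sum()
    return counts


def spatial_join_labels(
    segments: SegmentMap,
    refs: list[Feature],
    mode: str = "within_overlap",
    features: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Attach reference classes to segments by spatial join.

    Returns the learning database: one row per selected segment with its
    class (and the segment's feature columns when ``features`` is given).
    """
    if mode not in JOIN_MODES:
        raise ValueError(f"mode must be one of {JOIN_MODES}")
    if not refs:
        raise ValueError("empty reference polygon set")
    ref_geoms = [f["geometry"] for f in refs]
    tree = STRtree(ref_geoms)
    rows = []
    for sid, geom in segments.polygons.items():
        cand = tree.query(geom)
        if len(cand) == 0:
            continue
        within_any = False
        best: dict[int, float] = {}
        for ri in cand:
            ref = refs[int(ri)]
            rgeom = ref_geoms[int(ri)]
            if geom.within(rgeom):
                within_any = True
            inter = geom.intersection(rgeom).area
            if inter > 0:
                cls = int(ref["class"])
                best[cls] = best.get(cls, 0.0) + inter
        if not best:
            continue
        if mode == "within_only" and not within_any:
            continue
        ranked = sorted(best.items(), key=lambda kv: (-kv[1], kv[0]))
        if len(ranked) > 1 and abs(ranked[0][1] - ranked[1][1]) < 1e-12:
            logger.warning("segment %s: exact intersection-area tie; excluded", sid)
            continue
        rows.append({"segment_id": sid, "class": ranked[0][0],
                     "class_name": CLASS_NAMES.get(ranked[0][0], str(ranked[0][0]))})
    db = pd.DataFrame(rows)
    if features is not None and not db.empty:
        db = db.merge(features, on="segment_id", how="left", validate="1:1")
    return db


def reference_summary(refs: list[Feature], stack: RasterStack) -> pd.DataFrame:
    """Per-reference-polygon zonal means for all bands, keyed by class.

    This is the input table for the grouped boxplots and the PCA.
    """
    from .features import zonal_stats_polygons

    table = zonal_stats_polygons({f.get("polygon_id", i + 1): f["geometry"]
                                  for i, f in enumerate(refs)}, stack)
    meta = pd.DataFrame({
        "polygon_id": [f.get("polygon_id", i + 1) for i, f in enumerate(refs)],
        "class": [f["class"] for f in refs],
    })
    out = table.merge(meta, on="polygon_id", how="left")
    # keep only the means (the boxplot/PCA input), per-polygon sd is unused here
    keep = ["polygon_id", "class"] + [c for c in out.columns if c.endswith("_mean")]
    return out[keep]


def pca_reference(
    table: pd.DataFrame, drop_columns: tuple[str, ...] = ("polygon_id", "class")
) -> tuple[np.ndarray, pd.DataFrame, np.ndarray]:
    """Correlation-matrix PCA of the numeric columns.

    Columns are standardized (zero-variance columns dropped with a warning);
    components come from an eigen-decomposition of the correlation matrix,
    ordered by decreasing variance, with each component's largest-magnitude
    loading made positive. Returns (scores, loadings, explained_fractions).
    """
    num = table.drop(columns=[c for c in drop_columns if c in table], errors="ignore")
    num = num.select_dtypes(include=[np.number])
    if num.isna().any().any():
        raise ValueError("missing values in PCA input")
    if num.shape[0] < 2 or num.shape[1] < 2:
        raise ValueError("PCA needs >= 2 rows and >= 2 numeric columns")
    sd = num.std(ddof=1)
    zero_var = sd[sd == 0].index.tolist()
    if zero_var:
        logger.warning("dropping zero-variance columns: %s", zero_var)
        num = num.drop(columns=zero_var)
        sd = sd.drop(zero_var)
    z = (num - num.mean()) / sd
    corr = np.corrcoef(z.to_numpy(), rowvar=False)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval = np.maximum(eigval[order], 0.0)
    eigvec = eigvec[:, order]
    # sign convention: largest-magnitude loading positive
    for k in range(eigvec.shape[1]):
        imax = np.argmax(np.abs(eigvec[:, k]))
        if eigvec[imax, k] < 0:
            eigvec[:, k] = -eigvec[:, k]
    scores = z.to_numpy() @ eigvec
    loadings = pd.DataFrame(
        eigvec, index=num.columns,
        columns=[f"PC{i + 1}" for i in range(eigvec.shape[1])],
    )
    explained = eigval / eigval.sum()
    return scores, loadings, explained


def plot_key_lookup(plots: list[Feature]):
    """Point → {plot_id, replicate} resolver for feature-table key columns."""
    plot_tree = STRtree([p["geometry"] for p in plots])

    def lookup(point):
        hits = plot_tree.query(point, predicate="intersects")
        if len(hits):
            p = plots[int(hits[0])]
            return {"plot_id": p["plot_id"], "replicate": p["replicate"]}
        return {"plot_id": None, "replicate": None}

    return lookup


def build_learning_database(
    segmap: SegmentMap,
    stack: RasterStack,
    refs: list[Feature],
    plots: list[Feature],
    mode: str = "within_overlap",
    features: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Feature table + class labels + plot/replicate fold keys."""
    if features is None:
        features = build_feature_table(segmap, stack,
                                       plot_lookup=plot_key_lookup(plots))
    return spatial_join_labels(segmap, refs, mode=mode, features=features)
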