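"""Experiment orchestration: scene → stack → (grid of segmentations) →
learning database → spatial CV → metrics, plus full-scene mapping and
cover/DMY quantification for a designated parameter combination.

An experiment is a pure function of (config, seed): rerunning with the same
YAML config and seed writes byte-identical metric tables.
"""

from __future__ import annotations

import itertools
import json
import logging
import traceback
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .classify import RFHyperparams, make_folds, run_spatial_cv, train_rf
from .labeling import build_learning_database
from .preprocess import SEGMENTATION_BANDS, build_analysis_stack, compute_dtm_tin, GroundPointSet
from .quantify import cover_fractions, dmy_proportions, predict_map, regress_cover_vs_dmy
from .segment import SegmentationParams, segment_image
from .synthetic import CLASS_CODES, SceneConfig, SceneLayout, SyntheticScene, generate_scene
from .vectors import write_geojson

logger = logging.getLogger(__name__)

__all__ = [
    "ExperimentConfig",
    "enumerate_grid",
    "run_experiment",
    "drop_degenerate_combinations",
]


@dataclass
class ExperimentConfig:
    sensor: str = "ms"
    scene: dict[str, Any] = field(default_factory=dict)
    grid: dict[str, list] = field(default_factory=lambda: {
        "spatialr": [5], "ranger": [0.01, 0.02], "minsize": [2, 8]})
    labeling_mode: str = "within_overlap"
    rf: dict[str, Any] = field(default_factory=dict)
    segmentation: dict[str, Any] = field(default_factory=dict)  # max_iter etc.
    designated_combination: str | int = "best_oa"
    segment_per_plot: bool = True
    degenerate_floor: str | int = "labeled_polygons"
    seed: int = 0
    out: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**doc)

    def scene_config(self) -> SceneConfig:
        kwargs = dict(self.scene)
        if "layout" in kwargs and isinstance(kwargs["layout"], dict):
            kwargs["layout"] = SceneLayout(**kwargs["layout"])
        for tup_key in ("extent_m", "class_priors"):
            if tup_key in kwargs and isinstance(kwargs[tup_key], list):
                kwargs[tup_key] = tuple(kwargs[tup_key])
        kwargs.setdefault("seed", self.seed)
        return SceneConfig(**kwargs)


def enumerate_grid(grid: dict[str, list]) -> list[dict[str, Any]]:
    """Full factorial of the spatialr × ranger × minsize grid, in the
    conventional order (minsize fastest within ranger within spatialr)."""
    if not grid.get("spatialr") or not grid.get("ranger") or not grid.get("minsize"):
        raise ValueError("grid must list spatialr, ranger and minsize values")
    combos = []
    for sr, rr, ms in itertools.product(grid["spatialr"], grid["ranger"],
                                        grid["minsize"]):
        combos.append({"spatialr": sr, "ranger": rr, "minsize": ms})
    return combos


def drop_degenerate_combinations(
    report: pd.DataFrame, floor: int
) -> pd.DataFrame:
    """Flag combinations whose segment count falls below ``floor``."""
    out = report.copy()
    out["degenerate"] = out["n_segments"] < floor
    for _, row in out[out["degenerate"]].iterrows():
        logger.warning(
            "combination %s flagged: %d segments < floor %d",
            row["combination"], row["n_segments"], floor)
    return out


def segment_scene(seg_stack, scene: SyntheticScene, params: SegmentationParams,
                  per_plot: bool = True):
    """Segment the scene; with ``per_plot`` each plot is segmented
    independently (field plots are separate management units) and the label
    grids are composed with disjoint id ranges."""
    from .segment import SegmentMap

    if not per_plot:
        return segment_image(seg_stack, params)
    grid = seg_stack.grid
    labels = np.zeros(grid.shape, dtype=np.int32)
    polygons = {}
    offset = 0
    for p in scene.plots:
        minx, miny, maxx, maxy = p["geometry"].bounds
        r0, c0 = grid.xy_to_rowcol(np.array([minx]), np.array([maxy - 1e-9]))
        r1, c1 = grid.xy_to_rowcol(np.array([maxx - 1e-9]), np.array([miny + 1e-9]))
        r0, c0 = max(0, int(r0[0])), max(0, int(c0[0]))
        r1, c1 = min(grid.n_rows, int(r1[0]) + 1), min(grid.n_cols, int(c1[0]) + 1)
        sub = seg_stack.window(r0, r1, c0, c1)
        sm = segment_image(sub, params)
        sub_labels = sm.labels.copy()
        sub_labels[sub_labels > 0] += offset
        labels[r0:r1, c0:c1] = sub_labels
        for sid, geom in sm.polygons.items():
            polygons[sid + offset] = geom
        offset += int(sm.labels.max())
    return SegmentMap(labels=labels, grid=grid, params=params, polygons=polygons)


def run_experiment(cfg: ExperimentConfig, outdir: str | Path | None = None) -> dict:
    """Run the full workflow; returns a result dict and optionally writes
    metric tables, the classified map and the cover/DMY regression."""
    outdir = Path(outdir or cfg.out) if (outdir or cfg.out) else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    scene_cfg = cfg.scene_config()
    scene = generate_scene(scene_cfg, cfg.sensor)
    stack = prepare_stack(scene, cfg.sensor)
    seg_bands = [b for b in SEGMENTATION_BANDS[cfg.sensor] if b in stack]
    seg_stack = stack.subset(seg_bands)

    plots_df = pd.DataFrame([
        {"plot_id": p["plot_id"], "replicate": p["replicate"]} for p in scene.plots
    ])
    scheme = make_folds(plots_df)
    hp = RFHyperparams(seed=cfg.seed, **cfg.rf)

    combos = enumerate_grid(cfg.grid)
    rows = []
    runs: dict[int, dict] = {}
    for ci, combo in enumerate(combos, start=1):
        try:
            params = SegmentationParams(
                spatialr=int(combo["spatialr"]), ranger=float(combo["ranger"]),
                minsize=int(combo["minsize"]), **cfg.segmentation)
            segmap = segment_scene(seg_stack, scene, params,
                                   per_plot=cfg.segment_per_plot)
            from .features import build_feature_table
            from .labeling import plot_key_lookup
            feats_all = build_feature_table(segmap, stack,
                                            plot_lookup=plot_key_lookup(scene.plots))
            db = build_learning_database(segmap, stack, scene.ref_polygons,
                                         scene.plots, mode=cfg.labeling_mode,
                                         features=feats_all)
            if db.empty or db["class"].nunique() < 2:
                raise RuntimeError("learning database empty or single-class")
            report = run_spatial_cv(db, scheme, hp)
            pooled = report.pooled_metrics()
            row = {
                "combination": ci, **combo,
                "n_segments": segmap.n_segments,
                "n_labeled": len(db),
                "overall_accuracy": pooled["overall_accuracy"],
            }
            for code, pc in pooled["per_class"].items():
                row[f"f1_class{code}"] = pc["f1"]
            rows.append(row)
            runs[ci] = {"segmap": segmap, "db": db, "report": report,
                        "features": feats_all}
        except Exception as exc:  # noqa: BLE001 - combination failures are recorded
            logger.error("combination %d failed: %s", ci, exc)
            logger.debug(traceback.format_exc())
            rows.append({"combination": ci, **combo, "n_segments": 0,
                         "n_labeled": 0, "overall_accuracy": np.nan,
                         "error": str(exc)})
    report_df = pd.DataFrame(rows)

    floor = cfg.degenerate_floor
    if floor == "labeled_polygons":
        floor = len(scene.ref_polygons)
    report_df = drop_degenerate_combinations(report_df, int(floor))

    result: dict[str, Any] = {"combinations": report_df, "scene": scene,
                              "fold_scheme": scheme, "runs": runs}

    ok = report_df[~report_df["degenerate"] & report_df["overall_accuracy"].notna()]
    designated = None
    if cfg.designated_combination == "best_oa":
        if not ok.empty:
            designated = int(ok.loc[ok["overall_accuracy"].idxmax(), "combination"])
    else:
        designated = int(cfg.designated_combination)
    result["designated_combination"] = designated

    if designated is not None and designated in runs:
        run = runs[designated]
        model = train_rf(run["db"], hp)
        class_map = predict_map(model, run["segmap"], run["features"])
        cover = cover_fractions(class_map, scene.subplots)
        dmy_pct = dmy_proportions(scene.dmy)
        clover = CLASS_CODES["clover"]
        cx = cover[cover["class"] == clover].set_index("subplot_id")["cover_pct"]
        dy = dmy_pct[dmy_pct["class"] == clover].set_index("subplot_id")["dmy_pct"]
        joined = pd.concat([cx, dy], axis=1, join="inner").dropna()
        reg = regress_cover_vs_dmy(joined["cover_pct"].to_numpy(),
                                   joined["dmy_pct"].to_numpy())
        result.update({"class_map": class_map, "cover": cover,
                       "dmy_pct": dmy_pct, "regression": reg})

    if outdir:
        _write_outputs(result, outdir, cfg)
    return result


def prepare_stack(scene: SyntheticScene, sensor: str):
    """Analysis stack from scene layers, with the DTM rebuilt from ground
    points via TIN interpolation (the DSM is consumed as-is)."""
    points = GroundPointSet(scene.ground_points["x"].to_numpy(),
                            scene.ground_points["y"].to_numpy(),
                            scene.ground_points["z"].to_numpy())
    dtm, _ = compute_dtm_tin(points, scene.grid)
    return build_analysis_stack(scene.stack, scene.dsm, dtm, sensor)


def _fmt_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


def _write_outputs(result: dict, outdir: Path, cfg: ExperimentConfig) -> None:
    _fmt_csv(result["combinations"].drop(columns=["error"], errors="ignore"),
             outdir / "combinations.csv")
    metric_frames = []
    for ci, run in result["runs"].items():
        frame = run["report"].to_frame()
        frame.insert(0, "combination", ci)
        metric_frames.append(frame)
    if metric_frames:
        _fmt_csv(pd.concat(metric_frames, ignore_index=True), outdir / "metrics.csv")
    if "cover" in result:
        _fmt_csv(result["cover"], outdir / "cover.csv")
        _fmt_csv(result["dmy_pct"], outdir / "dmy_proportions.csv")
        reg = result["regression"]
        (outdir / "regression.json").write_text(json.dumps({
            "slope": reg.slope, "intercept": reg.intercept,
            "r_squared": reg.r_squared, "p_value": reg.p_value, "n": reg.n,
        }, indent=2))
        write_geojson(result["class_map"], outdir / "species_map.geojson")
    (outdir / "experiment.json").write_text(json.dumps({
        "sensor": cfg.sensor, "seed": cfg.seed,
        "designated_combination": result["designated_combination"],
        "n_combinations": int(len(result["combinations"])),
    }, indent=2))
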