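# swardmap

Object-based image analysis (OBIA) of mixed grass–clover sward imagery:
mean-shift segmentation of co-registered raster stacks, per-segment feature
extraction, Random Forest classification with replicate-wise spatial
cross-validation, and species cover-fraction quantification against
dry-matter-yield (DMY) proportions. A bundled synthetic sward-scene
generator provides fully ground-truthed inputs, so the entire chain runs
and is testable without any external data.

## Pipeline

```
synthetic scene ──► analysis stack ──► segmentation ──► features ──► labeling
 (class map, DSM,    (TIN DTM, CHM,     (mean-shift:     (zonal mean/   (spatial join
  spectra, plots,     HIS, vegetation    spatialr/        sd + shape     within/overlap)
  subplots, DMY)      indices, align)    ranger/minsize)  indices)           │
                                                                             ▼
          quantification ◄── species map ◄── Random Forest + spatial 4-fold CV
   (cover %, DMY %, OLS regression)          (500 trees, √p mtry, OA / per-class F1)
```

All rasters are ESRI ASCII grids (`.asc` + a `stack.json` manifest), vector
layers are GeoJSON, tables are CSV, configs are YAML — plain text end to end.

## CLI

Every stage is a subcommand of `swardmap` (or `python -m swardmap.cli`):

```bash
swardmap simulate   --config scene.yaml --sensor ms --out scene/ --seed 1
swardmap preprocess --scene scene/ --sensor ms --out stack/
swardmap segment    --stack stack/ --sensor ms --spatialr 5 --ranger 0.01 --minsize 2 --out seg/
swardmap features   --stack stack/ --segments seg/ --out features.csv
swardmap label      --features features.csv --segments seg/ --stack stack/ \
                    --refs scene/reference_polygons.geojson --out db.csv
swardmap cv         --db db.csv --plots scene/plots.geojson --seed 1 --out metrics.csv
swardmap map        --db db.csv --features features.csv --segments seg/ \
                    --stack stack/ --seed 1 --out map.geojson
swardmap quantify   --map map.geojson --subplots scene/subplots.geojson \
                    --dmy scene/dmy.csv --out quant/
swardmap experiment --config experiment.yaml --seed 1 --out results/
```

`experiment` runs the whole chain over a factorial `spatialr × ranger ×
minsize` grid, flags degenerate combinations, and produces per-combination
OA/F1 tables plus the cover-vs-DMY regression for the best combination.
Example experiment config:

```yaml
sensor: ms
scene:
  pixel_size_m: 0.02
  layout: {plot_size_m: 5.12, n_subplots: 10}
grid:
  spatialr: [5, 15]
  ranger: [0.01, 0.02]
  minsize: [2, 8, 14]
rf: {num_trees: 500}
labeling_mode: within_overlap
```

## Layout

| Module | Role |
| --- | --- |
| `swardmap.synthetic` | ground-truthed sward scene generator (class map, spectra, heights, plots, subplots, reference polygons, DMY) |
| `swardmap.rasters` / `swardmap.vectors` | grid geometry, ASCII-grid and GeoJSON I/O |
| `swardmap.preprocess` | TIN DTM, CHM, HIS transform, vegetation indices, nearest-neighbor alignment |
| `swardmap.segment` | mean-shift filter, mode clustering, minsize merging, polygon vectorization |
| `swardmap.features` | zonal statistics and polygon shape indices |
| `swardmap.labeling` | segment labeling by spatial join, reference summaries, PCA |
| `swardmap.classify` | Random Forest, replicate folds, confusion-matrix metrics |
| `swardmap.quantify` | full-scene species map, cover fractions, DMY proportions, OLS regression |
| `swardmap.pipeline` / `swardmap.cli` | experiment orchestration and command line |
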