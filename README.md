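# fieldseg

Weed instance segmentation in UAV imagery of seedling-stage row crops, and
the decision chain that turns detections into a variable-rate herbicide
prescription map.

Early-season weeds in soybean compete directly with the crop, but blanket
herbicide application wastes chemical on weed-free ground. Given nadir RGB
imagery flown at low altitude (12 m), the task is: segment every weed
instance at pixel level, place each detection on the map, and assign each
12 m × 12 m sprayer cell an application rate proportional to its weed
density. `fieldseg` implements that whole chain and a synthetic-field
generator that makes it testable end to end without field data.

## What is inside

**The network** is a YOLO-style anchor-free instance-segmentation model
(CSP backbone → SPPF → attention block → PAN neck → decoupled head with a
mask-prototype branch) with four switchable architectural upgrades aimed at
small, dense, low-contrast targets:

- **RCSOSA** — reparameterized convolution with channel shuffle and
  one-shot aggregation replaces every C3k2 stage. Each RCS unit splits
  channels, transforms one half through a multi-branch (3×3 + 1×1 +
  identity) convolution, and shuffles; at inference the branches fuse
  algebraically into a single 3×3 kernel with identical output.
- **SEAM** — a spatially enhanced attention module inside the post-SPPF
  attention block: a depthwise/pointwise residual path re-weighted by
  exponential channel attention.
- **iRMB** — an inverted residual mobile block (1×1 expand → windowed
  multi-head self-attention → 3×3 depthwise → 1×1 project) ahead of the
  mask-prototype branch.
- **ADown** — dual-branch downsampling: 2×2 average pool, channel split,
  then a 3×3 stride-2 conv branch and a 3×3 max-pool + 1×1 conv branch.
  For a c→c stride-2 contract it costs (5/2)c² parameters and (5/8)c²hw
  multiply-accumulates against 9c² and (9/4)c²hw for a plain 3×3 stride-2
  convolution — a factor of 18/5 = **3.6** in both.

The network runs on a small numpy reverse-mode autograd engine bundled with
the package (`fieldseg.nn`) — CPU-only, seeded, deterministic.

**Evaluation** follows the standard instance-segmentation protocol:
greedy score-ordered matching at IoU ≥ 0.5, precision `P = TP/(TP+FP)`,
recall `R = TP/(TP+FN)`, per-class average precision from the 101-point
interpolated precision–recall curve, and `mAP = (1/N) Σᵢ APᵢ`, reported
separately for the box and mask tracks.

**Georeferencing** maps a pixel through the nadir pinhole model
(`dx = (u−cx)·H/fx`), a Z·Y·X yaw-pitch-roll rotation into an ENU world
frame, and a Gauss–Krüger projection (WGS-84, 3° zones, scale 1, false
easting 500 000 m; Krüger series, round-trip < 1 mm) to WGS-84 geodetic
coordinates.

**Prescription mapping** grids the field at the 12 m sprayer working width,
counts georeferenced weed points per cell, classifies density into five
tiers (fixed thresholds 1–24 / 25–48 / 49–72 / 73–96 / ≥ 97 weeds per cell,
or exact Fisher–Jenks natural breaks recomputed from the data), and assigns
rates 120, 114, 108, 102, 96 L/hm² from the densest to the sparsest tier —
5 % of the 120 L/hm² baseline per step; weed-free cells get 0 (no spray).
Output is GeoJSON / CSV / GeoTIFF-or-ASCII raster.

**The synthetic generator** renders scenes that emulate the acquisition:
textured brown soil, crop rows of green seedlings (unlabeled background),
Poisson-scattered irregular weed blobs with exact per-pixel masks,
illumination gradients and soft shadows, plus UAV pose metadata. Dataset
construction mirrors field practice: 480 px sliding-window tiles, removal
of weed-free tiles, joint image/label augmentation, and a spatially
isolated train/val/test split (whole regions per split, 8:1:1).

## Worked example

Run the full chain on two synthetic frames (ground-truth masks stand in
for detections, so the decision chain is exercised without training):

```bash
fieldseg run --config examples/run.yaml
```

Output (abridged):

```json
"dataset":      {"tiles": 12, "positives": 12, "train": 8, "val": 2,
                 "test": 2, "train_augmented": 40},
"evaluate":     {"map_box": 1.0, "map_mask": 1.0},
"georeference": {"points": 43},
"prescribe":    {"cells": 1, "points_outside": 0,
                 "tiers": {"0": 0, "1": 0, "2": 1, "3": 0, "4": 0, "5": 0}}
```

Reading: the two 1440×960 scenes tile into 12 positive tiles (8/2/2 split,
8 training tiles expand to 40 after ×4 augmentation); evaluating the
ground-truth detections against themselves gives mAP@0.5 of 1.0 on both
tracks; 43 weed components are georeferenced; they all land in the single
12 m cell the small field spans, whose 43 weeds put it in density tier 2 →
102 L/hm², as `runs/demo/prescription.csv` shows:

```
row,col,x0,y0,size,weed_count,tier,rate_l_per_hm2,partial
0,0,456636.0,5405328.0,12.0,43,2,102.0,1
```

Other entry points:

```bash
fieldseg count --scale s --toggles 1111      # -> parameters: 8.560 M
fieldseg synth --seed 0 --scenes 1 --out ds  # dataset generation only
fieldseg train-smoke --tiles 8 --iterations 200   # trainability check
fieldseg ablation --scale n --input-size 64  # structural ablation table
```

## Layout

```
src/fieldseg/nn/        numpy autograd engine + layers
src/fieldseg/blocks.py  RCSOSA, SEAM, iRMB, ADown, RepConv, cost model
src/fieldseg/model.py   network assembly, ablation toggles, counting, fusion
src/fieldseg/train.py   losses, assigner, smoke trainer, inference
src/fieldseg/metrics.py matching, P/R, AP, mAP@0.5
src/fieldseg/synth.py   synthetic scenes + dataset pipeline
src/fieldseg/labels.py  LabelMe / YOLO-seg polygon IO
src/fieldseg/georef.py  pinhole + attitude + Gauss-Krüger chain
src/fieldseg/prescribe.py  12 m grid, tiers, rates, map export
src/fieldseg/pipeline.py   end-to-end orchestration, manifests
src/fieldseg/cli.py     `fieldseg` command-line interface
```

See `docs/methods.md` for the modelling assumptions, parameter choices and
known limitations.
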