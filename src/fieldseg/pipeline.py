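"""End-to-end orchestration: synthetic scenes (or ground truth supplied as
detections) → tiling/filtering/splitting → optional smoke training and
inference → mask evaluation → georeferencing → 12 m density grid →
prescription map export, under one seeded configuration.

Detections are produced per tile but merged back to scene space before
georeferencing: masks that meet across a shared tile edge are joined by
connected-component labelling, so an instance split by the tile grid is
georeferenced once.  With ground-truth masks fed as detections this chain
reproduces the generator's planted per-cell counts exactly.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from shapely.geometry import box as shapely_box
from skimage.measure import label as cc_label

from . import georef as G
from . import prescribe as P
from .metrics import evaluate_dataset, write_metrics_report
from .synth import (
    FieldParams,
    FieldScene,
    Tile,
    augment,
    filter_negative_tiles,
    generate_field,
    split_spatial,
    tile_scene,
    write_tiles,
)
from .train import tiles_to_ground_truth

__all__ = ["RunConfig", "run_end_to_end", "scene_to_projected",
           "planted_cell_counts", "detections_to_points", "ablation_report"]


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "runs/field"
    n_scenes: int = 2
    scene_width: int = 5280
    scene_height: int = 3956
    tile_size: int = 480
    stride: int | None = None
    weed_density: float = 2.0
    augment_multiplicity: int = 4
    label_format: str = "labelme"
    write_dataset: bool = True
    use_model: bool = False      # False: ground-truth masks act as detections
    model_scale: str = "n"
    train_iterations: int = 200
    cell_size: float = 12.0
    baseline_rate: float = 120.0
    classification: str = "fixed"  # or "jenks"
    lat: float = 48.78
    lon: float = 125.41

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def scene_to_projected(scene: FieldScene):
    """Affine pixel→Gauss-Krüger map of a nadir zero-attitude scene.

    Returns (easting0, northing0, gsd) so that a pixel (u, v) maps to
    (easting0 + u·gsd, northing0 − v·gsd).
    """
    anchor = G.geodetic_to_gk(G.GeoPoint(scene.pose.lat, scene.pose.lon))
    gsd = scene.params.gsd_m
    e0 = anchor.easting - scene.intrinsics.cx * gsd
    n0 = anchor.northing + scene.intrinsics.cy * gsd
    return e0, n0, gsd, anchor.zone


def planted_cell_counts(scenes, cells, tile_size: int) -> None:
    """Per-cell counts of planted weed components within the tiled extent.

    A 'weed point' is one connected component of the scene weed mask; its
    projected centroid is counted into the covering 12 m cell.
    """
    pts = []
    for scene in scenes:
        H, W = scene.label_map.shape
        h_cov = (H // tile_size) * tile_size
        w_cov = (W // tile_size) * tile_size
        mask = scene.label_map[:h_cov, :w_cov] > 0
        comps = cc_label(mask, connectivity=2)
        e0, n0, gsd, _zone = scene_to_projected(scene)
        for cid in range(1, comps.max() + 1):
            ys, xs = np.nonzero(comps == cid)
            u, v = xs.mean() + 0.5, ys.mean() + 0.5
            pts.append((e0 + u * gsd, n0 - v * gsd))
    P.count_points(cells, np.array(pts).reshape(-1, 2))


def detections_to_points(scene: FieldScene, tiles, detections) -> list[dict]:
    """Merge per-tile detection masks in scene space and georeference the
    resulting component centroids through the full coordinate chain."""
    H, W = scene.label_map.shape
    union = np.zeros((H, W), bool)
    scoremap = np.zeros((H, W), np.float32)
    for t, dets in zip(tiles, detections):
        r0, c0 = t.origin
        for d in dets:
            if d.mask is None:
                continue
            sub = union[r0 : r0 + d.mask.shape[0], c0 : c0 + d.mask.shape[1]]
            sub |= d.mask
            sm = scoremap[r0 : r0 + d.mask.shape[0], c0 : c0 + d.mask.shape[1]]
            np.maximum(sm, np.where(d.mask, d.score, 0), out=sm)
    comps = cc_label(union, connectivity=2)
    out = []
    for cid in range(1, comps.max() + 1):
        ys, xs = np.nonzero(comps == cid)
        u, v = float(xs.mean() + 0.5), float(ys.mean() + 0.5)
        gp = G.georeference_instance((u, v), scene.intrinsics, scene.pose)
        out.append({
            "point": gp,
            "scene_id": scene.scene_id,
            "score": float(scoremap[ys, xs].max()),
            "area_px": int(len(xs)),
        })
    return out


def _offset_latlon(lat: float, lon: float, d_east: float, d_north: float):
    base = G.geodetic_to_gk(G.GeoPoint(lat, lon))
    moved = G.ProjectedPoint(base.easting + d_east, base.northing + d_north, base.zone)
    gp = G.gk_to_geodetic(moved)
    return gp.lat, gp.lon


def run_end_to_end(cfg: RunConfig) -> dict:
    """Run the full perception→prescription chain; returns the manifest."""
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": asdict(cfg), "stages": {}, "artifacts": {}}

    def log_stage(name, t0, **stats):
        manifest["stages"][name] = {"seconds": round(time.time() - t0, 3), **stats}

    # 1. scenes laid out west→east
    t0 = time.time()
    scenes = []
    for i in range(cfg.n_scenes):
        params = FieldParams(width_px=cfg.scene_width, height_px=cfg.scene_height,
                             weed_density=cfg.weed_density)
        width_m = cfg.scene_width * params.gsd_m
        lat_i, lon_i = _offset_latlon(cfg.lat, cfg.lon, i * width_m, 0.0)
        params = FieldParams(width_px=cfg.scene_width, height_px=cfg.scene_height,
                             weed_density=cfg.weed_density, lat=lat_i, lon=lon_i)
        scene = generate_field(params, seed=cfg.seed + i)
        scene.scene_id = i
        scenes.append(scene)
    log_stage("generate", t0, scenes=len(scenes),
              instances=sum(len(s.instances) for s in scenes))

    # 2. tiling, filtering, spatial split, augmentation count
    t0 = time.time()
    tiles_by_scene = [tile_scene(s, cfg.tile_size, cfg.stride) for s in scenes]
    all_tiles = [t for ts in tiles_by_scene for t in ts]
    positives = filter_negative_tiles(all_tiles)
    if positives:
        splits = split_spatial(positives, seed=cfg.seed)
        train_aug = augment(splits["train"], cfg.augment_multiplicity, seed=cfg.seed)
    else:  # weed-free field: no dataset, an all-zero prescription map
        splits = {"train": [], "val": [], "test": []}
        train_aug = []
    log_stage("dataset", t0, tiles=len(all_tiles), positives=len(positives),
              train=len(splits["train"]), val=len(splits["val"]),
              test=len(splits["test"]), train_augmented=len(train_aug))
    if cfg.write_dataset and positives:
        write_tiles(positives, out_dir / "dataset", fmt=cfg.label_format)
        manifest["artifacts"]["dataset"] = str(out_dir / "dataset")

    # 3. detections: model inference or ground truth passthrough
    t0 = time.time()
    per_scene_tiles = [filter_negative_tiles(ts) for ts in tiles_by_scene]
    if cfg.use_model:
        from .model import ModelConfig, build_model
        from .train import TrainProtocol, predict, smoke_train

        model = build_model(ModelConfig(scale=cfg.model_scale,
                                        input_size=cfg.tile_size, seed=cfg.seed))
        smoke_train(model, splits["train"][:16],
                    TrainProtocol(iterations=cfg.train_iterations, seed=cfg.seed))
        detections_by_scene = [predict(model, [t.image for t in ts])
                               for ts in per_scene_tiles]
    else:
        detections_by_scene = []
        for ts in per_scene_tiles:
            gt = tiles_to_ground_truth(ts)
            from .metrics import InstancePrediction

            detections_by_scene.append([
                [InstancePrediction(box=g.box, score=1.0, class_id=0, mask=g.mask)
                 for g in gl] for gl in gt
            ])
    log_stage("detect", t0, mode="model" if cfg.use_model else "ground_truth")

    # 4. evaluation of detections against ground truth
    t0 = time.time()
    flat_preds = [d for ds in detections_by_scene for d in ds]
    flat_gts = []
    for ts in per_scene_tiles:
        flat_gts.extend(tiles_to_ground_truth(ts))
    box_m = evaluate_dataset(flat_preds, flat_gts, kind="box")
    mask_m = evaluate_dataset(flat_preds, flat_gts, kind="mask")
    write_metrics_report(out_dir / "metrics.json", box_m, mask_m)
    manifest["artifacts"]["metrics"] = str(out_dir / "metrics.json")
    log_stage("evaluate", t0, map_box=box_m["map"], map_mask=mask_m["map"])

    # 5. georeferencing
    t0 = time.time()
    points = []
    for scene, ts, dets in zip(scenes, per_scene_tiles, detections_by_scene):
        points.extend(detections_to_points(scene, ts, dets))
    G.write_points_geojson(
        out_dir / "weed_points.geojson",
        [p["point"] for p in points],
        [{k: v for k, v in p.items() if k != "point"} for p in points],
    )
    manifest["artifacts"]["weed_points"] = str(out_dir / "weed_points.geojson")
    log_stage("georeference", t0, points=len(points))

    # 6. density grid + prescription map
    t0 = time.time()
    polys = []
    for scene in scenes:
        e0, n0, gsd, zone = scene_to_projected(scene)
        H, W = scene.label_map.shape
        h_cov = (H // cfg.tile_size) * cfg.tile_size
        w_cov = (W // cfg.tile_size) * cfg.tile_size
        polys.append(shapely_box(e0, n0 - h_cov * gsd, e0 + w_cov * gsd, n0))
    from shapely.ops import unary_union

    field_poly = unary_union(polys)
    cells = P.make_grid(field_poly, cfg.cell_size)
    proj = [G.geodetic_to_gk(p["point"], zone) for p in points]
    outside = P.count_points(cells, np.array([[q.easting, q.northing] for q in proj]).reshape(-1, 2))
    rule = P.RateRule(baseline=cfg.baseline_rate)
    P.classify_cells(cells, cfg.classification, rule)

    def to_geodetic(x, y):
        gp = G.gk_to_geodetic(G.ProjectedPoint(x, y, zone))
        return (gp.lon, gp.lat)

    P.export_map(cells, out_dir / "prescription.geojson", "geojson", to_geodetic)
    P.export_map(cells, out_dir / "prescription.csv", "csv")
    manifest["artifacts"]["prescription"] = str(out_dir / "prescription.geojson")
    manifest["artifacts"]["prescription_csv"] = str(out_dir / "prescription.csv")
    log_stage("prescribe", t0, cells=len(cells), points_outside=outside,
              tiers={str(t): sum(1 for c in cells if c.tier == t) for t in range(6)})

    manifest["checksums"] = {
        name: _sha256(Path(p)) for name, p in manifest["artifacts"].items()
        if Path(p).is_file()
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    manifest["_cells"] = cells
    manifest["_scenes"] = scenes
    return manifest


def ablation_report(scale: str = "s", input_size: int = 480,
                    count_flops_at: int | None = None, out_csv=None) -> list[dict]:
    """Structural ablation table: one row per module combination.

    Populates the parameter/GFLOP columns from the assembled models; the
    accuracy columns are left to smoke-scale runs and are reported as
    smoke-scale, never as a field-scale reproduction.
    """
    import csv

    from .model import ablation_variant, build_model, count_flops, count_parameters

    rows = []
    combos = [
        (False, False, False, False), (True, False, False, False),
        (False, True, False, False), (False, False, True, False),
        (False, False, False, True), (True, True, False, False),
        (True, True, True, False), (True, False, True, True),
        (True, True, False, True), (True, True, True, True),
    ]
    for i, combo in enumerate(combos, start=1):
        cfg = ablation_variant(combo, scale=scale, input_size=input_size)
        model = build_model(cfg)
        row = {
            "test": i,
            "rcsosa": int(combo[0]), "seam": int(combo[1]),
            "irmb": int(combo[2]), "adown": int(combo[3]),
            "params_m": round(count_parameters(model) / 1e6, 3),
        }
        if count_flops_at:
            row["gflops"] = round(count_flops(model, count_flops_at) / 1e9, 2)
        rows.append(row)
    if out_csv:
        with open(out_csv, "w", newline="") as fh:
            w = csv.DictWriter(fh, fieldnames=list(rows[0].keys()))
            w.writeheader()
            w.writerows(rows)
    return rows
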