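"""Synthetic nadir UAV field scenes with exact weed ground truth.

The generator emulates the acquisition conditions of a low-altitude (12 m)
nadir RGB survey of a seedling-stage row crop: textured brown soil, regular
rows of crop seedlings (unlabeled background class), scattered weed blobs of
irregular shape and varied size (the labeled foreground), multiplicative
illumination gradients and soft shadows.  It is statistically structured —
green-dominant blobs on brown soil with row-organized distractors — but not
photorealistic; see docs/methods.md for what that implies.

The dataset-construction pipeline mirrors field practice: sliding-window
tiling (default 480 px, non-overlapping), removal of tiles without weed
pixels, joint geometric/photometric augmentation of training tiles, and a
spatially isolated train/val/test split in which whole scene regions are
assigned to a single split.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field, replace
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.draw import polygon as draw_polygon

from .georef import CameraIntrinsics, UavPose

__all__ = [
    "FieldParams",
    "WeedInstance",
    "FieldScene",
    "Tile",
    "generate_field",
    "tile_scene",
    "filter_negative_tiles",
    "augment",
    "split_spatial",
    "write_tiles",
]


@dataclass
class FieldParams:
    """Generator parameters; defaults emulate the study acquisition."""

    width_px: int = 5280
    height_px: int = 3956
    weed_density: float = 2.0        # weeds per m² of imaged ground
    weed_radius_px: tuple = (6, 18)  # base radius range
    row_spacing_px: int = 140        # crop row pitch (~45 cm at 3.2 mm/px)
    plant_spacing_px: int = 55
    crop_radius_px: tuple = (8, 15)
    illumination: float = 0.12       # multiplicative gradient amplitude
    shadow_strength: float = 0.25
    n_shadows: int = 4
    soil_noise: float = 6.0          # soil texture sigma, uint8 units
    altitude_m: float = 12.0
    focal_px: float = 3700.0         # ~3.3 µm pitch, 12.3 mm lens
    lat: float = 48.78               # WGS-84 scene anchor
    lon: float = 125.41
    yaw: float = 0.0
    pitch: float = 0.0
    roll: float = 0.0

    @property
    def gsd_m(self) -> float:
        """Ground sample distance (m per pixel) at nadir."""
        return self.altitude_m / self.focal_px

    @property
    def area_m2(self) -> float:
        return self.width_px * self.height_px * self.gsd_m**2


@dataclass
class WeedInstance:
    instance_id: int
    centroid_px: tuple  # (x, y)
    bbox: tuple         # (x1, y1, x2, y2) half-open
    area_px: int


@dataclass
class FieldScene:
    image: np.ndarray       # (H, W, 3) uint8
    label_map: np.ndarray   # (H, W) int32, 0 = background
    instances: list
    crop_centers: list      # (x, y) of unlabeled crop plants
    params: FieldParams
    pose: UavPose
    intrinsics: CameraIntrinsics
    scene_id: int = 0


@dataclass
class Tile:
    image: np.ndarray
    label_map: np.ndarray
    origin: tuple           # (row_px, col_px) in the scene
    scene_id: int
    region_id: str = ""
    split: str | None = None
    augmented: bool = False

    @property
    def instance_ids(self) -> list[int]:
        ids = np.unique(self.label_map)
        return [int(i) for i in ids if i != 0]

    def instance_mask(self, iid: int) -> np.ndarray:
        return self.label_map == iid


def _blob_polygon(rng, cx, cy, radius, n_verts=24, irregularity=0.35):
    """Irregular star-shaped polygon around (cx, cy)."""
    theta = np.linspace(0, 2 * np.pi, n_verts, endpoint=False)
    harmonics = (
        1.0
        + irregularity * rng.uniform(0.3, 1.0) * np.sin(2 * theta + rng.uniform(0, 2 * np.pi))
        + irregularity * rng.uniform(0.2, 0.8) * np.sin(3 * theta + rng.uniform(0, 2 * np.pi))
        + 0.5 * irregularity * rng.uniform(0, 1) * np.sin(5 * theta + rng.uniform(0, 2 * np.pi))
    )
    r = np.maximum(radius * harmonics, 1.5)
    return cx + r * np.cos(theta), cy + r * np.sin(theta)


def _paint_blob(image, rng, xs, ys, color, jitter=12.0, alpha=0.9):
    rr, cc = draw_polygon(ys, xs, shape=image.shape[:2])
    if len(rr) == 0:
        return rr, cc
    tint = np.clip(np.asarray(color, float) + rng.normal(0, jitter, 3), 0, 255)
    image[rr, cc] = (1 - alpha) * image[rr, cc] + alpha * tint
    return rr, cc


def generate_field(params: FieldParams | None = None, seed: int = 0) -> FieldScene:
    """Render one scene with exact per-pixel weed ground truth.

    The weed count is Poisson with mean density × imaged area; placement is
    uniform.  Same seed → bit-identical scene.
    """
    params = params or FieldParams()
    H, W = params.height_px, params.width_px
    if H <= 0 or W <= 0:
        raise ValueError("scene dimensions must be positive")
    rng = np.random.default_rng(seed)

    # soil: brown base + two scales of texture noise
    base = np.array([118.0, 91.0, 64.0])
    img = np.ones((H, W, 3)) * base
    coarse = gaussian_filter(rng.normal(0, 1, (H, W)), 18) * 40
    fine = rng.normal(0, params.soil_noise, (H, W))
    img += (coarse + fine)[..., None] * np.array([1.0, 0.9, 0.75])

    # crop rows: regularly spaced seedlings (unlabeled)
    crop_centers = []
    x = rng.uniform(0, params.row_spacing_px)
    while x < W:
        y = rng.uniform(0, params.plant_spacing_px)
        while y < H:
            cy = y + rng.normal(0, 3)
            cxx = x + rng.normal(0, 4)
            radius = rng.uniform(*params.crop_radius_px)
            xs, ys = _blob_polygon(rng, cxx, cy, radius, irregularity=0.25)
            _paint_blob(img, rng, xs, ys, (52, 132, 70), alpha=0.95)
            crop_centers.append((cxx, cy))
            y += params.plant_spacing_px * rng.uniform(0.8, 1.2)
        x += params.row_spacing_px * rng.uniform(0.95, 1.05)

    # weeds: Poisson count, uniform placement, distinct yellow-green tint
    label_map = np.zeros((H, W), np.int32)
    n_weeds = rng.poisson(params.weed_density * params.area_m2)
    instances = []
    iid = 0
    for _ in range(n_weeds):
        cx = rng.uniform(0, W)
        cy = rng.uniform(0, H)
        radius = rng.uniform(*params.weed_radius_px)
        xs, ys = _blob_polygon(rng, cx, cy, radius)
        rr, cc = _paint_blob(img, rng, xs, ys, (96, 168, 58), alpha=0.95)
        if len(rr) == 0:
            continue
        iid += 1
        label_map[rr, cc] = iid
        instances.append(iid)

    # illumination gradient + soft elliptical shadows (image only)
    gx = np.linspace(-1, 1, W)[None, :]
    gy = np.linspace(-1, 1, H)[:, None]
    ang = rng.uniform(0, 2 * np.pi)
    grad = 1.0 + params.illumination * (np.cos(ang) * gx + np.sin(ang) * gy)
    img *= grad[..., None]
    for _ in range(params.n_shadows):
        scx, scy = rng.uniform(0, W), rng.uniform(0, H)
        sa, sb = rng.uniform(0.08, 0.25, 2) * np.array([W, H])
        yy, xx = np.ogrid[:H, :W]
        dist = ((xx - scx) / sa) ** 2 + ((yy - scy) / sb) ** 2
        shade = 1.0 - params.shadow_strength * np.exp(-dist)
        img *= shade[..., None]

    image = np.clip(img, 0, 255).astype(np.uint8)

    # rebuild instance records from the final label map (overlaps overwrite)
    final_instances = []
    for i in instances:
        ys_, xs_ = np.nonzero(label_map == i)
        if len(xs_) == 0:
            continue
        final_instances.append(
            WeedInstance(
                instance_id=i,
                centroid_px=(float(xs_.mean()) + 0.5, float(ys_.mean()) + 0.5),
                bbox=(int(xs_.min()), int(ys_.min()), int(xs_.max()) + 1, int(ys_.max()) + 1),
                area_px=len(xs_),
            )
        )

    pose = UavPose(lat=params.lat, lon=params.lon, alt_agl=params.altitude_m,
                   yaw=params.yaw, pitch=params.pitch, roll=params.roll)
    K = CameraIntrinsics.nadir_default(W, H, params.focal_px)
    return FieldScene(image=image, label_map=label_map, instances=final_instances,
                      crop_centers=crop_centers, params=params, pose=pose,
                      intrinsics=K, scene_id=seed)


def tile_scene(scene: FieldScene, size: int = 480, stride: int | None = None,
               region_block: int = 2) -> list[Tile]:
    """Sliding-window tiles; default stride = size (non-overlapping grid).

    ``region_block`` groups a block of ``region_block``×``region_block``
    tiles into one spatial region for the isolated split.
    """
    stride = stride or size
    H, W = scene.label_map.shape
    if size > H or size > W:
        raise ValueError("tile size exceeds scene dimensions")
    tiles = []
    for ty, r0 in enumerate(range(0, H - size + 1, stride)):
        for tx, c0 in enumerate(range(0, W - size + 1, stride)):
            region = f"s{scene.scene_id}:{ty // region_block}-{tx // region_block}"
            tiles.append(Tile(
                image=scene.image[r0 : r0 + size, c0 : c0 + size].copy(),
                label_map=scene.label_map[r0 : r0 + size, c0 : c0 + size].copy(),
                origin=(r0, c0),
                scene_id=scene.scene_id,
                region_id=region,
            ))
    return tiles


def filter_negative_tiles(tiles: list[Tile]) -> list[Tile]:
    """Keep only tiles containing at least one weed pixel."""
    return [t for t in tiles if np.any(t.label_map)]


def split_spatial(tiles: list[Tile], ratios=(8, 1, 1), seed: int = 0) -> dict:
    """Assign whole regions to train/val/test, targeting the tile ratios.

    Regions never span two splits.  Returns {'train': [...], 'val': [...],
    'test': [...]} and sets ``tile.split`` in place.
    """
    regions: dict[str, list[Tile]] = {}
    for t in tiles:
        regions.setdefault(t.region_id, []).append(t)
    if len(regions) < 3:
        raise ValueError(f"need at least 3 spatial regions, got {len(regions)}")
    rng = np.random.default_rng(seed)
    names = sorted(regions)
    rng.shuffle(names)
    total = len(tiles)
    frac = np.array(ratios, float) / np.sum(ratios)
    targets = frac * total
    splits = {"train": [], "val": [], "test": []}
    order = ("train", "val", "test")
    counts = dict.fromkeys(order, 0)
    # largest-deficit-first greedy keeps achieved ratios close to targets
    for name in names:
        deficits = {s: targets[i] - counts[s] for i, s in enumerate(order)}
        best = max(order, key=lambda s: deficits[s])
        for t in regions[name]:
            t.split = best
        splits[best].extend(regions[name])
        counts[best] += len(regions[name])
    for s in order:
        if not splits[s]:
            # force at least one region into an empty split (tiny inputs)
            donor = max(order, key=lambda q: counts[q])
            name = next(n for n in names if regions[n][0].split == donor)
            for t in regions[name]:
                t.split = s
            splits[s] = regions[name]
            splits[donor] = [t for t in splits[donor] if t.region_id != name]
            counts[donor] -= len(regions[name])
            counts[s] += len(regions[name])
    return splits


def _augment_one(tile: Tile, rng: np.random.Generator) -> Tile:
    img = tile.image.astype(np.float32)
    lab = tile.label_map
    k = int(rng.integers(0, 4))  # right-angle rotation keeps masks exact
    if k:
        img = np.rot90(img, k, axes=(0, 1))
        lab = np.rot90(lab, k, axes=(0, 1))
    if rng.random() < 0.5:
        img = img[:, ::-1]
        lab = lab[:, ::-1]
    if rng.random() < 0.5:
        img = img[::-1]
        lab = lab[::-1]
    gains = rng.uniform(0.8, 1.2, 3)
    shift = rng.uniform(-15, 15)
    img = img * gains + shift
    img = img + rng.normal(0, rng.uniform(2, 8), img.shape)
    return Tile(
        image=np.clip(img, 0, 255).astype(np.uint8),
        label_map=np.ascontiguousarray(lab),
        origin=tile.origin,
        scene_id=tile.scene_id,
        region_id=tile.region_id,
        split=tile.split,
        augmented=True,
    )


def augment(tiles: list[Tile], multiplicity: int = 4, seed: int = 0) -> list[Tile]:
    """Originals plus ``multiplicity`` jointly-augmented variants each.

    Only training tiles may be augmented; geometric transforms are applied
    identically to image and label map.
    """
    for t in tiles:
        if t.split not in (None, "train"):
            raise ValueError("augmentation is restricted to training tiles")
    rng = np.random.default_rng(seed)
    out = list(tiles)
    for t in tiles:
        for _ in range(multiplicity):
            out.append(_augment_one(t, rng))
    return out


def write_tiles(tiles: list[Tile], out_dir, fmt: str = "labelme",
                scene: FieldScene | None = None) -> list[dict]:
    """Write tile PNGs + labels + a metadata table; returns the records."""
    import csv

    import imageio.v3 as iio

    from .labels import write_labelme, write_yoloseg

    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "labels").mkdir(parents=True, exist_ok=True)
    records = []
    for i, t in enumerate(tiles):
        stem = f"tile_{i:05d}"
        img_path = out_dir / "images" / f"{stem}.png"
        iio.imwrite(img_path, t.image)
        if np.any(t.label_map):
            if fmt == "labelme":
                write_labelme(out_dir / "labels" / f"{stem}.json", t.label_map,
                              image_path=f"../images/{stem}.png")
            elif fmt == "yoloseg":
                write_yoloseg(out_dir / "labels" / f"{stem}.txt", t.label_map)
            else:
                raise ValueError(f"unsupported label format {fmt!r}")
        rec = {
            "tile": stem, "scene_id": t.scene_id, "row_px": t.origin[0],
            "col_px": t.origin[1], "region_id": t.region_id,
            "split": t.split or "", "augmented": int(t.augmented),
        }
        if scene is not None:
            rec.update({"lat": scene.pose.lat, "lon": scene.pose.lon,
                        "alt_agl": scene.pose.alt_agl, "yaw": scene.pose.yaw})
        records.append(rec)
    with open(out_dir / "tiles.csv", "w", newline="") as fh:
        w = csv.DictWriter(fh, fieldnames=list(records[0].keys()))
        w.writeheader()
        w.writerows(records)
    return records
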