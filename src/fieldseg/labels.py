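"""Polygon label IO: LabelMe JSON and YOLO-seg text formats.

Instance masks are converted to polygons by tracing exact pixel boundaries
(union of unit pixel squares), so a write/read round trip reproduces the
mask pixel-for-pixel apart from dropped interior holes, which the polygon
formats cannot express.  Multi-part instances (e.g. split by a tile edge)
are written as one shape per part sharing a ``group_id``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import shapely
from shapely.geometry import MultiPolygon, Polygon

__all__ = [
    "mask_to_polygons",
    "polygons_to_mask",
    "write_labelme",
    "read_labelme",
    "write_yoloseg",
    "read_yoloseg",
]


def mask_to_polygons(mask: np.ndarray) -> list[Polygon]:
    """Exact pixel-boundary polygons (exteriors) of a binary mask.

    Vertices lie on the integer pixel grid in (x, y) image coordinates, so
    pixel centres at half-integer coordinates are strictly inside/outside.
    """
    ys, xs = np.nonzero(np.asarray(mask, bool))
    if len(xs) == 0:
        return []
    boxes = shapely.box(xs, ys, xs + 1.0, ys + 1.0)
    merged = shapely.union_all(boxes)
    if isinstance(merged, Polygon):
        parts = [merged]
    elif isinstance(merged, MultiPolygon):
        parts = list(merged.geoms)
    else:  # pragma: no cover - union of boxes is always polygonal
        parts = [g for g in merged.geoms if isinstance(g, Polygon)]
    return [Polygon(p.exterior) for p in parts]


def polygons_to_mask(polygons, shape) -> np.ndarray:
    """Rasterize polygons: a pixel is set when its centre falls inside."""
    h, w = shape
    mask = np.zeros((h, w), bool)
    for poly in polygons:
        minx, miny, maxx, maxy = poly.bounds
        x0, x1 = max(0, int(np.floor(minx))), min(w, int(np.ceil(maxx)))
        y0, y1 = max(0, int(np.floor(miny))), min(h, int(np.ceil(maxy)))
        if x1 <= x0 or y1 <= y0:
            continue
        xc, yc = np.meshgrid(np.arange(x0, x1) + 0.5, np.arange(y0, y1) + 0.5)
        inside = shapely.contains_xy(poly, xc.ravel(), yc.ravel()).reshape(yc.shape)
        mask[y0:y1, x0:x1] |= inside
    return mask


def _instance_polygons(label_map: np.ndarray) -> dict[int, list[Polygon]]:
    out = {}
    for iid in np.unique(label_map):
        if iid == 0:
            continue
        out[int(iid)] = mask_to_polygons(label_map == iid)
    return out


def write_labelme(path, label_map: np.ndarray, image_path: str = "",
                  label: str = "weed") -> Path:
    """Write a LabelMe-style JSON for one tile's instance label map."""
    if not np.any(label_map):
        raise ValueError("refusing to write labels for an empty tile "
                         "(negatives are filtered upstream)")
    h, w = label_map.shape
    shapes = []
    for iid, polys in _instance_polygons(label_map).items():
        for poly in polys:
            pts = [[float(x), float(y)] for x, y in np.asarray(poly.exterior.coords)[:-1]]
            if len(pts) < 3:
                continue
            shapes.append({
                "label": label,
                "points": pts,
                "group_id": iid,
                "shape_type": "polygon",
                "flags": {},
            })
    doc = {
        "version": "5.0.0",
        "flags": {},
        "shapes": shapes,
        "imagePath": image_path,
        "imageData": None,
        "imageHeight": h,
        "imageWidth": w,
    }
    path = Path(path)
    path.write_text(json.dumps(doc))
    return path


def read_labelme(path, shape=None) -> dict[int, np.ndarray]:
    """Read a LabelMe JSON back into per-instance masks keyed by group id."""
    doc = json.loads(Path(path).read_text())
    h = doc["imageHeight"] if shape is None else shape[0]
    w = doc["imageWidth"] if shape is None else shape[1]
    groups: dict[int, list[Polygon]] = {}
    for i, s in enumerate(doc["shapes"]):
        gid = s.get("group_id")
        gid = int(gid) if gid is not None else -(i + 1)
        groups.setdefault(gid, []).append(Polygon(s["points"]))
    return {gid: polygons_to_mask(polys, (h, w)) for gid, polys in groups.items()}


def write_yoloseg(path, label_map: np.ndarray, class_id: int = 0,
                  precision: int = 6) -> Path:
    """Write YOLO-seg polygon labels (class x1 y1 x2 y2 ..., normalized)."""
    if not np.any(label_map):
        raise ValueError("refusing to write labels for an empty tile "
                         "(negatives are filtered upstream)")
    h, w = label_map.shape
    lines = []
    for _iid, polys in _instance_polygons(label_map).items():
        for poly in polys:
            coords = np.asarray(poly.exterior.coords)[:-1]
            if len(coords) < 3:
                continue
            norm = coords / [w, h]
            flat = " ".join(f"{v:.{precision}f}" for v in norm.ravel())
            lines.append(f"{class_id} {flat}")
    path = Path(path)
    path.write_text("\n".join(lines) + "\n")
    return path


def read_yoloseg(path, shape) -> list[np.ndarray]:
    """Read YOLO-seg labels into one mask per polygon line."""
    h, w = shape
    masks = []
    for line in Path(path).read_text().splitlines():
        parts = line.split()
        if len(parts) < 7:
            continue
        xy = np.array(parts[1:], float).reshape(-1, 2) * [w, h]
        masks.append(polygons_to_mask([Polygon(xy)], shape))
    return masks
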