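"""Grid-based weed density classification and variable-rate prescription maps.

The field is partitioned into axis-aligned cells at the sprayer working
width (12 m).  Georeferenced weed points are counted per cell with a
left/top-inclusive boundary rule, classified into five density tiers —
either by the fixed agronomic thresholds (1–24, 25–48, 49–72, 73–96, ≥97
weeds per cell) or by exact Fisher-Jenks natural breaks recomputed from the
data — and each tier is mapped to an application rate: baseline 120 L/hm²
for the densest tier, stepping down 5 % of baseline per tier to 96 L/hm²
for the sparsest.  Cells without weeds receive tier 0 / rate 0 (no spray).
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from shapely.geometry import Polygon, box as shapely_box

__all__ = [
    "GridCell",
    "RateRule",
    "FIXED_TIER_BOUNDS",
    "make_grid",
    "count_points",
    "classify_fixed",
    "jenks_breaks",
    "classify_jenks",
    "assign_rate",
    "export_map",
]

# tier t covers counts in [FIXED_TIER_BOUNDS[t-1], FIXED_TIER_BOUNDS[t]) for
# t = 1..5, with the last tier open-ended (>= 97)
FIXED_TIER_BOUNDS = (1, 25, 49, 73, 97)


@dataclass
class RateRule:
    """Tier → application-rate rule (L/hm²).

    rate(t) = baseline − baseline·decrement_fraction·(n_tiers − t) for
    t in 1..n_tiers; rate(0) = 0 (no spray).
    """

    baseline: float = 120.0
    decrement_fraction: float = 0.05
    n_tiers: int = 5

    def rate(self, tier: int) -> float:
        if not 0 <= tier <= self.n_tiers:
            raise ValueError(f"tier {tier} out of range 0..{self.n_tiers}")
        if tier == 0:
            return 0.0
        return self.baseline * (1.0 - self.decrement_fraction * (self.n_tiers - tier))


@dataclass
class GridCell:
    row: int
    col: int
    x0: float  # projected metres, lower-left corner
    y0: float
    size: float
    partial: bool = False  # intersects the field boundary
    weed_count: int = 0
    tier: int = 0
    rate: float = 0.0

    @property
    def polygon(self) -> Polygon:
        return shapely_box(self.x0, self.y0, self.x0 + self.size, self.y0 + self.size)


def make_grid(field_polygon: Polygon, cell: float = 12.0) -> list[GridCell]:
    """Axis-aligned ``cell``-metre grid covering the field polygon.

    Cells whose square does not intersect the field are dropped; cells
    crossing the boundary are flagged ``partial``.
    """
    if field_polygon.is_empty or field_polygon.area <= 0:
        raise ValueError("degenerate field polygon")
    minx, miny, maxx, maxy = field_polygon.bounds
    col0 = int(np.floor(minx / cell))
    row0 = int(np.floor(miny / cell))
    cols = int(np.ceil(maxx / cell)) - col0
    rows = int(np.ceil(maxy / cell)) - row0
    cells = []
    for r in range(rows):
        for c in range(cols):
            x0 = (col0 + c) * cell
            y0 = (row0 + r) * cell
            sq = shapely_box(x0, y0, x0 + cell, y0 + cell)
            if not sq.intersects(field_polygon):
                continue
            partial = not field_polygon.contains(sq)
            cells.append(GridCell(row=r, col=c, x0=x0, y0=y0, size=cell, partial=partial))
    return cells


def count_points(cells: list[GridCell], points: np.ndarray) -> int:
    """Assign projected points (N, 2 easting/northing) to cells.

    Boundary rule: a point on a shared edge belongs to the cell whose
    left/bottom edge it lies on (floor indexing), so every point lands in
    exactly one cell.  Returns the number of points outside all cells.
    """
    points = np.asarray(points, float).reshape(-1, 2)
    index = {(c.row, c.col): c for c in cells}
    for c in cells:
        c.weed_count = 0
    if len(cells) == 0:
        return len(points)
    size = cells[0].size
    col0 = round(min(c.x0 - c.col * size for c in cells) / size)
    row0 = round(min(c.y0 - c.row * size for c in cells) / size)
    outside = 0
    for x, y in points:
        col = int(np.floor(x / size)) - col0
        row = int(np.floor(y / size)) - row0
        cell = index.get((row, col))
        if cell is None:
            outside += 1
        else:
            cell.weed_count += 1
    return outside


def classify_fixed(count: int) -> int:
    """Density tier from the fixed thresholds; tier 0 for empty cells."""
    if count < 0:
        raise ValueError("negative weed count")
    if count == 0:
        return 0
    for tier in range(len(FIXED_TIER_BOUNDS), 1, -1):
        if count >= FIXED_TIER_BOUNDS[tier - 1]:
            return tier
    return 1


def jenks_breaks(values, k: int) -> list[float]:
    """Exact Fisher-Jenks natural breaks by dynamic programming.

    Partitions the sorted values into ``k`` classes minimizing the total
    within-class sum of squared deviations; returns the k−1 break values
    (lower bound of each class after the first, by convention the first
    value of the class).  Ties break toward earlier positions.
    """
    vals = np.sort(np.asarray(list(values), float))
    n = len(vals)
    if k < 1 or k > n:
        raise ValueError(f"need 1 <= k <= n, got k={k}, n={n}")
    # prefix sums for O(1) within-class SSE
    cs = np.concatenate([[0.0], np.cumsum(vals)])
    cs2 = np.concatenate([[0.0], np.cumsum(vals**2)])

    def sse(i: int, j: int) -> float:  # class = vals[i:j]
        m = j - i
        s = cs[j] - cs[i]
        return (cs2[j] - cs2[i]) - s * s / m

    INF = np.inf
    cost = np.full((k + 1, n + 1), INF)
    split = np.zeros((k + 1, n + 1), int)
    cost[0, 0] = 0.0
    for cls in range(1, k + 1):
        for j in range(cls, n + 1):
            best, arg = INF, cls - 1
            for i in range(cls - 1, j):
                c = cost[cls - 1, i] + sse(i, j)
                if c < best - 1e-12:  # strict improvement → earliest split kept on ties
                    best, arg = c, i
            cost[cls, j] = best
            split[cls, j] = arg
    # backtrack
    bounds = []
    j = n
    for cls in range(k, 0, -1):
        i = split[cls, j]
        bounds.append(i)
        j = i
    bounds = sorted(bounds)[1:]  # drop the leading 0
    return [float(vals[b]) for b in bounds]


def classify_jenks(counts, k: int = 5) -> list[int]:
    """Tier per count using Jenks breaks recomputed from the non-zero counts."""
    counts = list(counts)
    nonzero = [c for c in counts if c > 0]
    if len(nonzero) < k:
        raise ValueError(f"need at least {k} non-empty cells for {k} Jenks tiers")
    breaks = jenks_breaks(nonzero, k)
    tiers = []
    for c in counts:
        if c == 0:
            tiers.append(0)
        else:
            tiers.append(1 + sum(c >= b for b in breaks))
    return tiers


def assign_rate(tier: int, rule: RateRule | None = None) -> float:
    """Application rate (L/hm²) for a density tier."""
    return (rule or RateRule()).rate(tier)


def classify_cells(cells: list[GridCell], method: str = "fixed",
                   rule: RateRule | None = None) -> None:
    """Set tier and rate on every cell in place."""
    rule = rule or RateRule()
    if method == "fixed":
        for c in cells:
            c.tier = classify_fixed(c.weed_count)
    elif method == "jenks":
        tiers = classify_jenks([c.weed_count for c in cells], rule.n_tiers)
        for c, t in zip(cells, tiers):
            c.tier = t
    else:
        raise ValueError(f"unknown classification method {method!r}")
    for c in cells:
        c.rate = rule.rate(c.tier)


def export_map(cells: list[GridCell], path, fmt: str = "geojson",
               to_geodetic=None) -> Path:
    """Write the prescription map.

    ``geojson`` — cell polygons with count/tier/rate properties (WGS-84 when
    a projected→geodetic converter is given, else projected coordinates);
    ``csv`` — tabular; ``geotiff`` — single-band rate raster via tifffile
    with pixel-scale/tiepoint tags; ``asc`` — ESRI ASCII grid.
    """
    path = Path(path)
    if fmt == "geojson":
        feats = []
        for c in cells:
            ring = [
                (c.x0, c.y0), (c.x0 + c.size, c.y0),
                (c.x0 + c.size, c.y0 + c.size), (c.x0, c.y0 + c.size),
                (c.x0, c.y0),
            ]
            if to_geodetic is not None:
                ring = [to_geodetic(x, y) for x, y in ring]
            feats.append({
                "type": "Feature",
                "geometry": {"type": "Polygon", "coordinates": [[list(p) for p in ring]]},
                "properties": {
                    "row": c.row, "col": c.col, "weed_count": c.weed_count,
                    "tier": c.tier, "rate_l_per_hm2": c.rate, "partial": c.partial,
                },
            })
        path.write_text(json.dumps({"type": "FeatureCollection", "features": feats}, indent=1))
    elif fmt == "csv":
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["row", "col", "x0", "y0", "size", "weed_count", "tier", "rate_l_per_hm2", "partial"])
            for c in cells:
                w.writerow([c.row, c.col, c.x0, c.y0, c.size, c.weed_count, c.tier, c.rate, int(c.partial)])
    elif fmt in ("geotiff", "asc"):
        raster, x0, y0, size = _rasterize(cells)
        if fmt == "asc":
            header = (
                f"ncols {raster.shape[1]}\nnrows {raster.shape[0]}\n"
                f"xllcorner {x0}\nyllcorner {y0}\ncellsize {size}\nNODATA_value -1\n"
            )
            body = "\n".join(" ".join(f"{v:g}" for v in row) for row in raster)
            path.write_text(header + body + "\n")
        else:
            import tifffile

            top = y0 + raster.shape[0] * size
            tifffile.imwrite(
                path,
                raster.astype(np.float32),
                extratags=[
                    (33550, "d", 3, (size, size, 0.0)),           # ModelPixelScale
                    (33922, "d", 6, (0.0, 0.0, 0.0, x0, top, 0.0)),  # ModelTiepoint
                ],
            )
    else:
        raise ValueError(f"unsupported export format {fmt!r}")
    return path


def _rasterize(cells: list[GridCell]):
    if not cells:
        raise ValueError("no cells to rasterize")
    size = cells[0].size
    rows = max(c.row for c in cells) + 1
    cols = max(c.col for c in cells) + 1
    raster = np.full((rows, cols), -1.0)
    x0 = min(c.x0 - c.col * size for c in cells)
    y0 = min(c.y0 - c.row * size for c in cells)
    for c in cells:
        # raster row 0 is the northernmost row
        raster[rows - 1 - c.row, c.col] = c.rate
    return raster, x0, y0, size


def read_map_geojson(path) -> list[dict]:
    """Read back an exported GeoJSON prescription map's properties."""
    d = json.loads(Path(path).read_text())
    return [f["properties"] for f in d["features"]]
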