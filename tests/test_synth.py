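"""Synthetic-field generator and dataset pipeline: determinism, Poisson
placement statistics, tiling arithmetic and conservation, negative-tile
filtering, joint augmentation, spatially isolated splitting, and label
round trips."""

import numpy as np
import pytest

from fieldseg.labels import (
    mask_to_polygons,
    polygons_to_mask,
    read_labelme,
    read_yoloseg,
    write_labelme,
    write_yoloseg,
)
from fieldseg.synth import (
    FieldParams,
    FieldScene,
    augment,
    filter_negative_tiles,
    generate_field,
    split_spatial,
    tile_scene,
)


class TestGenerate:
    def test_same_seed_bit_identical(self):
        p = FieldParams(width_px=400, height_px=300)
        a = generate_field(p, seed=11)
        b = generate_field(p, seed=11)
        assert np.array_equal(a.image, b.image)
        assert np.array_equal(a.label_map, b.label_map)

    def test_zero_density_zero_instances(self):
        sc = generate_field(FieldParams(width_px=300, height_px=300, weed_density=0.0), seed=1)
        assert sc.instances == []
        assert not sc.label_map.any()

    def test_zero_area_raises(self):
        with pytest.raises(ValueError):
            generate_field(FieldParams(width_px=0, height_px=100), seed=0)

    def test_instance_count_within_poisson_band(self):
        """Over 20 seeds the mean planted count must sit within 3σ of the
        Poisson expectation λ = density × area."""
        p = FieldParams(width_px=500, height_px=500, weed_density=4.0)
        lam = p.weed_density * p.area_m2
        counts = [len(generate_field(p, seed=s).instances) for s in range(20)]
        se = np.sqrt(lam / len(counts))
        assert abs(np.mean(counts) - lam) < 3 * se + 1  # +1: rare blob erasure

    def test_ground_truth_exact_by_construction(self, small_scene):
        for inst in small_scene.instances[:10]:
            mask = small_scene.label_map == inst.instance_id
            assert mask.sum() == inst.area_px
            ys, xs = np.nonzero(mask)
            assert inst.bbox == (xs.min(), ys.min(), xs.max() + 1, ys.max() + 1)


class TestTiling:
    def test_source_frame_tile_count(self):
        # 5280×3956 at 480/480 → 11 × 8 = 88 tiles (floor arithmetic);
        # geometry only, so an empty scene of the source dimensions suffices
        scene = _blank_scene(5280, 3956)
        assert len(tile_scene(scene, 480, 480)) == 88

    def test_mask_conservation_over_tiles(self, small_scene):
        tiles = tile_scene(small_scene, 480, 480)
        total = sum((t.label_map > 0).sum() for t in tiles)
        H = (small_scene.label_map.shape[0] // 480) * 480
        W = (small_scene.label_map.shape[1] // 480) * 480
        assert total == (small_scene.label_map[:H, :W] > 0).sum()

    def test_half_stride_matches_window_enumeration(self, small_scene):
        tiles = tile_scene(small_scene, 480, 240)
        H, W = small_scene.label_map.shape
        expected = [(r, c) for r in range(0, H - 480 + 1, 240)
                    for c in range(0, W - 480 + 1, 240)]
        assert [t.origin for t in tiles] == expected

    def test_tile_too_large_raises(self, small_scene):
        with pytest.raises(ValueError):
            tile_scene(small_scene, 5000)


class TestFiltering:
    def test_all_background_scene_empty_output(self):
        scene = generate_field(FieldParams(width_px=300, height_px=300, weed_density=0.0), seed=2)
        assert filter_negative_tiles(tile_scene(scene, 100, 100)) == []

    def test_every_retained_tile_has_weed_pixels(self, small_scene):
        for t in filter_negative_tiles(tile_scene(small_scene, 96, 96)):
            assert (t.label_map > 0).sum() >= 1

    def test_matches_per_tile_pixel_scan(self, small_scene):
        # oracle: scan the scene label map directly at each tile origin
        tiles = tile_scene(small_scene, 96, 96)
        kept = filter_negative_tiles(tiles)
        brute = [
            t.origin for t in tiles
            if small_scene.label_map[t.origin[0] : t.origin[0] + 96,
                                     t.origin[1] : t.origin[1] + 96].any()
        ]
        assert [t.origin for t in kept] == brute


class TestAugment:
    def test_multiplicity_count(self, small_tiles):
        tiles = small_tiles[:6]
        out = augment(tiles, multiplicity=4, seed=0)
        assert len(out) == 5 * len(tiles)
        assert sum(t.augmented for t in out) == 4 * len(tiles)

    def test_flip_twice_identity_rotation_conserves_mask(self, small_tiles):
        lab = small_tiles[0].label_map
        assert np.array_equal(lab[:, ::-1][:, ::-1], lab)
        for k in range(4):
            assert np.rot90(lab, k).sum() == lab.sum()

    def test_geometric_ops_applied_jointly(self, small_tiles):
        out = augment(small_tiles[:3], multiplicity=2, seed=5)
        for t in out:
            # weed pixels must remain green-dominant after augmentation,
            # i.e. image and mask were transformed together
            m = t.label_map > 0
            if m.sum() < 10:
                continue
            weed_rgb = t.image[m].mean(axis=0)
            soil_rgb = t.image[~m].mean(axis=0)
            assert weed_rgb[1] - weed_rgb[2] > soil_rgb[1] - soil_rgb[2]

    def test_refuses_val_tiles(self, small_tiles):
        t = small_tiles[0]
        t2 = type(t)(image=t.image, label_map=t.label_map, origin=t.origin,
                     scene_id=t.scene_id, region_id=t.region_id, split="val")
        with pytest.raises(ValueError):
            augment([t2], 2)

    def test_deterministic(self, small_tiles):
        a = augment(small_tiles[:4], 2, seed=9)
        b = augment(small_tiles[:4], 2, seed=9)
        for x, y in zip(a, b):
            assert np.array_equal(x.image, y.image)


class TestSplit:
    def test_regions_never_span_splits(self, small_tiles):
        split_spatial(small_tiles, seed=3)
        by_region = {}
        for t in small_tiles:
            by_region.setdefault(t.region_id, set()).add(t.split)
        for splits in by_region.values():
            assert len(splits) == 1

    def test_region_rectangles_disjoint_across_splits(self, small_tiles):
        """Geometric isolation: tile rectangles from different splits never
        overlap (non-overlapping grid + whole-region assignment)."""
        split_spatial(small_tiles, seed=3)
        for a in small_tiles:
            for b in small_tiles:
                if a.split == b.split:
                    continue
                ar = (a.origin[0], a.origin[1], a.origin[0] + 96, a.origin[1] + 96)
                br = (b.origin[0], b.origin[1], b.origin[0] + 96, b.origin[1] + 96)
                overlap = (min(ar[2], br[2]) > max(ar[0], br[0])
                           and min(ar[3], br[3]) > max(ar[1], br[1]))
                assert not overlap

    def test_ratios_near_8_1_1(self, small_tiles):
        splits = split_spatial(small_tiles, seed=3)
        n = len(small_tiles)
        assert len(splits["train"]) / n > 0.6
        assert splits["val"] and splits["test"]

    def test_fewer_than_three_regions_raises(self, small_tiles):
        clones = [type(t)(image=t.image, label_map=t.label_map, origin=t.origin,
                          scene_id=0, region_id="only") for t in small_tiles[:4]]
        with pytest.raises(ValueError):
            split_spatial(clones)

    def test_fixed_seed_identical_assignment(self, small_tiles):
        a = {t.region_id: None for t in small_tiles}
        split_spatial(small_tiles, seed=5)
        first = [(t.region_id, t.split) for t in small_tiles]
        split_spatial(small_tiles, seed=5)
        assert [(t.region_id, t.split) for t in small_tiles] == first


class TestLabels:
    def test_labelme_round_trip_iou(self, small_tiles, tmp_path):
        wrote = 0
        for i, t in enumerate(small_tiles[:8]):
            p = write_labelme(tmp_path / f"{i}.json", t.label_map)
            back = read_labelme(p)
            for gid, mask in back.items():
                orig = t.label_map == gid
                iou = (orig & mask).sum() / (orig | mask).sum()
                assert iou >= 0.99
                wrote += 1
        assert wrote > 0

    def test_yoloseg_round_trip_iou(self, small_tiles, tmp_path):
        t = small_tiles[0]
        p = write_yoloseg(tmp_path / "t.txt", t.label_map)
        masks = read_yoloseg(p, t.label_map.shape)
        union = np.zeros(t.label_map.shape, bool)
        for m in masks:
            union |= m
        orig = t.label_map > 0
        assert (union & orig).sum() / (union | orig).sum() >= 0.99

    def test_empty_tile_write_refused(self, tmp_path):
        with pytest.raises(ValueError):
            write_labelme(tmp_path / "e.json", np.zeros((32, 32), np.int32))
        with pytest.raises(ValueError):
            write_yoloseg(tmp_path / "e.txt", np.zeros((32, 32), np.int32))

    def test_polygons_have_at_least_three_vertices(self, small_tiles):
        for t in small_tiles[:4]:
            for iid in t.instance_ids:
                for poly in mask_to_polygons(t.instance_mask(iid)):
                    assert len(poly.exterior.coords) - 1 >= 3

    def test_mask_polygon_mask_exact_for_single_component(self):
        rng = np.random.default_rng(0)
        m = np.zeros((40, 40), bool)
        m[10:30, 8:25] = True
        m[12:20, 20:33] = True
        polys = mask_to_polygons(m)
        back = polygons_to_mask(polys, m.shape)
        assert np.array_equal(m, back)


def _blank_scene(w, h):
    from fieldseg.georef import CameraIntrinsics, UavPose

    return FieldScene(
        image=np.zeros((h, w, 3), np.uint8),
        label_map=np.zeros((h, w), np.int32),
        instances=[],
        crop_centers=[],
        params=FieldParams(width_px=w, height_px=h),
        pose=UavPose(lat=48.0, lon=125.0),
        intrinsics=CameraIntrinsics.nadir_default(w, h),
    )
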