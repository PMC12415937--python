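import numpy as np
import pytest

from caaquant.segmentation import (LabeledVessels, SegmentationParams,
                                   derive_capillaries, detect_arterioles,
                                   find_complete_rings, threshold_channel)


def _annulus(shape, cy, cx, r_in, r_out):
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    d2 = (yy - cy) ** 2 + (xx - cx) ** 2
    return (d2 <= r_out**2) & (d2 > r_in**2)


def _disk(shape, cy, cx, r):
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2


class TestThreshold:
    def test_constant_zero_image_fixed_threshold(self):
        mask = threshold_channel(np.zeros((8, 8)), "fixed", value=10.0)
        assert not mask.any()

    def test_two_level_image_otsu_selects_bright_class(self, rng):
        img = np.zeros((16, 16))
        bright = rng.random((16, 16)) < 0.3
        img[bright] = 100.0
        mask = threshold_channel(img, "otsu")
        np.testing.assert_array_equal(mask, bright)

    def test_matches_per_pixel_comparison(self, rng):
        img = rng.uniform(0, 50, (12, 12))
        t = 23.7
        mask = threshold_channel(img, t)
        expected = np.empty((12, 12), dtype=bool)
        for i in range(12):
            for j in range(12):
                expected[i, j] = img[i, j] > t
        np.testing.assert_array_equal(mask, expected)

    def test_fixed_without_value_rejected(self):
        with pytest.raises(ValueError):
            threshold_channel(np.ones((4, 4)), "fixed")


class TestCompleteRings:
    def test_closed_annulus_is_a_ring_with_interior_lumen(self, annulus_masks):
        ring, _ = annulus_masks
        _, frame = find_complete_rings(ring)
        assert len(frame) == 1
        assert bool(frame.iloc[0]["is_ring"])
        # lumen is the enclosed disk of radius 5 (~78.5 px rasterised)
        assert frame.iloc[0]["lumen_px"] == pytest.approx(np.pi * 25, rel=0.15)

    def test_gap_cut_annulus_is_not_a_ring(self, annulus_masks):
        ring, gap = annulus_masks
        _, f_ring = find_complete_rings(ring)
        _, f_gap = find_complete_rings(gap)
        assert bool(f_ring.iloc[0]["is_ring"])
        assert not bool(f_gap.iloc[0]["is_ring"])
        assert f_gap.iloc[0]["lumen_px"] == 0

    def test_solid_disk_is_not_a_ring(self):
        disk = _disk((32, 32), 16, 16, 10)
        _, frame = find_complete_rings(disk)
        assert not bool(frame.iloc[0]["is_ring"])

    def test_border_truncated_ring_rejected(self):
        ring = _annulus((20, 32), 0, 16, 5, 10)  # open at the top border
        _, frame = find_complete_rings(ring)
        assert not frame["is_ring"].any()

    def test_ring_flag_invariant_to_translation_and_rotation(self, annulus_masks):
        ring, gap = annulus_masks
        for mask, expected in ((ring, True), (gap, False)):
            for shifted in (np.roll(mask, (3, -2), axis=(0, 1)),
                            np.rot90(mask), np.rot90(mask, 2)):
                _, frame = find_complete_rings(shifted)
                assert bool(frame.iloc[0]["is_ring"]) is expected

    def test_empty_mask_gives_empty_result(self):
        labels, frame = find_complete_rings(np.zeros((8, 8), dtype=bool))
        assert labels.max() == 0 and len(frame) == 0


class TestDetectArterioles:
    def _copositive_scene(self, wall_px_target):
        # build an annulus, then trim to an exact pixel count
        shape = (64, 64)
        ring = _annulus(shape, 32, 32, 8, 12)
        extra = int(ring.sum()) - wall_px_target
        assert extra >= 0
        if extra:
            # remove outermost pixels (keeps the ring closed)
            yy, xx = np.mgrid[0:64, 0:64]
            d2 = (yy - 32) ** 2 + (xx - 32) ** 2
            order = np.argsort(-d2[ring])
            coords = np.argwhere(ring)[order[:extra]]
            ring[coords[:, 0], coords[:, 1]] = False
        return ring

    def test_known_wall_pixel_count_detected(self):
        params = SegmentationParams()
        ring = self._copositive_scene(200)
        out = detect_arterioles(ring, ring, params, 0.5676)
        assert out.count == 1
        assert out.records.iloc[0]["area_px"] == 200

    def test_wall_below_150_px_excluded(self):
        params = SegmentationParams()
        ring = self._copositive_scene(149)
        _, frame = find_complete_rings(ring)
        assert bool(frame.iloc[0]["is_ring"])  # still a ring, fails on area
        out = detect_arterioles(ring, ring, params, 0.5676)
        assert out.count == 0

    def test_exact_threshold_wall_retained(self):
        ring = self._copositive_scene(150)
        out = detect_arterioles(ring, ring, SegmentationParams(), 0.5676)
        assert out.count == 1

    def test_no_collagen_overlap_excluded(self):
        ring = self._copositive_scene(200)
        empty = np.zeros_like(ring)
        out = detect_arterioles(empty, ring, SegmentationParams(), 0.5676)
        assert out.count == 0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            detect_arterioles(np.zeros((4, 4), bool), np.zeros((5, 5), bool),
                              SegmentationParams(), 1.0)

    def test_raising_area_threshold_never_increases_count(self):
        ring_a = _annulus((96, 96), 24, 24, 8, 12)
        ring_b = _annulus((96, 96), 70, 70, 5, 8)
        scene = ring_a | ring_b
        counts = []
        for thr in (50, 150, 300, 500):
            params = SegmentationParams(min_arteriole_area_px=thr)
            counts.append(detect_arterioles(scene, scene, params, 1.0).count)
        assert counts == sorted(counts, reverse=True)


class TestDeriveCapillaries:
    def test_separate_tube_kept_with_exact_area(self):
        shape = (64, 64)
        ring = _annulus(shape, 20, 20, 8, 12)
        col = ring.copy()
        col[50:55, 10:20] = True  # 50-px tube well away from the arteriole
        params = SegmentationParams()
        art = detect_arterioles(col, ring, params, 1.0)
        caps = derive_capillaries(col, art, params, 1.0)
        assert caps.count == 1
        assert caps.records.iloc[0]["area_px"] == 50

    def test_component_below_29_px_removed(self):
        shape = (64, 64)
        col = np.zeros(shape, dtype=bool)
        col[10:14, 10:17] = True  # 28 px
        art = detect_arterioles(np.zeros(shape, bool), np.zeros(shape, bool),
                                SegmentationParams(), 1.0)
        caps = derive_capillaries(col, art, SegmentationParams(), 1.0)
        assert caps.count == 0

    def test_component_at_29_px_retained(self):
        col = np.zeros((64, 64), dtype=bool)
        col[10:11, 10:39] = True  # 29 px
        art = detect_arterioles(np.zeros((64, 64), bool),
                                np.zeros((64, 64), bool),
                                SegmentationParams(), 1.0)
        caps = derive_capillaries(col, art, SegmentationParams(), 1.0)
        assert caps.count == 1

    def test_empty_collagen_mask_gives_no_capillaries(self):
        art = detect_arterioles(np.zeros((32, 32), bool),
                                np.zeros((32, 32), bool),
                                SegmentationParams(), 1.0)
        caps = derive_capillaries(np.zeros((32, 32), bool), art,
                                  SegmentationParams(), 1.0)
        assert caps.count == 0

    def test_arteriole_and_capillary_pixels_disjoint(self):
        shape = (96, 96)
        ring = _annulus(shape, 30, 30, 8, 12)
        col = ring.copy()
        col[70:74, 20:60] = True
        params = SegmentationParams()
        art = detect_arterioles(col, ring, params, 1.0)
        caps = derive_capillaries(col, art, params, 1.0)
        assert not (art.mask() & caps.mask()).any()
        # the dilated margin separates the two classes by >= 4 px
        assert caps.count == 1
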