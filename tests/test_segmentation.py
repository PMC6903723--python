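import numpy as np
import pytest
from scipy import ndimage as ndi

from ctri.limbs import split_limbs
from ctri.segmentation import (
    SegmentationParams,
    body_mask,
    close_to_region,
    count_reticulation,
    denoise,
    donut_roi,
    eliminate_hu_band,
    jitter_params,
    peel_skin,
    segment_limb,
)

from _oracles import closing as bf_closing
from _oracles import erode as bf_erode
from _oracles import label8, remove_small, stage_chain

CONN8 = np.ones((3, 3), bool)


def _disk_image(value, radius=10, size=32, background=-1000.0):
    img = np.full((size, size), background)
    rr, cc = np.ogrid[:size, :size]
    img[(rr - size // 2) ** 2 + (cc - size // 2) ** 2 <= radius**2] = value
    return img


class TestParams:
    def test_band_order_enforced(self):
        with pytest.raises(ValueError, match="hu_band_low"):
            SegmentationParams(hu_band_low=30, hu_band_high=26)

    def test_body_threshold_below_band(self):
        with pytest.raises(ValueError, match="body_mask_hu"):
            SegmentationParams(body_mask_hu=0.0)

    def test_radii_positive(self):
        with pytest.raises(ValueError, match="skin_peel_px"):
            SegmentationParams(skin_peel_px=0)


class TestBodyMask:
    def test_uniform_air_slice_errors(self, default_params):
        with pytest.raises(ValueError, match="no body found"):
            body_mask(np.full((16, 16), -1000.0), default_params)

    def test_disk_with_interior_hole_is_filled(self, default_params):
        img = _disk_image(40.0)
        img[16, 16] = -1000.0  # interior air pocket
        mask = body_mask(img, default_params)
        assert mask[16, 16]
        assert mask.sum() == (_disk_image(40.0) > -300).sum()

    def test_two_limbs_give_two_components(self, two_disk_slice, default_params):
        mask = body_mask(two_disk_slice, default_params)
        _, n = ndi.label(mask, structure=CONN8)
        assert n == 2


class TestEliminateBand:
    @pytest.mark.parametrize(
        "hu,expected",
        [(0.0, False), (40.0, True), (26.0, False), (-50.0, False), (27.0, True)],
    )
    def test_band_membership_inclusive(self, hu, expected, default_params):
        img = _disk_image(hu)
        body = body_mask(img, default_params)
        band = eliminate_hu_band(img, body, default_params)
        centre = band[16, 16]
        assert centre == expected

    def test_empty_body_rejected(self, default_params):
        with pytest.raises(ValueError, match="empty"):
            eliminate_hu_band(np.zeros((4, 4)), np.zeros((4, 4), bool), default_params)


class TestDenoise:
    def test_isolated_pixel_removed(self, default_params):
        mask = np.zeros((16, 16), bool)
        mask[8, 8] = True
        assert not denoise(mask, default_params).any()

    def test_large_square_survives_opening(self):
        # opening is anti-extensive and only rounds the four corners here
        params = SegmentationParams(min_object_px=1)
        mask = np.zeros((32, 32), bool)
        mask[5:25, 5:25] = True
        out = denoise(mask, params)
        assert not (out & ~mask).any()
        assert mask.sum() - out.sum() <= 4  # corner rounding only
        assert out[6:24, 6:24].all()

    def test_small_object_threshold(self, default_params):
        # one 5-px and one 50-px component; min_object_px=9 keeps only the latter
        mask = np.zeros((32, 32), bool)
        mask[2:7, 2] = True  # 5 px line (erased by opening anyway; use radius 0)
        mask[10:20, 10:15] = True  # 50 px block
        params = SegmentationParams(opening_radius_px=0, min_object_px=9)
        out = denoise(mask, params)
        np.testing.assert_array_equal(out, remove_small(mask, 9))
        labels, n = label8(out)
        assert n == 1 and out.sum() == 50

    def test_jitter_is_deterministic_and_in_range(self, default_params):
        p1 = jitter_params(default_params, 123)
        p2 = jitter_params(default_params, 123)
        assert p1 == p2
        assert p1.opening_radius_px in (1, 2)
        assert 5 <= p1.min_object_px <= 15


class TestPeelSkin:
    def test_skin_line_is_outer_shell(self, default_params):
        img = _disk_image(40.0)
        body = body_mask(img, default_params)
        _, skin = peel_skin(body, body, default_params)
        np.testing.assert_array_equal(skin, body & ~bf_erode(body, 2))

    def test_interior_mask_unchanged(self, default_params):
        img = _disk_image(40.0)
        body = body_mask(img, default_params)
        inner = np.zeros_like(body)
        inner[14:18, 14:18] = True
        peeled, _ = peel_skin(inner, body, default_params)
        np.testing.assert_array_equal(peeled, inner)

    def test_shell_pixel_count_set_arithmetic(self, default_params):
        img = _disk_image(40.0, radius=12, size=40)
        body = body_mask(img, default_params)
        _, skin = peel_skin(body, body, default_params)
        assert skin.sum() == body.sum() - bf_erode(body, default_params.skin_peel_px).sum()


class TestCloseToRegion:
    def test_bridges_small_gap(self):
        params = SegmentationParams(closing_radius_px=2)
        mask = np.zeros((20, 30), bool)
        mask[8:12, 5:10] = True
        mask[8:12, 12:17] = True  # 2 px gap, safely below the disk diameter
        _, n = label8(close_to_region(mask, params))
        assert n == 1

    def test_idempotent_on_connected_blob(self, default_params):
        mask = np.zeros((32, 32), bool)
        rr, cc = np.ogrid[:32, :32]
        mask[(rr - 16) ** 2 + (cc - 16) ** 2 <= 100] = True
        once = close_to_region(mask, default_params)
        np.testing.assert_array_equal(close_to_region(once, default_params), once)

    def test_component_count_never_increases(self, default_params):
        rng = np.random.default_rng(5)
        for _ in range(10):
            mask = rng.random((24, 24)) < 0.08
            _, n_in = label8(mask)
            _, n_out = label8(close_to_region(mask, default_params))
            assert n_out <= max(n_in, 1)

    def test_escalation_merges_when_requested(self):
        mask = np.zeros((40, 60), bool)
        mask[15:25, 5:15] = True
        mask[15:25, 40:50] = True  # 25 px apart: radius 5 cannot bridge
        stubborn = SegmentationParams(closing_radius_px=5, closing_escalations=0)
        _, n0 = label8(close_to_region(mask, stubborn))
        assert n0 == 2
        eager = SegmentationParams(closing_radius_px=5, closing_escalations=4)
        _, n1 = label8(close_to_region(mask, eager))
        assert n1 == 1


class TestDonutAndCount:
    def _concentric(self):
        rr, cc = np.ogrid[:48, :48]
        d2 = (rr - 24) ** 2 + (cc - 24) ** 2
        body = d2 <= 20**2
        skin = body & (d2 > 17**2)
        core = d2 <= 8**2
        return body, skin, core

    def test_concentric_geometry_yields_intermediate_annulus(self):
        body, skin, core = self._concentric()
        donut = donut_roi(core, skin, body)
        assert not (donut & skin).any() and not (donut & core).any()
        assert donut.sum() == body.sum() - core.sum() - skin.sum()

    def test_full_coverage_gives_empty_donut(self):
        body, skin, _ = self._concentric()
        core = body & ~skin
        assert not donut_roi(core, skin, body).any()

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            donut_roi(np.zeros((4, 4), bool), np.zeros((4, 4), bool), np.zeros((5, 5), bool))

    def test_count_zero_without_bright_pixels(self):
        body, skin, core = self._concentric()
        donut = donut_roi(core, skin, body)
        count, mask = count_reticulation(np.full(body.shape, -100.0), donut, np.zeros_like(donut))
        assert count == 0 and not mask.any()

    def test_count_gated_by_band_threshold(self, default_params):
        # trabecular HU just inside vs outside the eliminated band
        for hu, expect_positive in ((20.0, False), (60.0, True)):
            img = _disk_image(-100.0, radius=20, size=48)
            rr, cc = np.ogrid[:48, :48]
            d2 = (rr - 24) ** 2 + (cc - 24) ** 2
            img[d2 <= 4**2] = 45.0  # core, > 10 px clear of the arc
            img[(d2 > 15**2) & (d2 <= 17**2) & (rr < 24)] = hu  # arc in the fat
            body = body_mask(img, default_params)
            seg = segment_limb(img, body, default_params)
            assert (seg.reticulation_count > 0) == expect_positive


class TestChainProperties:
    def test_containment_chain(self, clean_phantom, default_params):
        _, volume, _ = clean_phantom
        body = body_mask(volume.voxels[0], default_params)
        pair = split_limbs(body, 0, "left")
        seg = segment_limb(volume.voxels[0], pair.left_region, default_params)
        donut = seg.stage_masks["donut"]
        assert (seg.reticulation_mask & ~donut).sum() == 0
        assert (donut & ~pair.left_region).sum() == 0
        assert not (seg.skin_line & donut).any()
        assert seg.reticulation_count == int(seg.reticulation_mask.sum())

    def test_stage5_single_component_per_limb(self, noisy_phantom, default_params):
        _, volume, _ = noisy_phantom
        body = body_mask(volume.voxels[1], default_params)
        pair = split_limbs(body, 1, "left")
        for region in (pair.left_region, pair.right_region):
            seg = segment_limb(volume.voxels[1], region, default_params)
            _, n = ndi.label(seg.stage_masks["closed"], structure=CONN8)
            assert n == 1

    def test_min_object_monotonicity(self, noisy_phantom):
        _, volume, _ = noisy_phantom
        base = SegmentationParams()
        body = body_mask(volume.voxels[0], base)
        pair = split_limbs(body, 0, "left")
        prev_den, prev_count = None, None
        for min_px in (1, 5, 9, 15, 30):
            params = SegmentationParams(min_object_px=min_px)
            seg = segment_limb(volume.voxels[0], pair.left_region, params)
            den = int(seg.stage_masks["denoised"].sum())
            if prev_den is not None:
                assert den <= prev_den
                assert seg.reticulation_count <= prev_count
            prev_den, prev_count = den, seg.reticulation_count

    def test_hu_shift_invariance(self, two_disk_slice, default_params):
        shift = 15.0
        shifted_params = SegmentationParams(
            hu_band_low=default_params.hu_band_low + shift,
            hu_band_high=default_params.hu_band_high + shift,
        )
        body = body_mask(two_disk_slice, default_params)
        pair = split_limbs(body, 0, "left")
        seg_a = segment_limb(two_disk_slice, pair.left_region, default_params)
        seg_b = segment_limb(two_disk_slice + shift, pair.left_region, shifted_params)
        for name in seg_a.stage_masks:
            np.testing.assert_array_equal(seg_a.stage_masks[name], seg_b.stage_masks[name])
        assert seg_a.reticulation_count == seg_b.reticulation_count


class TestBruteForceOracle:
    """Every stage mask equals naive per-pixel set arithmetic on small slices."""

    def test_stage_chain_matches_oracle(self, two_disk_slice, default_params):
        body = body_mask(two_disk_slice, default_params)
        pair = split_limbs(body, 0, "left")
        for region in (pair.left_region, pair.right_region):
            seg = segment_limb(two_disk_slice, region, default_params)
            expected = stage_chain(two_disk_slice, region, default_params)
            for name in seg.stage_masks:
                np.testing.assert_array_equal(
                    seg.stage_masks[name], expected[name], err_msg=f"stage {name}"
                )
            np.testing.assert_array_equal(seg.reticulation_mask, expected["reticulation"])

    def test_closing_matches_oracle_on_random_masks(self, default_params):
        rng = np.random.default_rng(11)
        for _ in range(5):
            mask = ndi.binary_dilation(rng.random((32, 32)) < 0.04, np.ones((2, 2)))
            np.testing.assert_array_equal(
                close_to_region(mask, default_params),
                bf_closing(mask, default_params.closing_radius_px),
            )
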