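"""Morphological primitives against brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from taphen import morphops
from taphen.errors import ContractError
from taphen.imgio import GrayImage
from taphen.morphops import (
    BinaryMask,
    StructuringElement,
    binarize,
    clean_mask,
    dilate_mask,
    extended_maxima,
    filter_regions,
    measure_regions,
    otsu_threshold,
    tophat,
)

from oracles import (
    component_areas_oracle,
    disk_offsets,
    extended_maxima_oracle,
    otsu_oracle,
    tophat_oracle,
)


class TestOtsu:
    def test_half_and_half_split(self):
        img = np.zeros((16, 16))
        img[:, 8:] = 255.0
        thr = otsu_threshold(img)
        assert thr == otsu_oracle(img)
        mask = binarize(img, thr)
        np.testing.assert_array_equal(mask.pixels, img == 255)

    def test_constant_image_degenerates_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            thr = otsu_threshold(np.full((5, 5), 7.0))
        assert thr == 7.0
        assert not binarize(np.full((5, 5), 7.0), thr).pixels.any()

    def test_three_level_histogram_matches_oracle(self):
        vals = np.repeat([0.0, 100.0, 200.0], 10)
        img = vals.reshape(3, 10)
        assert otsu_threshold(img) == otsu_oracle(img)

    def test_matches_exhaustive_search_on_random_images(self, rng):
        for _ in range(40):
            img = rng.integers(0, 256, (16, 16)).astype(float)
            assert otsu_threshold(img) == otsu_oracle(img)


class TestCleanMask:
    def test_empty_mask_unchanged(self):
        m = BinaryMask(np.zeros((10, 10), bool))
        assert not clean_mask(m, 100, True).pixels.any()

    def test_area_threshold_separates_components(self):
        px = np.zeros((40, 40), bool)
        px[2:11, 2:11] = True  # 81 px
        px[20:32, 20:32] = True  # 144 px
        out = clean_mask(BinaryMask(px), 100, remove_edge=False)
        assert component_areas_oracle(out.pixels, 8) == [144]

    def test_edge_removal(self):
        px = np.zeros((20, 20), bool)
        px[0:3, 5:9] = True  # touches row 0
        px[10:14, 10:14] = True
        out = clean_mask(BinaryMask(px), 0, remove_edge=True)
        assert component_areas_oracle(out.pixels, 8) == [16]

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=15)
    def test_idempotent(self, seed):
        rng = np.random.default_rng(seed)
        m = BinaryMask(rng.uniform(size=(24, 24)) < 0.4)
        once = clean_mask(m, 5, remove_edge=True)
        twice = clean_mask(once, 5, remove_edge=True)
        np.testing.assert_array_equal(once.pixels, twice.pixels)


class TestTopHat:
    SE = StructuringElement("ellipsoid", 60, 5.0)

    def test_constant_image_zeroed(self):
        out = tophat(np.full((40, 50), 17.0), self.SE)
        np.testing.assert_allclose(out.pixels, 0.0, atol=1e-9)

    def test_single_pixel_retained(self):
        # an isolated spike survives the top-hat almost unchanged: the
        # opening at the spike equals height*(1 - sqrt(1 - 1/r^2)), i.e.
        # the SE profile drop over one pixel (~7e-4 for radius 60)
        f = np.zeros((30, 30))
        f[15, 15] = 100.0
        out = tophat(f, StructuringElement("ellipsoid", 8, 5.0), method="exact")
        ref = tophat_oracle(f, 8, 5.0)
        np.testing.assert_allclose(out.pixels, ref, atol=1e-9)
        assert out.pixels[15, 15] == pytest.approx(100.0, abs=0.05)

    def test_exact_path_matches_direct_oracle(self, rng):
        f = rng.uniform(0, 255, (20, 24))
        out = tophat(f, StructuringElement("ellipsoid", 5, 3.0), method="exact")
        np.testing.assert_allclose(out.pixels, tophat_oracle(f, 5, 3.0), atol=1e-9)

    def test_fast_path_within_quantization_bound(self, rng):
        f = rng.uniform(0, 255, (48, 56))
        se = StructuringElement("ellipsoid", 12, 5.0)
        exact = tophat(f, se, method="exact").pixels
        fast = tophat(f, se, method="fast").pixels
        # one quantization step per erosion/dilation stage
        assert np.abs(fast - exact).max() <= 2 * 5.0 / 5 + 1e-9

    def test_shallow_ramp_suppressed(self):
        ramp = np.tile(np.linspace(0.0, 5.0, 2560), (2, 1))
        out = tophat(ramp, self.SE)
        assert out.pixels.max() < 1.0

    @pytest.mark.parametrize("method", ["exact", "fast"])
    def test_shift_invariance(self, rng, method):
        f = rng.uniform(0, 100, (30, 30))
        se = StructuringElement("ellipsoid", 8, 4.0)
        a = tophat(f, se, method=method).pixels
        b = tophat(f + 37.0, se, method=method).pixels
        np.testing.assert_allclose(a, b, atol=1e-9)

    def test_output_nonnegative(self, rng):
        f = rng.uniform(0, 255, (80, 80))
        assert tophat(f, self.SE, method="fast").pixels.min() >= 0.0


class TestExtendedMaxima:
    def test_two_peaks_with_saddle_merge(self):
        f = np.zeros((7, 15))
        f[3, 3] = 120.0
        f[3, 11] = 110.0
        f[3, 4:11] = 100.0
        out = extended_maxima(f, 30.0, 8)
        ref = extended_maxima_oracle(f, 30.0, 8)
        np.testing.assert_array_equal(out.pixels, ref)
        assert len(component_areas_oracle(out.pixels, 8)) == 1
        assert out.pixels[3, 3] and out.pixels[3, 11]

    def test_plateau_detected_exactly(self):
        f = np.zeros((11, 11))
        f[3:8, 3:8] = 40.0
        out = extended_maxima(f, 30.0, 8)
        np.testing.assert_array_equal(out.pixels, f == 40.0)

    def test_constant_image_single_component(self):
        out = extended_maxima(np.full((6, 6), 3.0), 30.0, 8)
        assert out.pixels.all()

    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_matches_iterative_reconstruction_oracle(self, rng, connectivity):
        for _ in range(20):
            h = float(rng.integers(1, 40))
            f = rng.integers(0, 100, (16, 16)).astype(float)
            np.testing.assert_array_equal(
                extended_maxima(f, h, connectivity).pixels,
                extended_maxima_oracle(f, h, connectivity),
            )


class TestMeasureRegions:
    def test_filled_square_measurements(self):
        px = np.zeros((30, 30), bool)
        px[5:25, 5:25] = True
        inten = np.full((30, 30), 200.0)
        (rec,) = measure_regions(BinaryMask(px), inten)
        assert rec.area_px == 400
        assert rec.total_intensity == 80000.0
        assert rec.centroid == (14.5, 14.5)
        assert not rec.touches_edge

    def test_empty_mask_empty_list(self):
        assert measure_regions(BinaryMask(np.zeros((5, 5), bool))) == []

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ContractError):
            measure_regions(BinaryMask(np.zeros((5, 5), bool)), np.zeros((6, 6)))

    def test_area_sum_equals_true_pixels(self, rng):
        px = rng.uniform(size=(40, 40)) < 0.3
        recs = measure_regions(BinaryMask(px))
        assert sum(r.area_px for r in recs) == px.sum()

    @pytest.mark.parametrize("side", [10, 20, 40])
    def test_square_perimeter_within_ten_percent(self, side):
        px = np.zeros((side + 10, side + 10), bool)
        px[5 : 5 + side, 5 : 5 + side] = True
        (rec,) = measure_regions(BinaryMask(px))
        assert rec.perimeter_px == pytest.approx(4 * (side - 1), rel=0.10)

    def test_labels_in_raster_order(self):
        px = np.zeros((20, 20), bool)
        px[10:14, 2:6] = True  # first pixel later in raster order
        px[2:6, 10:14] = True
        recs = measure_regions(BinaryMask(px))
        assert [r.label for r in recs] == [1, 2]
        assert recs[0].centroid[0] < recs[1].centroid[0]


class TestFilterRegions:
    def _rec(self, area, perim=50.0):
        from taphen.morphops import RegionRecord

        return RegionRecord(1, area, perim, (0, 0), False)

    def test_window_membership(self):
        recs = [self._rec(250), self._rec(400), self._rec(1200)]
        kept, disc = filter_regions(recs, 300, 1000, 165.0)
        assert [r.area_px for r in kept] == [400]
        assert len(disc) == 2

    def test_boundaries_kept(self):
        kept, disc = filter_regions([self._rec(300), self._rec(1000), self._rec(500, 165.0)], 300, 1000, 165.0)
        assert len(kept) == 3 and not disc

    def test_empty_input(self):
        assert filter_regions([], 0, 10, 1.0) == ([], [])

    def test_idempotent(self, rng):
        recs = [self._rec(int(a), float(p)) for a, p in rng.uniform(1, 2000, (30, 2))]
        kept, _ = filter_regions(recs, 300, 1000, 165.0)
        kept2, disc2 = filter_regions(kept, 300, 1000, 165.0)
        assert kept2 == kept and not disc2


class TestDilateMask:
    def test_radius_zero_identity(self, rng):
        m = BinaryMask(rng.uniform(size=(10, 10)) < 0.5)
        np.testing.assert_array_equal(dilate_mask(m, 0).pixels, m.pixels)

    def test_single_pixel_becomes_disk(self):
        px = np.zeros((11, 11), bool)
        px[5, 5] = True
        out = dilate_mask(BinaryMask(px), 3)
        assert out.pixels.sum() == len(disk_offsets(3))
        for dy, dx in disk_offsets(3):
            assert out.pixels[5 + dy, 5 + dx]

    def test_empty_stays_empty(self):
        assert not dilate_mask(BinaryMask(np.zeros((8, 8), bool)), 5).pixels.any()
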