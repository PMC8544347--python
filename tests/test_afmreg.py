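"""AFM height-map I/O, similarity estimation, warping and overlay export."""

import numpy as np
import pytest

from taphen import afmreg
from taphen.afmreg import (
    ControlPoints,
    HeightMap,
    SimilarityTransform,
    crop_to_scan,
    estimate_similarity,
    export_overlay,
    read_height_map,
    warp_fluorescence,
    write_height_map,
)
from taphen.errors import ContractError, FormatError

from conftest import make_rgb


class TestHeightMapIO:
    def test_zero_matrix_round_trip(self, tmp_path):
        hm = HeightMap(np.zeros((3, 3)), (20.0, 20.0))
        p = tmp_path / "map.txt"
        write_height_map(hm, p)
        back = read_height_map(p)
        np.testing.assert_array_equal(back.heights, 0.0)
        assert back.scan_size_um == (20.0, 20.0)

    def test_values_round_trip_exactly(self, tmp_path, rng):
        hm = HeightMap(rng.uniform(-5, 300, (7, 9)), (4.0, 3.5))
        p = tmp_path / "map.txt"
        write_height_map(hm, p)
        back = read_height_map(p)
        np.testing.assert_array_equal(back.heights, hm.heights)

    def test_ragged_rows_rejected_with_row_index(self, tmp_path):
        p = tmp_path / "bad.txt"
        p.write_text("# scan_size_um_x = 1\n# scan_size_um_y = 1\n1 2 3\n1 2 3 4\n")
        with pytest.raises(FormatError, match="4"):
            read_height_map(p)

    def test_non_numeric_token_rejected(self, tmp_path):
        p = tmp_path / "bad.txt"
        p.write_text("# scan_size_um_x = 1\n# scan_size_um_y = 1\n1 2\n3 oops\n")
        with pytest.raises(FormatError, match="non-numeric"):
            read_height_map(p)

    def test_missing_scan_size_rejected(self, tmp_path):
        p = tmp_path / "bad.txt"
        p.write_text("1 2\n3 4\n")
        with pytest.raises(FormatError, match="scan_size"):
            read_height_map(p)


def _apply(tf: SimilarityTransform, pts: np.ndarray) -> np.ndarray:
    return tf.apply(pts)


class TestEstimateSimilarity:
    def test_identity_on_identical_sets(self, rng):
        pts = rng.uniform(0, 100, (6, 2))
        tf, rms = estimate_similarity(ControlPoints(pts, pts.copy()))
        assert tf.scale == pytest.approx(1.0, abs=1e-9)
        assert tf.rotation_rad == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(tf.translation, 0.0, atol=1e-9)
        assert rms < 1e-9

    def test_known_transform_recovered_to_machine_precision(self, rng):
        truth = SimilarityTransform(1.5, np.deg2rad(30.0), (10.0, -5.0))
        src = rng.uniform(0, 200, (6, 2))
        dst = truth.apply(src)
        tf, rms = estimate_similarity(ControlPoints(src, dst))
        assert tf.scale == pytest.approx(truth.scale, abs=1e-6)
        assert tf.rotation_rad == pytest.approx(truth.rotation_rad, abs=1e-6)
        assert np.allclose(tf.translation, truth.translation, atol=1e-6)
        assert rms < 1e-9

    def test_jittered_points_recovered_on_average(self):
        rng = np.random.default_rng(99)
        scale_errs, rot_errs, rmss = [], [], []
        for _ in range(50):
            truth = SimilarityTransform(
                rng.uniform(0.5, 2.0), rng.uniform(-np.pi, np.pi),
                (rng.uniform(-50, 50), rng.uniform(-50, 50)),
            )
            src = rng.uniform(0, 300, (12, 2))
            dst = truth.apply(src) + rng.normal(0, 0.5, (12, 2))
            tf, rms = estimate_similarity(ControlPoints(src, dst))
            scale_errs.append(abs(tf.scale / truth.scale - 1))
            d = (tf.rotation_rad - truth.rotation_rad + np.pi) % (2 * np.pi) - np.pi
            rot_errs.append(abs(d))
            rmss.append(rms)
        assert np.mean(scale_errs) < 0.02
        assert np.mean(rot_errs) < np.deg2rad(1.0)
        assert 0.2 < np.mean(rmss) < 0.8  # ~ sigma = 0.5 px

    def test_rms_invariant_under_global_rigid_motion(self, rng):
        src = rng.uniform(0, 100, (8, 2))
        dst = src + rng.normal(0, 1.0, (8, 2))
        _, rms0 = estimate_similarity(ControlPoints(src, dst))
        motion = SimilarityTransform(1.0, 0.7, (30.0, -12.0))
        _, rms1 = estimate_similarity(ControlPoints(motion.apply(src), motion.apply(dst)))
        assert rms1 == pytest.approx(rms0, rel=1e-9)

    def test_coincident_points_rejected(self):
        pts = np.array([[5.0, 5.0], [5.0, 5.0 + 1e-12]])
        with pytest.raises(ContractError, match="degenerate|coincide"):
            estimate_similarity(ControlPoints(pts, pts + 3))

    def test_duplicate_source_points_rejected(self):
        src = np.array([[1.0, 2.0], [1.0, 2.0], [3.0, 4.0]])
        with pytest.raises(ContractError, match="duplicat"):
            ControlPoints(src, src + 1)

    def test_csv_round_trip(self, tmp_path, rng):
        cp = ControlPoints(rng.uniform(0, 10, (4, 2)), rng.uniform(0, 10, (4, 2)))
        cp.write_csv(tmp_path / "pts.csv")
        back = ControlPoints.read_csv(tmp_path / "pts.csv")
        np.testing.assert_allclose(back.fluor, cp.fluor)
        np.testing.assert_allclose(back.afm, cp.afm)


class TestWarp:
    def test_identity_transform_preserves_pixels(self, rng):
        img = make_rgb(rng.integers(0, 256, (12, 14, 3)))
        out = warp_fluorescence(img, SimilarityTransform(), (12, 14))
        np.testing.assert_array_equal(out.pixels, img.pixels)

    def test_integer_translation_is_exact_shift(self, rng):
        img = make_rgb(rng.integers(0, 256, (12, 14, 3)))
        out = warp_fluorescence(img, SimilarityTransform(1.0, 0.0, (3.0, 2.0)), (12, 14))
        np.testing.assert_array_equal(out.pixels[3:, 2:], img.pixels[:-3, :-2])
        assert (out.pixels[:3] == 0).all() and (out.pixels[:, :2] == 0).all()

    def test_quarter_rotation_matches_index_permutation(self, rng):
        arr = rng.integers(0, 256, (5, 5, 3))
        img = make_rgb(arr)
        ctr = np.array([2.0, 2.0])
        rot = SimilarityTransform(1.0, np.pi / 2, (0.0, 0.0))
        # choose the translation so the centre maps onto itself
        shift = ctr - rot.apply(ctr[None, :])[0]
        tf = SimilarityTransform(1.0, np.pi / 2, tuple(shift))
        out = warp_fluorescence(img, tf, (5, 5))
        expected = np.zeros_like(arr)
        for r in range(5):
            for c in range(5):
                rr, cc = np.rint(tf.apply(np.array([[r, c]]))[0]).astype(int)
                expected[rr, cc] = arr[r, c]
        np.testing.assert_array_equal(out.pixels, expected)

    def test_round_trip_warp_nearly_lossless_on_smooth_content(self):
        # bilinear interpolation is near-exact on band-limited content; the
        # round trip must reproduce smooth interiors to ~1 gray level
        yy, xx = np.mgrid[0:40, 0:40].astype(float)
        smooth = 120 + 60 * np.sin(2 * np.pi * xx / 40) * np.cos(2 * np.pi * yy / 36)
        img = make_rgb(np.repeat(np.rint(smooth)[:, :, None], 3, axis=2))
        # rotate about the image centre, mapped to the output centre, so no
        # content leaves the larger intermediate frame
        rot = SimilarityTransform(1.0, 0.3, (0.0, 0.0))
        shift = np.array([32.0, 32.0]) - rot.apply(np.array([[20.0, 20.0]]))[0]
        tf = SimilarityTransform(1.0, 0.3, tuple(shift))
        there = warp_fluorescence(img, tf, (64, 64))
        back = warp_fluorescence(there, tf.inverse(), (40, 40))
        interior = np.s_[12:28, 12:28]
        diff = back.pixels[interior].astype(int) - img.pixels[interior].astype(int)
        assert np.abs(diff).max() <= 2  # interpolation + one rounding per leg


class TestCrop:
    def test_identity_centered_crop(self, rng):
        img = make_rgb(rng.integers(0, 256, (40, 40, 3)))
        afm = HeightMap(np.zeros((10, 10)), (1.0, 1.0))
        tf = SimilarityTransform(1.0, 0.0, (-15.0, -15.0))  # AFM covers rows 15..24
        out = crop_to_scan(img, afm, tf)
        np.testing.assert_array_equal(out.pixels, img.pixels[15:25, 15:25])

    def test_footprint_outside_rejected(self, rng):
        img = make_rgb(rng.integers(0, 256, (20, 20, 3)))
        afm = HeightMap(np.zeros((5, 5)), (1.0, 1.0))
        tf = SimilarityTransform(1.0, 0.0, (-100.0, -100.0))
        with pytest.raises(ContractError, match="intersect"):
            crop_to_scan(img, afm, tf)

    def test_straddling_footprint_clipped(self, rng):
        img = make_rgb(rng.integers(0, 256, (20, 20, 3)))
        afm = HeightMap(np.zeros((10, 10)), (1.0, 1.0))
        tf = SimilarityTransform(1.0, 0.0, (5.0, 5.0))  # AFM rows -5..4 in fluor frame
        out = crop_to_scan(img, afm, tf)
        assert out.shape == (5, 5)


class TestExportOverlay:
    def test_flat_topography_drape_equals_color_image(self, rng):
        warped = make_rgb(rng.integers(0, 256, (10, 12, 3)))
        afm = HeightMap(np.zeros((10, 12)), (1.0, 1.0))
        out = export_overlay(afm, warped, "draped")
        np.testing.assert_array_equal(out.pixels, warped.pixels)

    def test_side_by_side_panels_same_dimensions(self, tmp_path, rng):
        warped = make_rgb(rng.integers(0, 256, (10, 12, 3)))
        afm = HeightMap(rng.uniform(0, 300, (20, 24)), (1.0, 1.0))
        out = export_overlay(afm, warped, "side_by_side", tmp_path / "sbs.png")
        assert out.shape == (10, 24)  # two 10x12 panels
        assert (tmp_path / "sbs.png").exists()

    def test_draped_shape_mismatch_rejected(self, rng):
        warped = make_rgb(rng.integers(0, 256, (10, 12, 3)))
        afm = HeightMap(np.zeros((8, 12)), (1.0, 1.0))
        with pytest.raises(ContractError, match="shape"):
            export_overlay(afm, warped, "draped")

    def test_draped_rod_keeps_fluorescence_hue(self):
        # a synthetic rod colored red keeps a red-dominant hue in >= 90 % of
        # its pixels after draping over its own topography
        arr = np.zeros((40, 60, 3), dtype=np.uint8)
        from taphen import synthgen

        r0, c0, mask, dist, _ = synthgen._rod_patch((40, 60), (20, 30), 0.2, 40, 14)
        arr[r0 : r0 + mask.shape[0], c0 : c0 + mask.shape[1]][mask] = (200, 30, 40)
        heights = np.zeros((40, 60))
        prof = 300.0 * np.sqrt(np.maximum(0.0, 1.0 - (dist / 7.0) ** 2))
        heights[r0 : r0 + mask.shape[0], c0 : c0 + mask.shape[1]][mask] = prof[mask]
        out = export_overlay(HeightMap(heights, (1.0, 1.0)), make_rgb(arr), "draped")
        full = np.zeros((40, 60), bool)
        full[r0 : r0 + mask.shape[0], c0 : c0 + mask.shape[1]] = mask
        rod = out.pixels[full]
        red_dominant = (rod[:, 0] > rod[:, 1]) & (rod[:, 0] > rod[:, 2])
        lit = rod.sum(axis=1) > 0
        assert (red_dominant | ~lit).mean() >= 0.999
        assert lit.mean() >= 0.9


class TestTransformObject:
    def test_inverse_composition_is_identity(self, rng):
        tf = SimilarityTransform(1.3, 0.4, (7.0, -3.0))
        pts = rng.uniform(0, 50, (5, 2))
        back = tf.inverse().apply(tf.apply(pts))
        np.testing.assert_allclose(back, pts, atol=1e-9)

    def test_json_round_trip(self, tmp_path):
        tf = SimilarityTransform(0.8, -1.2, (3.5, 9.25))
        tf.to_json(tmp_path / "t.json")
        back = SimilarityTransform.from_json(tmp_path / "t.json")
        assert back == tf

    def test_nonpositive_scale_rejected(self):
        with pytest.raises(ContractError):
            SimilarityTransform(scale=0.0)
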