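"""Flat-field, homography, degradation and gain-chain tests."""

import numpy as np
import pytest

from scintimon.calibration import (
    CorrectionMatrix,
    DeadRegionError,
    DegenerateConfigurationError,
    GainChain,
    Homography,
    adc_to_dose,
    apply_corrections,
    build_correction_matrix,
    degradation_map,
    estimate_homography,
    oblique_view_homography,
)
from scintimon.simulate import VignetteModel


def synthetic_flat(rng, shape=(120, 160), level_pe=2000.0, gain=2.593,
                   field=None):
    """Poisson flat-field frame (pedestal 100) under an illumination field."""
    mu = np.full(shape, level_pe) if field is None else level_pe * field
    return 100.0 + gain * rng.poisson(mu)


class TestCorrectionMatrix:
    def test_uniform_input_gives_unit_corrections(self):
        flat = np.full((80, 80), 600.0)
        cm = build_correction_matrix(flat, mesh_mm=1.0, px_per_mm=4.0, pedestal=0.0)
        assert np.allclose(cm.cells, 1.0)
        assert cm.cells[cm.ref_cell] == 1.0

    def test_corrections_invert_vignette(self):
        rng = np.random.default_rng(0)
        v = VignetteModel(lens_mm=(0, 0, 60.0), ref_point_mm=(0, 0))
        yy, xx = np.mgrid[0:120, 0:160]
        x_mm, y_mm = (xx - 80) / 4.0, (yy - 60) / 4.0
        field = v.factor(x_mm, y_mm)
        flat = synthetic_flat(rng, field=field)
        cm = build_correction_matrix(flat, mesh_mm=1.0, px_per_mm=4.0,
                                     pedestal=100.0, ref_point_px=(80, 60))
        # cell corrections track 1/vignette at each cell center, normalized
        ref_v = field[60, 80]
        cell_v = field.reshape(30, 4, 40, 4).mean(axis=(1, 3))
        expected = ref_v / cell_v
        assert np.allclose(cm.cells, expected / expected[cm.ref_cell], rtol=0.03)

    def test_flattens_smooth_field_below_percent(self):
        rng = np.random.default_rng(1)
        yy, xx = np.mgrid[0:120, 0:160]
        field = (1 + 0.3 * xx / 160) * (1 - 0.2 * yy / 120)  # separable tilt
        flat = synthetic_flat(rng, field=field)
        cm = build_correction_matrix(flat, mesh_mm=1.0, px_per_mm=4.0, pedestal=100.0)
        corrected = apply_corrections(flat, cm, pedestal=100.0)
        cell_means = corrected.reshape(30, 4, 40, 4).mean(axis=(1, 3))
        assert cell_means.std() / cell_means.mean() < 0.01

    def test_identity_when_all_ones(self):
        cm = CorrectionMatrix(1.0, 4, np.ones((5, 5)), (2, 2))
        frame = np.random.default_rng(2).uniform(10, 50, (20, 20))
        out = apply_corrections(frame, cm, pedestal=0.0)
        assert np.allclose(out, frame)

    def test_ref_cell_center_pixel_unchanged(self):
        flat = np.full((40, 40), 500.0)
        flat[:, :20] *= 2.0  # step illumination
        cm = build_correction_matrix(flat, mesh_mm=1.0, px_per_mm=4.0,
                                     pedestal=0.0, ref_point_px=(30, 30))
        out = apply_corrections(flat, cm, pedestal=0.0)
        ry, rx = cm.ref_cell
        cy, cx = int((ry + 0.5) * 4 - 0.5), int((rx + 0.5) * 4 - 0.5)
        assert out[cy + 1, cx + 1] == pytest.approx(flat[cy + 1, cx + 1], rel=1e-9)

    def test_dead_region_reported(self):
        flat = np.full((40, 40), 300.0)
        flat[8:12, 8:12] = 0.0
        with pytest.raises(DeadRegionError) as exc:
            build_correction_matrix(flat, mesh_mm=1.0, px_per_mm=4.0, pedestal=0.0)
        assert (2, 2) in exc.value.cells

    def test_partial_cells_dropped_with_mask(self):
        flat = np.full((40, 40), 300.0)
        mask = np.zeros((40, 40), bool)
        mask[:, 6:] = True  # boundary cuts through cell column 1
        cm = build_correction_matrix(flat, mesh_mm=1.0, px_per_mm=4.0,
                                     pedestal=0.0, active_mask=mask)
        assert np.isnan(cm.cells[:, 0]).all()
        assert np.isnan(cm.cells[:, 1]).all()
        assert np.isfinite(cm.cells[:, 2:]).all()

    def test_save_load_roundtrip(self, tmp_path):
        cells = np.ones((4, 4))
        cells[0, 0] = 1.25
        cm = CorrectionMatrix(1.0, 4, cells, (2, 2))
        cm.save(tmp_path / "c.csv", tmp_path / "c.json")
        back = CorrectionMatrix.load(tmp_path / "c.csv", tmp_path / "c.json")
        assert np.allclose(back.cells, cm.cells)
        assert back.ref_cell == cm.ref_cell and back.cell_px == 4


class TestHomography:
    def test_identity_from_fixed_corners(self):
        pts = np.array([[0.0, 0], [10, 0], [10, 10], [0, 10]])
        hom, rms = estimate_homography(pts, pts)
        assert np.allclose(hom.h, np.eye(3), atol=1e-9)
        assert rms < 1e-9

    def test_exact_recovery_from_random_points(self):
        rng = np.random.default_rng(3)
        true = oblique_view_homography(40.0, 4.0, (960, 540))
        src = rng.uniform(-50, 50, (8, 2))
        est, rms = estimate_homography(src, true.map(src))
        assert np.allclose(est.h, true.h, atol=1e-6)
        assert rms < 1e-6

    def test_oblique_trapezoid_maps_back_to_square(self):
        true = oblique_view_homography(40.0, 4.0, (200, 200))
        square = np.array([[-40.0, -40], [40, -40], [40, 40], [-40, 40]])
        trapezoid = true.map(square)
        # foreshortening: the far edge is imaged shorter than the near edge
        near = abs(trapezoid[1, 0] - trapezoid[0, 0])
        far = abs(trapezoid[2, 0] - trapezoid[3, 0])
        assert far != pytest.approx(near, rel=0.01)
        est, rms = estimate_homography(square, trapezoid)
        back = est.inverse().map(trapezoid)
        assert np.allclose(back, square, atol=1e-6)
        v1, v2 = back[1] - back[0], back[3] - back[0]
        assert abs(np.dot(v1, v2)) < 1e-6  # right angles restored
        assert rms < 1e-6

    def test_matches_independent_reference_estimator(self):
        skimage_tf = pytest.importorskip("skimage.transform")
        rng = np.random.default_rng(4)
        true = oblique_view_homography(35.0, 3.0, (400, 300))
        src = rng.uniform(-45, 45, (12, 2))
        dst = true.map(src)
        ours, _ = estimate_homography(src, dst)
        ref = skimage_tf.ProjectiveTransform.from_estimate(src, dst)
        assert np.allclose(ours.map(src), ref(src), atol=1e-8)
        assert np.allclose(ours.h, ref.params / ref.params[2, 2], rtol=1e-6,
                           atol=1e-9)
        # under pixel noise the two algebraic solutions stay close
        noisy = dst + rng.normal(0, 0.2, dst.shape)
        ours_n, _ = estimate_homography(src, noisy)
        ref_n = skimage_tf.ProjectiveTransform.from_estimate(src, noisy)
        assert np.allclose(ours_n.map(src), ref_n(src), atol=0.05)

    def test_reprojection_rms_scales_with_noise(self):
        rng = np.random.default_rng(5)
        true = oblique_view_homography(40.0, 4.0, (300, 300))
        src = rng.uniform(-45, 45, (40, 2))
        dst = true.map(src)
        rms = []
        for sigma in (0.1, 0.4):
            noisy = dst + rng.normal(0, sigma, dst.shape)
            _, r = estimate_homography(src, noisy)
            rms.append(r)
        assert rms[1] / rms[0] == pytest.approx(4.0, rel=0.5)

    def test_roundtrip_identity(self):
        hom = oblique_view_homography(40.0, 4.0, (100, 100))
        pts = np.array([[1.0, 2.0], [-30, 12], [25, -40]])
        assert np.allclose(hom.inverse().map(hom.map(pts)), pts, rtol=1e-9,
                           atol=1e-9)

    def test_collinear_points_rejected(self):
        src = np.array([[0.0, 0], [1, 1], [2, 2], [3, 3], [4, 4]])
        with pytest.raises(DegenerateConfigurationError):
            estimate_homography(src, src * 2.0)

    def test_too_few_points_rejected(self):
        pts = np.array([[0.0, 0], [1, 0], [0, 1]])
        with pytest.raises(DegenerateConfigurationError):
            estimate_homography(pts, pts)

    def test_json_roundtrip(self, tmp_path):
        hom = oblique_view_homography(40.0, 4.0, (10, 20))
        hom.to_json(tmp_path / "h.json")
        assert np.allclose(Homography.from_json(tmp_path / "h.json").h, hom.h)


class TestDegradationMap:
    def test_identical_frames_no_loss(self):
        ref = np.full((40, 40), 400.0)
        loss, replace = degradation_map(ref, ref, px_per_mm=4.0, pedestal=0.0)
        assert np.allclose(loss, 0.0)
        assert replace is False

    def test_two_percent_global_loss_flags_replacement(self):
        ref = np.full((40, 40), 400.0)
        loss, replace = degradation_map(0.98 * ref, ref, px_per_mm=4.0,
                                        pedestal=0.0)
        assert loss.mean() == pytest.approx(0.02)
        assert replace is True

    def test_localized_loss_is_area_weighted(self):
        ref = np.full((40, 40), 400.0)
        cur = ref.copy()
        cur[:4, :] *= 0.95  # 5% deep over 10% of the area
        loss, replace = degradation_map(cur, ref, px_per_mm=4.0, pedestal=0.0)
        assert loss.mean() == pytest.approx(0.005)
        assert replace is False

    def test_nonpositive_reference_rejected(self):
        ref = np.zeros((8, 8))
        with pytest.raises(DeadRegionError):
            degradation_map(ref, ref, px_per_mm=4.0, pedestal=0.0)


class TestGainChain:
    def test_adc_to_pe_calibration_point(self):
        gc = GainChain(adc_per_pe=2800.0 / 1080.0, pe_per_Gy=1.0)
        assert adc_to_dose(2800.0, gc) == pytest.approx(1080.0)

    def test_pe_to_dose_calibration_point(self):
        gc = GainChain(adc_per_pe=1.0, pe_per_Gy=1080.0 / 0.17)
        assert adc_to_dose(1080.0, gc) == pytest.approx(0.17)

    def test_zero_and_linearity(self):
        gc = GainChain(adc_per_pe=2.5, pe_per_Gy=1000.0)
        assert adc_to_dose(0.0, gc) == 0.0
        assert adc_to_dose(500.0, gc) == pytest.approx(10 * adc_to_dose(50.0, gc))

    def test_unset_gains_rejected(self):
        with pytest.raises(ValueError):
            adc_to_dose(100.0, None)
        with pytest.raises(ValueError):
            GainChain(adc_per_pe=0.0, pe_per_Gy=1.0)
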