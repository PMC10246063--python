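"""Frame-simulator statistics, determinism and dose-ledger tests."""

import numpy as np
import pytest
from dataclasses import replace

from scintimon.beam import PulseStructure
from scintimon.geometry import oblique_view_homography
from scintimon.simulate import (
    BeamSpot,
    SceneTruth,
    SensorModel,
    VignetteModel,
    cam_e_like,
    cam_p_like,
    expected_pe_map,
    render_frame,
    simulate_pulse_train,
    simulate_scan,
    vignette_factor,
)


def noise_adc(sensor):
    return sensor.adc_per_pe * sensor.read_noise_e


class TestRenderFrame:
    def test_noise_only_frame_stays_near_pedestal(self, contained_truth, small_sensor):
        dark = replace(contained_truth,
                       beam=replace(contained_truth.beam, total_pe=0.0))
        f = render_frame(dark, small_sensor, seed=7)
        dev = np.abs(f.pixels.astype(float) - small_sensor.pedestal_adc)
        assert dev.max() <= 6 * noise_adc(small_sensor)

    def test_same_seed_bit_identical(self, contained_truth, small_sensor):
        a = render_frame(contained_truth, small_sensor, seed=42)
        b = render_frame(contained_truth, small_sensor, seed=42)
        assert np.array_equal(a.pixels, b.pixels)
        c = render_frame(contained_truth, small_sensor, seed=43)
        assert not np.array_equal(a.pixels, c.pixels)

    def test_total_signal_conserves_injected_yield(self, contained_truth, small_sensor):
        f = render_frame(contained_truth, small_sensor, seed=3)
        est = (f.pixels.astype(float) - small_sensor.pedestal_adc).sum() \
            / small_sensor.adc_per_pe
        assert abs(est - 1e6) < 3 * np.sqrt(1e6)

    def test_yield_estimator_unbiased_over_seeds(self, small_sensor, compact_spot):
        truth = SceneTruth(
            beam=replace(compact_spot, total_pe=1e5),
            homography=oblique_view_homography(0.0, 4.0, (80, 60)),
            active_halfwidth_mm=14.0)
        ests = []
        for seed in range(100):
            f = render_frame(truth, small_sensor, seed=seed)
            ests.append((f.pixels.astype(float) - 100.0).sum()
                        / small_sensor.adc_per_pe)
        ests = np.asarray(ests)
        se = ests.std(ddof=1) / 10.0
        assert abs(ests.mean() - 1e5) < 4 * se
        assert abs(ests.mean() - 1e5) / 1e5 < 3 / np.sqrt(1e5)

    def test_dark_corner_outside_active_area_has_no_beam(self, compact_spot):
        # oblique view leaves sensor corners mapping outside the scintillator
        sensor = SensorModel(160, 120, pedestal_adc=100.0)
        truth = SceneTruth(beam=replace(compact_spot, total_pe=1e7),
                           homography=oblique_view_homography(40.0, 2.0, (80, 60)),
                           active_halfwidth_mm=10.0)
        mu, _ = expected_pe_map(truth, sensor)
        corner = np.s_[:10, :10]
        assert mu[corner].max() == 0.0
        f = render_frame(truth, sensor, seed=5)
        dev = np.abs(f.pixels[corner].astype(float) - 100.0)
        assert dev.max() <= 6 * noise_adc(sensor)

    def test_saturation_flag(self, compact_spot):
        sensor = SensorModel(64, 48, adc_bits=8, adc_per_pe=10.0, pedestal_adc=20.0)
        truth = SceneTruth(beam=replace(compact_spot, total_pe=1e7),
                           homography=oblique_view_homography(0.0, 2.0, (32, 24)),
                           active_halfwidth_mm=14.0)
        f = render_frame(truth, sensor, seed=1)
        assert f.meta["saturated"] is True
        assert f.pixels.max() == sensor.adc_max

    def test_roi_frame_shape(self):
        sensor = cam_p_like()
        assert sensor.frame_shape == (212, 212)
        assert 44000 < 212 * 212 < 46000

    def test_cam_e_gain_matches_calibration_signal(self):
        # 2800 ADC at the beam peak corresponds to 1080 PE
        assert cam_e_like().adc_per_pe * 1080 == pytest.approx(2800.0)


class TestVignette:
    def test_reference_point_unity(self, contained_truth):
        truth = replace(contained_truth,
                        vignette=VignetteModel(lens_mm=(0, 0, 100),
                                               ref_point_mm=(0, 0)))
        center_px = truth.homography.map(np.array([0.0, 0.0]))
        assert vignette_factor(center_px, truth) == pytest.approx(1.0)

    def test_inverse_square_at_double_distance(self):
        v = VignetteModel(lens_mm=(0, 0, 100.0), ref_point_mm=(0, 0))
        # beam-plane point at 3D distance 200 = 2 x r_ref
        x = np.sqrt(200.0**2 - 100.0**2)
        assert v.factor(x, 0.0) == pytest.approx(0.25)

    def test_monotone_decrease_along_ray(self):
        v = VignetteModel(lens_mm=(0, 0, 150.0), ref_point_mm=(0, 0))
        r = np.linspace(0, 80, 50)
        f = v.factor(r, 0.3 * r)
        assert np.all(np.diff(f) < 0)


class TestScan:
    def test_positions_and_metadata(self, contained_truth, small_sensor):
        positions = np.arange(-8.0, 9.0, 1.0)  # 17 x 1 mm steps
        frames = simulate_scan(contained_truth, small_sensor, positions, seed=2)
        assert len(frames) == 17
        xs = [f.meta["commanded_position_mm"][0] for f in frames]
        assert np.allclose(np.diff(xs), 1.0)

    def test_empty_positions(self, contained_truth, small_sensor):
        assert simulate_scan(contained_truth, small_sensor, [], seed=0) == []

    def test_outside_active_area_rejected(self, contained_truth, small_sensor):
        with pytest.raises(ValueError, match="active area"):
            simulate_scan(contained_truth, small_sensor, [100.0], seed=0)

    def test_deterministic_under_seed(self, contained_truth, small_sensor):
        a = simulate_scan(contained_truth, small_sensor, [0.0, 1.0], seed=9)
        b = simulate_scan(contained_truth, small_sensor, [0.0, 1.0], seed=9)
        assert all(np.array_equal(x.pixels, y.pixels) for x, y in zip(a, b))


class TestPulseTrain:
    def test_ledger_totals_hardness_schedule(self, contained_truth, small_sensor):
        ps = PulseStructure(dose_per_pulse_Gy=8.0, pulse_width_s=1e-9,
                            rep_rate_Hz=30.0, duration_s=900.0)
        frames, ledger = simulate_pulse_train(contained_truth, small_sensor, ps,
                                              seed=0, frame_stride=27000)
        assert len(ledger) == 27000
        assert ledger["cumulative_kGy"].iloc[-1] == pytest.approx(216.0)
        assert len(frames) == 1

    def test_stable_beam_frames_statistically_identical(self, contained_truth,
                                                        small_sensor):
        ps = PulseStructure(1.0, 1e-9, 100.0, 0.1)
        frames, _ = simulate_pulse_train(contained_truth, small_sensor, ps, seed=4)
        sums = [(f.pixels.astype(float) - 100).sum() for f in frames]
        assert np.std(sums) / np.mean(sums) < 5e-3  # Poisson scale at 1e6 PE

    def test_degradation_scales_final_yield(self, small_sensor, compact_spot):
        truth = SceneTruth(beam=compact_spot,
                           homography=oblique_view_homography(0.0, 4.0, (80, 60)),
                           active_halfwidth_mm=14.0)
        rate, n = 0.002, 200
        ps = PulseStructure(dose_per_pulse_Gy=500.0, pulse_width_s=1e-9,
                            rep_rate_Hz=100.0, duration_s=2.0)  # 100 kGy total
        frames, ledger = simulate_pulse_train(truth, small_sensor, ps,
                                              degradation_rate_per_kGy=rate,
                                              seed=11, frame_stride=n - 1)
        first, last = frames[0], frames[-1]
        d_last = ledger["cumulative_kGy"].iloc[-2]  # dose before the last pulse
        # peak pixels degrade by 1 - rate x dose; off-peak pixels see less
        # local fluence, so the expected block ratio is the mu-weighted mean
        mu, rel = expected_pe_map(truth, small_sensor)
        core = np.s_[56:64, 76:84]
        expected = float((mu[core] * (1 - rate * d_last * rel[core])).sum()
                         / mu[core].sum())
        r_first = first.pixels[core].astype(float).sum() - 100.0 * 64
        r_last = last.pixels[core].astype(float).sum() - 100.0 * 64
        assert r_last / r_first == pytest.approx(expected, rel=0.02)
        assert 1 - rate * d_last == pytest.approx(expected, abs=0.05)

    def test_degradation_clamped_with_warning(self, contained_truth, small_sensor):
        ps = PulseStructure(dose_per_pulse_Gy=1000.0, pulse_width_s=1e-9,
                            rep_rate_Hz=100.0, duration_s=0.1)
        with pytest.warns(UserWarning, match="clamped"):
            frames, _ = simulate_pulse_train(contained_truth, small_sensor, ps,
                                             degradation_rate_per_kGy=0.5,
                                             seed=0, frame_stride=9)
        # the beam core is fully quenched in the last frame: noise only there
        core = frames[-1].pixels[56:64, 76:84].astype(float) - 100.0
        assert np.abs(core).max() <= 6 * noise_adc(small_sensor)

    def test_negative_rates_rejected(self, contained_truth, small_sensor):
        ps = PulseStructure(1.0, 1e-9, 10.0, 0.1)
        with pytest.raises(ValueError):
            simulate_pulse_train(contained_truth, small_sensor, ps,
                                 degradation_rate_per_kGy=-1.0, seed=0)
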