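import numpy as np
import pytest

from scintimon.beam import DoubleGaussianProfile
from scintimon.geometry import oblique_view_homography
from scintimon.simulate import BeamSpot, SceneTruth, SensorModel


@pytest.fixture
def small_sensor() -> SensorModel:
    """Desk-scale sensor: 160x120 px; 16-bit ADC so bright compact spots
    do not clip."""
    return SensorModel(width_px=160, height_px=120, adc_bits=16,
                       adc_per_pe=2.593, read_noise_e=2.5, pedestal_adc=100.0)


@pytest.fixture
def compact_spot() -> BeamSpot:
    """A beam spot fully contained in the small sensor's field of view."""
    p = DoubleGaussianProfile(center_mm=0.0, amp_narrow=1.0, sigma_narrow_mm=1.0,
                              amp_wide=0.1, sigma_wide_mm=3.0)
    return BeamSpot(p, p, total_pe=1e6)


@pytest.fixture
def contained_truth(small_sensor, compact_spot) -> SceneTruth:
    """Head-on view, 4 px/mm, beam centered on the sensor."""
    h = oblique_view_homography(tilt_deg=0.0, px_per_mm=4.0,
                                center_px=(small_sensor.width_px / 2,
                                           small_sensor.height_px / 2))
    return SceneTruth(beam=compact_spot, homography=h, active_halfwidth_mm=14.0)


def residual_of(frame) -> np.ndarray:
    return np.clip(frame.pixels.astype(float) - frame.meta["pedestal_adc"], 0, None)
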