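"""Synthetic scintillator-camera frame generation.

Emulates the monitor's imaging chain at the statistics level: a
double-Gaussian beam spot deposits dose in the scintillator, the emitted
light is projected onto the sensor through the oblique-view homography
(with the Jacobian as density weight) and attenuated by the inverse-square
optical-path vignette; each pixel then draws Poisson photoelectrons,
Gaussian readout noise, is scaled by the ADC gain, offset by the pedestal
and quantized.  Sparse single-pixel background hits model direct x-ray
(bremsstrahlung) conversions in the sensor.

Everything is driven by an explicit seed: the same inputs produce
bit-identical frames.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .beam import DoubleGaussianProfile, PulseStructure, eval_profile
from .geometry import Homography

__all__ = [
    "SensorModel",
    "BeamSpot",
    "VignetteModel",
    "SceneTruth",
    "Frame",
    "cam_e_like",
    "cam_p_like",
    "expected_pe_map",
    "render_frame",
    "vignette_factor",
    "simulate_scan",
    "simulate_pulse_train",
]


@dataclass(frozen=True)
class SensorModel:
    """CMOS sensor and digitization parameters.

    ``roi`` is an optional (x0, y0, width, height) sub-window in pixel
    coordinates; frames then have the ROI shape.
    """

    width_px: int
    height_px: int
    adc_bits: int = 12
    adc_per_pe: float = 2.593
    read_noise_e: float = 2.5
    pedestal_adc: float = 100.0
    roi: tuple[int, int, int, int] | None = None

    def __post_init__(self) -> None:
        if self.adc_per_pe <= 0:
            raise ValueError("adc_per_pe must be > 0")
        if self.read_noise_e < 0:
            raise ValueError("read_noise_e must be >= 0")
        if self.roi is not None:
            x0, y0, w, h = self.roi
            if x0 < 0 or y0 < 0 or x0 + w > self.width_px or y0 + h > self.height_px:
                raise ValueError("roi must lie within the sensor extent")

    @property
    def adc_max(self) -> int:
        return 2**self.adc_bits - 1

    @property
    def frame_shape(self) -> tuple[int, int]:
        if self.roi is not None:
            return (self.roi[3], self.roi[2])
        return (self.height_px, self.width_px)

    @property
    def origin_px(self) -> tuple[int, int]:
        return (self.roi[0], self.roi[1]) if self.roi is not None else (0, 0)


def cam_e_like(**overrides) -> SensorModel:
    """Low-noise ~2 MP electron-beam camera (gain from 2800 ADC ~ 1080 PE)."""
    params = dict(
        width_px=1920, height_px=1080, adc_bits=12,
        adc_per_pe=2800.0 / 1080.0, read_noise_e=2.5, pedestal_adc=100.0,
    )
    params.update(overrides)
    return SensorModel(**params)


def cam_p_like(**overrides) -> SensorModel:
    """1 MP proton-beam camera read out in a ~45 kpx ROI at 20 kHz."""
    params = dict(
        width_px=1024, height_px=1024, adc_bits=12,
        adc_per_pe=2.0, read_noise_e=15.0, pedestal_adc=100.0,
        roi=(406, 406, 212, 212),
    )
    params.update(overrides)
    return SensorModel(**params)


@dataclass(frozen=True)
class BeamSpot:
    """Separable 2D beam: one double Gaussian per transverse axis."""

    profile_x: DoubleGaussianProfile
    profile_y: DoubleGaussianProfile
    total_pe: float

    def __post_init__(self) -> None:
        if self.total_pe < 0:
            raise ValueError("total_pe must be >= 0")

    def density(self, x_mm, y_mm):
        """Normalized 2D density (1/mm^2) at beam-plane points."""
        fx = eval_profile(self.profile_x, x_mm) / self.profile_x.integral
        fy = eval_profile(self.profile_y, y_mm) / self.profile_y.integral
        return fx * fy

    @property
    def center_mm(self) -> tuple[float, float]:
        return (self.profile_x.center_mm, self.profile_y.center_mm)

    def translated(self, dx_mm: float, dy_mm: float) -> "BeamSpot":
        return BeamSpot(
            replace(self.profile_x, center_mm=self.profile_x.center_mm + dx_mm),
            replace(self.profile_y, center_mm=self.profile_y.center_mm + dy_mm),
            self.total_pe,
        )


@dataclass(frozen=True)
class VignetteModel:
    """Inverse-square light-collection falloff.

    ``lens_mm`` is the lens position in beam-plane coordinates with a
    height above the plane: (x, y, z).  The factor at a scintillator
    point p is (r_ref / r(p))^2 with r the 3D point-to-lens distance,
    normalized to 1 at ``ref_point_mm``.
    """

    lens_mm: tuple[float, float, float] = (0.0, 0.0, 400.0)
    ref_point_mm: tuple[float, float] = (0.0, 0.0)

    def factor(self, x_mm, y_mm):
        lx, ly, lz = self.lens_mm
        rx, ry = self.ref_point_mm
        r2 = (np.asarray(x_mm) - lx) ** 2 + (np.asarray(y_mm) - ly) ** 2 + lz**2
        r2_ref = (rx - lx) ** 2 + (ry - ly) ** 2 + lz**2
        return r2_ref / r2


@dataclass(frozen=True)
class SceneTruth:
    """Ground truth for one rendered scene."""

    beam: BeamSpot
    homography: Homography = field(default_factory=Homography.identity)
    vignette: VignetteModel | None = None
    background_hit_rate: float = 0.0
    background_hit_amp_adc: float = 50.0
    active_halfwidth_mm: float = 50.0

    def __post_init__(self) -> None:
        if self.background_hit_rate < 0:
            raise ValueError("background_hit_rate must be >= 0")


@dataclass
class Frame:
    """A digitized camera frame: ADC counts plus acquisition metadata."""

    pixels: np.ndarray
    meta: dict = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def _pixel_grid(sensor: SensorModel) -> tuple[np.ndarray, np.ndarray]:
    x0, y0 = sensor.origin_px
    h, w = sensor.frame_shape
    xs = np.arange(x0, x0 + w, dtype=float)
    ys = np.arange(y0, y0 + h, dtype=float)
    return np.meshgrid(xs, ys)


def expected_pe_map(truth: SceneTruth, sensor: SensorModel) -> tuple[np.ndarray, np.ndarray]:
    """Expected photoelectrons per pixel and the relative beam intensity.

    Returns ``(mu, rel)``.  ``rel`` is the local beam fluence normalized
    so that the fluence-weighted mean over the beam core (the FW3QM disc
    of the spot) is 1: the dose ledger quotes the core dose per pulse,
    so local dose = DPP x rel.  If the core does not project onto the
    sensor, ``rel`` falls back to peak normalization.
    """
    px, py = _pixel_grid(sensor)
    pts = np.column_stack([px.ravel(), py.ravel()])
    inv = truth.homography.inverse()
    beam_xy = inv.map(pts)
    jac = inv.jacobian_det(pts)  # mm^2 per px^2
    x_mm = beam_xy[:, 0].reshape(px.shape)
    y_mm = beam_xy[:, 1].reshape(px.shape)
    density = truth.beam.density(x_mm, y_mm)
    # light only comes from the scintillator active area
    active = (np.abs(x_mm) <= truth.active_halfwidth_mm) & (
        np.abs(y_mm) <= truth.active_halfwidth_mm
    )
    mu = truth.beam.total_pe * density * jac.reshape(px.shape)
    mu = np.where(active, mu, 0.0)
    if truth.vignette is not None:
        mu = mu * truth.vignette.factor(x_mm, y_mm)
    peak = truth.beam.density(*truth.beam.center_mm)
    rel = np.where(active, density / peak, 0.0)
    core = _core_mask(truth, x_mm, y_mm) & active
    if core.any() and density[core].sum() > 0:
        # fluence-weighted core mean -> 1, so core signal tracks DPP x rel
        w = density[core]
        rel = rel * (peak * w.sum() / (density[core] * w).sum())
    return mu, rel


def _core_mask(truth: SceneTruth, x_mm: np.ndarray, y_mm: np.ndarray) -> np.ndarray:
    """Beam-core (FW3QM disc) membership of beam-plane points."""
    from .beam import NoPeakError, fw3qm

    prof = truth.beam.profile_x
    span = 3.0 * prof.sigma_narrow_mm
    xs = np.linspace(prof.center_mm - span, prof.center_mm + span, 2001)
    try:
        width = fw3qm(xs, eval_profile(prof, xs))
    except NoPeakError:
        return np.zeros_like(x_mm, dtype=bool)
    cx, cy = truth.beam.center_mm
    return (x_mm - cx) ** 2 + (y_mm - cy) ** 2 <= (width / 2.0) ** 2


def _digitize(mu: np.ndarray, sensor: SensorModel, rng: np.random.Generator,
              hit_rate: float, hit_amp: float) -> np.ndarray:
    counts = rng.poisson(np.clip(mu, 0.0, None)).astype(float)
    if sensor.read_noise_e > 0:
        counts = counts + rng.normal(0.0, sensor.read_noise_e, size=counts.shape)
    adc = sensor.pedestal_adc + sensor.adc_per_pe * counts
    if hit_rate > 0:
        n = rng.poisson(hit_rate)
        if n > 0:
            h, w = counts.shape
            rows = rng.integers(0, h, size=n)
            cols = rng.integers(0, w, size=n)
            amps = rng.exponential(hit_amp, size=n)
            np.add.at(adc, (rows, cols), amps)
    return np.clip(np.rint(adc), 0, sensor.adc_max).astype(np.uint16)


def render_frame(truth: SceneTruth, sensor: SensorModel, seed: int,
                 exposure_s: float = 1.0, frame_index: int = 0) -> Frame:
    """Render one frame; bit-identical for identical inputs and seed."""
    rng = np.random.default_rng(seed)
    mu, _ = expected_pe_map(truth, sensor)
    pixels = _digitize(mu, sensor, rng, truth.background_hit_rate,
                       truth.background_hit_amp_adc)
    saturated = _saturation_flag(pixels, mu, sensor)
    return Frame(
        pixels,
        meta={
            "exposure_s": exposure_s,
            "frame_index": frame_index,
            "pulse_tag": frame_index,
            "pedestal_adc": sensor.pedestal_adc,
            "rng_seed": int(seed),
            "saturated": saturated,
        },
    )


def _saturation_flag(pixels: np.ndarray, mu: np.ndarray, sensor: SensorModel) -> bool:
    beam_px = mu > 0
    if not beam_px.any():
        return False
    frac = np.mean(pixels[beam_px] >= sensor.adc_max - 1)
    return bool(frac > 0.01)


def vignette_factor(pixel_xy, truth: SceneTruth):
    """Inverse-square vignette multiplier at sensor pixel coordinates."""
    if truth.vignette is None:
        return np.ones(np.atleast_2d(pixel_xy).shape[0]) if np.asarray(pixel_xy).ndim > 1 else 1.0
    beam_xy = truth.homography.inverse().map(pixel_xy)
    pts = np.atleast_2d(beam_xy)
    out = truth.vignette.factor(pts[:, 0], pts[:, 1])
    if np.asarray(pixel_xy).ndim == 1:
        return float(out[0])
    return out


def simulate_scan(truth: SceneTruth, sensor: SensorModel, positions_mm,
                  seed: int, exposure_s: float = 1.0) -> list[Frame]:
    """One frame per commanded beam position (stepper-scan emulation).

    ``positions_mm`` entries are either x offsets (scalars) or (x, y)
    offsets applied to the beam center in beam-plane mm.
    """
    frames: list[Frame] = []
    seeds = np.random.SeedSequence(seed).generate_state(max(len(positions_mm), 1))
    base_cx, base_cy = truth.beam.center_mm
    for i, pos in enumerate(positions_mm):
        if np.isscalar(pos):
            dx, dy = float(pos), 0.0
        else:
            dx, dy = float(pos[0]), float(pos[1])
        if (abs(base_cx + dx) > truth.active_halfwidth_mm
                or abs(base_cy + dy) > truth.active_halfwidth_mm):
            raise ValueError(f"commanded position {pos} outside the active area")
        shifted = replace(truth, beam=truth.beam.translated(dx, dy))
        frame = render_frame(shifted, sensor, int(seeds[i]),
                             exposure_s=exposure_s, frame_index=i)
        frame.meta["commanded_position_mm"] = (dx, dy)
        frames.append(frame)
    return frames


def simulate_pulse_train(
    truth: SceneTruth,
    sensor: SensorModel,
    ps: PulseStructure,
    degradation_rate_per_kGy: float = 0.0,
    fluctuation_rms: float = 0.0,
    seed: int = 0,
    frame_stride: int = 1,
    exposure_s: float = 1e-3,
) -> tuple[list[Frame], pd.DataFrame]:
    """Pulse-by-pulse frame stream with delivered-dose ledger.

    Each pulse's light yield is scaled by a common Gaussian beam-current
    fluctuation and by fluence-proportional scintillator degradation:
    the local yield factor is 1 - rate x (cumulative local dose in kGy),
    where the local dose scales with the beam intensity at that point.
    Dose is accounted for every pulse; frames are materialized every
    ``frame_stride``-th pulse so long schedules stay tractable.
    """
    if degradation_rate_per_kGy < 0 or fluctuation_rms < 0:
        raise ValueError("rates must be >= 0")
    if frame_stride < 1:
        raise ValueError("frame_stride must be >= 1")
    rng = np.random.default_rng(seed)
    mu_base, rel = expected_pe_map(truth, sensor)
    n_pulses = ps.n_pulses
    frames: list[Frame] = []
    rows = []
    cum_kGy = 0.0
    clamp_warned = False
    for k in range(n_pulses):
        fluct = 1.0 + (rng.normal(0.0, fluctuation_rms) if fluctuation_rms > 0 else 0.0)
        damage = 1.0 - degradation_rate_per_kGy * cum_kGy * rel
        if damage.min() < 0:
            if not clamp_warned:
                warnings.warn("degradation drove the yield negative; clamped at 0")
                clamp_warned = True
            damage = np.clip(damage, 0.0, None)
        if k % frame_stride == 0:
            mu = mu_base * fluct * damage
            pixels = _digitize(mu, sensor, rng, truth.background_hit_rate,
                               truth.background_hit_amp_adc)
            frames.append(Frame(pixels, meta={
                "exposure_s": exposure_s,
                "frame_index": len(frames),
                "pulse_tag": k,
                "pedestal_adc": sensor.pedestal_adc,
                "rng_seed": int(seed),
                "saturated": _saturation_flag(pixels, mu, sensor),
                "cumulative_kGy": cum_kGy,
            }))
        cum_kGy += ps.dose_per_pulse_Gy / 1000.0
        rows.append((k, ps.dose_per_pulse_Gy, cum_kGy, fluct, k % frame_stride == 0))
    ledger = pd.DataFrame(
        rows, columns=["pulse", "dpp_Gy", "cumulative_kGy", "fluctuation", "rendered"]
    )
    return frames, ledger
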