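"""Scenario configuration: YAML schema, validation and object builders.

A scenario file describes the sensor, the beam scene, the pulse schedule
or scan, the analysis options and the gain chain.  Unknown keys are
rejected by name so typos fail loudly.
"""

from __future__ import annotations

import yaml

from .beam import DoubleGaussianProfile, PulseStructure
from .calibration import GainChain
from .geometry import Homography, oblique_view_homography
from .pipeline import PipelineConfig
from .simulate import (
    BeamSpot,
    SceneTruth,
    SensorModel,
    VignetteModel,
    cam_e_like,
    cam_p_like,
)

__all__ = ["ConfigError", "ScenarioConfig", "load_scenario"]


class ConfigError(ValueError):
    """Invalid or unknown configuration content."""


_SCHEMA = {
    "sensor": {"preset", "width_px", "height_px", "adc_bits", "adc_per_pe",
               "read_noise_e", "pedestal_adc", "roi"},
    "beam": {"center_mm", "amp_narrow", "sigma_narrow_mm", "amp_wide",
             "sigma_wide_mm", "total_pe", "y"},
    "homography": {"matrix", "tilt_deg", "px_per_mm", "center_px", "view_distance_mm"},
    "vignette": {"lens_mm", "ref_point_mm"},
    "background": {"hit_rate", "hit_amp_adc"},
    "scene": {"active_halfwidth_mm"},
    "pulses": {"dose_per_pulse_Gy", "pulse_width_s", "rep_rate_Hz", "duration_s",
               "degradation_rate_per_kGy", "fluctuation_rms", "frame_stride"},
    "scan": {"start_mm", "step_mm", "n_positions"},
    "analysis": {"k_sigma", "box_px", "noise_sigma_adc", "dose_rate_Gy_per_s",
                 "response_interval_s", "frame_period_s"},
    "gains": {"adc_per_pe", "pe_per_Gy"},
    "n_frames": None,
    "seed": None,
    "exposure_s": None,
}

_BEAM_AXIS_KEYS = {"center_mm", "amp_narrow", "sigma_narrow_mm", "amp_wide", "sigma_wide_mm"}


def _check_keys(section: str, data: dict, allowed: set) -> None:
    unknown = set(data) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) in '{section}': {sorted(unknown)}")


class ScenarioConfig:
    """Validated scenario; builder methods construct the model objects."""

    def __init__(self, data: dict):
        if not isinstance(data, dict):
            raise ConfigError("scenario must be a mapping")
        _check_keys("scenario", data, set(_SCHEMA))
        for section, allowed in _SCHEMA.items():
            if allowed is not None and section in data:
                if not isinstance(data[section], dict):
                    raise ConfigError(f"'{section}' must be a mapping")
                _check_keys(section, data[section], allowed)
        if "beam" in data and "y" in data["beam"]:
            _check_keys("beam.y", data["beam"]["y"], _BEAM_AXIS_KEYS)
        self.data = data

    @property
    def seed(self) -> int:
        return int(self.data.get("seed", 0))

    @property
    def n_frames(self) -> int:
        return int(self.data.get("n_frames", 1))

    @property
    def exposure_s(self) -> float:
        return float(self.data.get("exposure_s", 1.0))

    def build_sensor(self) -> SensorModel:
        cfg = dict(self.data.get("sensor", {}))
        preset = cfg.pop("preset", None)
        if "roi" in cfg and cfg["roi"] is not None:
            cfg["roi"] = tuple(cfg["roi"])
        if preset == "cam_e":
            return cam_e_like(**cfg)
        if preset == "cam_p":
            return cam_p_like(**cfg)
        if preset is not None:
            raise ConfigError(f"unknown sensor preset {preset!r}")
        return SensorModel(**cfg)

    def build_homography(self) -> Homography:
        cfg = self.data.get("homography", {})
        if "matrix" in cfg:
            import numpy as np

            return Homography(np.asarray(cfg["matrix"], dtype=float).reshape(3, 3))
        sensor = self.build_sensor()
        h, w = sensor.frame_shape
        x0, y0 = sensor.origin_px
        default_center = (x0 + w / 2.0, y0 + h / 2.0)
        return oblique_view_homography(
            tilt_deg=float(cfg.get("tilt_deg", 0.0)),
            px_per_mm=float(cfg.get("px_per_mm", 4.0)),
            center_px=tuple(cfg.get("center_px", default_center)),
            view_distance_mm=float(cfg.get("view_distance_mm", 400.0)),
        )

    def build_truth(self) -> SceneTruth:
        beam = dict(self.data.get("beam", {}))
        y_over = beam.pop("y", {})
        center = beam.pop("center_mm", (0.0, 0.0))
        if not isinstance(center, (list, tuple)):
            center = (float(center), 0.0)
        total_pe = float(beam.pop("total_pe", 1e5))
        axis = dict(amp_narrow=0.92, sigma_narrow_mm=2.11, amp_wide=0.106,
                    sigma_wide_mm=26.2)
        axis.update(beam)
        px = DoubleGaussianProfile(center_mm=float(center[0]), **axis)
        axis_y = dict(axis)
        axis_y.update({k: v for k, v in y_over.items() if k != "center_mm"})
        py = DoubleGaussianProfile(
            center_mm=float(y_over.get("center_mm", center[1])), **axis_y)
        vignette = None
        if "vignette" in self.data:
            v = self.data["vignette"]
            vignette = VignetteModel(
                lens_mm=tuple(v.get("lens_mm", (0.0, 0.0, 400.0))),
                ref_point_mm=tuple(v.get("ref_point_mm", (0.0, 0.0))))
        bg = self.data.get("background", {})
        scene = self.data.get("scene", {})
        return SceneTruth(
            beam=BeamSpot(px, py, total_pe),
            homography=self.build_homography(),
            vignette=vignette,
            background_hit_rate=float(bg.get("hit_rate", 0.0)),
            background_hit_amp_adc=float(bg.get("hit_amp_adc", 50.0)),
            active_halfwidth_mm=float(scene.get("active_halfwidth_mm", 50.0)),
        )

    def build_pulse_structure(self) -> PulseStructure | None:
        if "pulses" not in self.data:
            return None
        p = self.data["pulses"]
        return PulseStructure(
            dose_per_pulse_Gy=float(p.get("dose_per_pulse_Gy", 0.0)),
            pulse_width_s=float(p.get("pulse_width_s", 1e-9)),
            rep_rate_Hz=float(p.get("rep_rate_Hz", 30.0)),
            duration_s=float(p.get("duration_s", 1.0)),
        )

    def pulse_options(self) -> dict:
        p = self.data.get("pulses", {})
        return {
            "degradation_rate_per_kGy": float(p.get("degradation_rate_per_kGy", 0.0)),
            "fluctuation_rms": float(p.get("fluctuation_rms", 0.0)),
            "frame_stride": int(p.get("frame_stride", 1)),
        }

    def scan_positions(self) -> list[float] | None:
        if "scan" not in self.data:
            return None
        s = self.data["scan"]
        start = float(s.get("start_mm", 0.0))
        step = float(s.get("step_mm", 1.0))
        n = int(s.get("n_positions", 1))
        return [start + i * step for i in range(n)]

    def build_gains(self) -> GainChain | None:
        if "gains" not in self.data:
            return None
        g = self.data["gains"]
        return GainChain(adc_per_pe=float(g["adc_per_pe"]),
                         pe_per_Gy=float(g["pe_per_Gy"]))

    def build_pipeline_config(self) -> PipelineConfig:
        a = self.data.get("analysis", {})
        sensor = self.build_sensor()
        default_noise = sensor.adc_per_pe * max(sensor.read_noise_e, 1.0)
        return PipelineConfig(
            k_sigma=float(a.get("k_sigma", 5.0)),
            noise_sigma_adc=float(a.get("noise_sigma_adc", default_noise)),
            box_px=int(a.get("box_px", 17)),
            gains=self.build_gains(),
            homography=self.build_homography(),
            dose_rate_Gy_per_s=float(a.get("dose_rate_Gy_per_s", 100.0)),
            response_interval_s=float(a.get("response_interval_s", 50e-6)),
            frame_period_s=float(a.get("frame_period_s", 50e-6)),
        )


def load_scenario(path) -> ScenarioConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        data = {}
    return ScenarioConfig(data)
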