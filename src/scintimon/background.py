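"""Background and signal budget calculators.

Projects the per-frame optical signal and the direct-hit sensor
backgrounds for FLASH delivery scenarios: bremsstrahlung photons for
pulsed electron beams (signal and background scale with dose per pulse,
so backgrounds fall as the same dose is spread over more pulses), fast
neutrons for proton operation, and the shield-effectiveness bookkeeping
of the measured background-to-signal ratios.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .beam import ELEMENTARY_CHARGE_C

__all__ = [
    "FlashDeliverySpec",
    "NeutronEnvironment",
    "BARN_CM2",
    "flash_frame_budget",
    "neutron_hits",
    "shield_summary",
]

BARN_CM2 = 1e-24


@dataclass(frozen=True)
class FlashDeliverySpec:
    """A FLASH electron delivery: total dose spread over a pulse train."""

    total_dose_Gy: float = 10.0
    delivery_time_s: float = 0.2
    pulse_rate_Hz: float = 100.0
    pe_per_Gy: float = 1080.0 / 0.17
    bkg_fraction: float = 0.009
    dark_noise_e: float = 2.3

    def __post_init__(self) -> None:
        for name in ("total_dose_Gy", "delivery_time_s", "pulse_rate_Hz",
                     "pe_per_Gy", "bkg_fraction", "dark_noise_e"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.pulse_rate_Hz * self.delivery_time_s < 1:
            raise ValueError("delivery must contain at least one pulse")


@dataclass(frozen=True)
class NeutronEnvironment:
    """Fast-neutron environment of the sensor during proton delivery."""

    fluence_per_proton_cm2: float = 3e-5
    sensor_area_cm2: float = 0.07
    beam_current_nA: float = 800.0
    frame_time_s: float = 50e-6
    sensor_thickness_cm: float = 0.075
    cross_section_barn: float = 1.2
    number_density_cm3: float = 5e22

    def __post_init__(self) -> None:
        for name in ("fluence_per_proton_cm2", "sensor_area_cm2", "beam_current_nA",
                     "frame_time_s", "sensor_thickness_cm", "cross_section_barn",
                     "number_density_cm3"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def flash_frame_budget(spec: FlashDeliverySpec, pulse_rates_Hz=None) -> pd.DataFrame:
    """Per-frame signal and bremsstrahlung-background budget.

    One row per pulse rate (default: the delivery's own rate).  Columns:
    n_pulses, dpp_Gy, signal_pe (rounded to the nearest PE; the exact
    value in signal_pe_exact), bkg_pe (bkg_fraction x signal, rounded
    to the nearest PE) and bkg_over_dark (one decimal), matching the
    conventions of a printed budget table.
    """
    rates = [spec.pulse_rate_Hz] if pulse_rates_Hz is None else list(pulse_rates_Hz)
    rows = []
    for rate in rates:
        n_pulses = rate * spec.delivery_time_s
        if n_pulses < 1:
            raise ValueError(f"zero pulses at rate {rate} Hz")
        dpp = spec.total_dose_Gy / n_pulses
        signal = spec.pe_per_Gy * dpp
        bkg = round(spec.bkg_fraction * signal)
        rows.append({
            "pulse_rate_Hz": rate,
            "n_pulses": int(round(n_pulses)),
            "dpp_Gy": dpp,
            "signal_pe": int(round(signal)),
            "signal_pe_exact": signal,
            "bkg_pe": bkg,
            "bkg_pe_exact": spec.bkg_fraction * signal,
            "bkg_over_dark": round(bkg / spec.dark_noise_e, 1)
            if spec.dark_noise_e > 0 else np.inf,
        })
    return pd.DataFrame(rows)


def neutron_hits(env: NeutronEnvironment) -> dict:
    """Expected fast-neutron flux on the sensor and resulting hits/frame.

    protons/frame = I_p/e x dt; neutrons/frame = phi x A_sens x protons;
    the interacting fraction Q = tau/lambda with lambda = 1/(sigma eta).
    """
    protons = env.beam_current_nA * 1e-9 / ELEMENTARY_CHARGE_C * env.frame_time_s
    neutrons = env.fluence_per_proton_cm2 * env.sensor_area_cm2 * protons
    sigma_cm2 = env.cross_section_barn * BARN_CM2
    mean_free_path_cm = (
        1.0 / (sigma_cm2 * env.number_density_cm3)
        if sigma_cm2 * env.number_density_cm3 > 0 else np.inf
    )
    q = env.sensor_thickness_cm / mean_free_path_cm
    return {
        "protons_per_frame": protons,
        "neutrons_per_frame": neutrons,
        "interaction_fraction_Q": q,
        "hits_per_frame": neutrons * q,
    }


def _round_half_up(x: float, decimals: int) -> float:
    # eps guards against binary representation of decimal halves
    # (e.g. 2.3/0.4 = 5.749999...) rounding the wrong way
    scale = 10**decimals
    return np.floor(x * scale + 0.5 + 1e-9) / scale


def shield_summary(records: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """Shield effectiveness from paired with/without-shield measurements.

    ``records`` columns: shielded (bool), energy_MeV, bkg_adc,
    signal_adc, and optionally bkg_over_sig_pct (a pre-tabulated
    percentage, used verbatim when present; otherwise computed from the
    ADC pair and rounded half-up to one decimal).  The reduction factor
    per energy is the unshielded over the shielded percentage, one
    decimal; the second return value is the mean factor over energies.
    """
    required = {"shielded", "energy_MeV", "bkg_adc", "signal_adc"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"records missing columns: {sorted(missing)}")
    df = records.copy()
    if "bkg_over_sig_pct" in df.columns:
        pct = df["bkg_over_sig_pct"].astype(float)
    else:
        pct = (df["bkg_adc"] / df["signal_adc"] * 100.0).map(
            lambda v: _round_half_up(v, 1))
    df["bkg_over_sig_pct"] = pct
    rows = []
    for energy, grp in df.groupby("energy_MeV"):
        unsh = grp[~grp["shielded"].astype(bool)]
        sh = grp[grp["shielded"].astype(bool)]
        if len(unsh) != 1 or len(sh) != 1:
            raise ValueError(f"energy {energy}: need exactly one shielded and one "
                             "unshielded record")
        factor = _round_half_up(
            float(unsh["bkg_over_sig_pct"].iloc[0]) / float(sh["bkg_over_sig_pct"].iloc[0]), 1)
        rows.append({
            "energy_MeV": energy,
            "unshielded_pct": float(unsh["bkg_over_sig_pct"].iloc[0]),
            "shielded_pct": float(sh["bkg_over_sig_pct"].iloc[0]),
            "reduction_factor": factor,
        })
    table = pd.DataFrame(rows)
    return table, float(table["reduction_factor"].mean())
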