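"""Offline characterization analyses.

Covers the bench and beam studies used to qualify the monitor: stepper-
scan spatial resolution (RMS of linear-fit residuals), pixel re-binning,
band-averaged beam profiles with double-Gaussian core+tail fits,
profile-vs-profile residual comparison (the film cross-check), the
ratio-of-ratios radiation-hardness trend, and dose-response linearity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .beam import DoubleGaussianProfile

__all__ = [
    "ScanResult",
    "HardnessSeries",
    "LinearityResult",
    "DoubleGaussianFit",
    "FitError",
    "resolution_from_scan",
    "rebin",
    "band_profile",
    "fit_double_gaussian",
    "profile_residual_rms",
    "hardness_analysis",
    "linearity_analysis",
    "region_means",
    "thickness_normalized_signal_ratio",
]


def thickness_normalized_signal_ratio(mean_adc_a: float, thickness_a_mm: float,
                                      mean_adc_b: float, thickness_b_mm: float) -> float:
    """Per-unit-thickness signal ratio of scintillator A over B.

    Used to compare a thin test scintillator against a reference crystal
    of different thickness under the same source: (A/t_A) / (B/t_B).
    """
    if min(thickness_a_mm, thickness_b_mm) <= 0 or mean_adc_b <= 0:
        raise ValueError("thicknesses and reference signal must be > 0")
    return (mean_adc_a / thickness_a_mm) / (mean_adc_b / thickness_b_mm)


class FitError(RuntimeError):
    """Nonlinear fit failed to converge; carries diagnostics."""


@dataclass(frozen=True)
class ScanResult:
    """Linear position-scan calibration and its residual spread."""

    commanded_mm: np.ndarray
    measured_centroids: np.ndarray
    slope: float            # centroid units per mm
    intercept: float
    residual_rms: float     # beam-plane units (mm)

    @property
    def resolution_um(self) -> float:
        return self.residual_rms * 1000.0


@dataclass(frozen=True)
class HardnessSeries:
    """Ratio-of-ratios hardness trend vs cumulative dose."""

    time_s: np.ndarray
    dose_kGy: np.ndarray
    signal_adc: np.ndarray
    control_adc: np.ndarray
    R: np.ndarray
    slope_per_kGy: float
    slope_err_per_kGy: float


@dataclass(frozen=True)
class LinearityResult:
    dpp_Gy: np.ndarray
    signal: np.ndarray
    slope: float
    intercept: float
    fractional_deviation: np.ndarray


@dataclass(frozen=True)
class DoubleGaussianFit:
    profile: DoubleGaussianProfile
    param_errors: dict
    residual_rms_pct: float   # RMS of fit residuals, % of peak
    converged: bool


def resolution_from_scan(commanded_mm, centroids) -> ScanResult:
    """Spatial resolution from a linear stepper scan.

    The measured centroids (any units, e.g. pixels) are regressed on
    the commanded positions; the resolution is the RMS of the fit
    residuals converted to beam-plane mm via the fitted slope.
    """
    x = np.asarray(commanded_mm, dtype=float)
    y = np.asarray(centroids, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 matched points")
    if np.ptp(x) == 0:
        raise ValueError("degenerate scan: all commanded positions equal")
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    rms = float(np.sqrt(np.mean(resid**2)) / abs(slope))
    return ScanResult(x, y, float(slope), float(intercept), rms)


def rebin(pixels, n: int) -> tuple[np.ndarray, bool]:
    """Sum pixels into n x n supercells.

    Edge rows/columns that do not fill a supercell are dropped; the
    returned flag reports whether anything was dropped.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    arr = np.asarray(pixels.pixels if hasattr(pixels, "pixels") else pixels)
    h, w = arr.shape
    nr, nc = h // n, w // n
    if nr == 0 or nc == 0:
        raise ValueError("supercell larger than the frame")
    dropped = (h % n != 0) or (w % n != 0)
    out = arr[: nr * n, : nc * n].astype(np.int64).reshape(nr, n, nc, n).sum(axis=(1, 3))
    return out, dropped


def band_profile(image, axis: str = "x", band_px: int = 10,
                 center: int | None = None) -> np.ndarray:
    """Mean profile over a band of rows (axis='x') or columns (axis='y').

    ``center`` is the band's central row/column index (default: image
    center).  The band must lie fully inside the image.
    """
    arr = np.asarray(image.pixels if hasattr(image, "pixels") else image, dtype=float)
    if axis not in ("x", "y"):
        raise ValueError("axis must be 'x' or 'y'")
    extent = arr.shape[0] if axis == "x" else arr.shape[1]
    if center is None:
        center = extent // 2
    lo = center - band_px // 2
    hi = lo + band_px
    if lo < 0 or hi > extent:
        raise ValueError("band extends outside the image")
    if axis == "x":
        return arr[lo:hi, :].mean(axis=0)
    return arr[:, lo:hi].mean(axis=1)


def _double_gaussian(x, c, a_n, s_n, a_w, s_w):
    return (a_n * np.exp(-((x - c) ** 2) / (2 * s_n**2))
            + a_w * np.exp(-((x - c) ** 2) / (2 * s_w**2)))


def fit_double_gaussian(x_mm, intensity, max_nfev: int = 20000) -> DoubleGaussianFit:
    """Fit a narrow-core + wide-tail double Gaussian to a 1D profile.

    Initializer: center at the profile argmax, narrow sigma from
    FWHM/2.355, tail amplitude 10% of the peak with sigma 10x the core.
    If the optimizer swaps the roles of the two components they are
    swapped back so that sigma_w > sigma_n always holds.
    """
    x = np.asarray(x_mm, dtype=float)
    y = np.asarray(intensity, dtype=float)
    peak = float(y.max())
    if peak <= 0:
        raise FitError("profile has no positive peak")
    c0 = float(x[np.argmax(y)])
    above = x[y >= 0.5 * peak]
    fwhm = float(above.max() - above.min()) if above.size > 1 else float(np.ptp(x)) / 10
    s_n0 = max(fwhm / 2.355, 1e-6)
    p0 = [c0, 0.9 * peak, s_n0, 0.1 * peak, 10 * s_n0]
    bounds = ([x.min(), 0.0, 1e-9, 0.0, 1e-9],
              [x.max(), 2 * peak, np.ptp(x), 2 * peak, 100 * np.ptp(x)])
    try:
        popt, pcov = curve_fit(_double_gaussian, x, y, p0=p0, bounds=bounds,
                               maxfev=max_nfev)
    except RuntimeError as exc:
        raise FitError(f"double-Gaussian fit did not converge: {exc}") from exc
    c, a_n, s_n, a_w, s_w = popt
    perr = np.sqrt(np.clip(np.diag(pcov), 0, None))
    if s_w < s_n:  # components swapped roles
        a_n, a_w = a_w, a_n
        s_n, s_w = s_w, s_n
        perr = perr[[0, 3, 4, 1, 2]]
    if s_w <= s_n:  # degenerate tail (single-Gaussian input)
        s_w = s_n * (1 + 1e-9)
    profile = DoubleGaussianProfile(center_mm=float(c), amp_narrow=float(a_n),
                                    sigma_narrow_mm=float(s_n), amp_wide=float(a_w),
                                    sigma_wide_mm=float(s_w))
    resid = y - _double_gaussian(x, c, a_n, s_n, a_w, s_w)
    rms_pct = float(np.sqrt(np.mean(resid**2)) / peak * 100.0)
    errors = dict(zip(["center_mm", "amp_narrow", "sigma_narrow_mm",
                       "amp_wide", "sigma_wide_mm"], perr.tolist()))
    return DoubleGaussianFit(profile, errors, rms_pct, converged=True)


def profile_residual_rms(x1, y1, x2, y2) -> float:
    """RMS difference of two peak-normalized profiles, in % of peak.

    The second profile is resampled onto the first profile's axis over
    the overlapping range by linear interpolation.
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    y1 = np.asarray(y1, dtype=float)
    y2 = np.asarray(y2, dtype=float)
    lo, hi = max(x1.min(), x2.min()), min(x1.max(), x2.max())
    if lo >= hi:
        raise ValueError("profile axes do not overlap")
    sel = (x1 >= lo) & (x1 <= hi)
    p1 = y1[sel] / y1.max()
    p2 = np.interp(x1[sel], x2, y2) / y2.max()
    return float(np.sqrt(np.mean((p1 - p2) ** 2)) * 100.0)


def hardness_analysis(time_s, dose_kGy, signal_adc, control_adc) -> HardnessSeries:
    """Ratio-of-ratios radiation-hardness trend.

    R(t) = (A_s(t)/A_s(0)) / (A_con(t)/A_con(0)) cancels any drift
    common to the signal and control regions (beam-current variations);
    the slope of R vs cumulative dose is the material's fractional
    signal loss per kGy.
    """
    t = np.asarray(time_s, dtype=float)
    d = np.asarray(dose_kGy, dtype=float)
    s = np.asarray(signal_adc, dtype=float)
    c = np.asarray(control_adc, dtype=float)
    if not (t.size == d.size == s.size == c.size) or t.size < 3:
        raise ValueError("need >= 3 matched samples")
    if s[0] == 0 or c[0] == 0 or np.any(c == 0):
        raise ValueError("zero denominator in ratio-of-ratios")
    r = (s / s[0]) / (c / c[0])
    (slope, intercept), cov = np.polyfit(d, r, 1, cov=True)
    return HardnessSeries(t, d, s, c, r, float(slope), float(np.sqrt(cov[0, 0])))


def region_means(frames, signal_mask, control_mask, pedestal=0.0):
    """Mean pedestal-subtracted ADC in the signal / control regions of
    each frame; the inputs for :func:`hardness_analysis`."""
    sig, con = [], []
    for f in frames:
        residual = np.asarray(f.pixels if hasattr(f, "pixels") else f, dtype=float) - pedestal
        sig.append(float(residual[signal_mask].mean()))
        con.append(float(residual[control_mask].mean()))
    return np.asarray(sig), np.asarray(con)


def linearity_analysis(dpp_Gy, signal, fit_max_Gy: float | None = None) -> LinearityResult:
    """Dose-response linearity: OLS fit and per-point fractional deviation.

    Points with DPP above ``fit_max_Gy`` are excluded from the fit (but
    still get a deviation), mirroring the exclusion of saturating
    high-rate points from a linear-response fit.
    """
    x = np.asarray(dpp_Gy, dtype=float)
    y = np.asarray(signal, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 matched points")
    sel = np.ones_like(x, dtype=bool) if fit_max_Gy is None else x <= fit_max_Gy
    if np.ptp(x[sel]) == 0:
        raise ValueError("degenerate dose axis")
    slope, intercept = np.polyfit(x[sel], y[sel], 1)
    pred = slope * x + intercept
    dev = (y - pred) / pred
    return LinearityResult(x, y, float(slope), float(intercept), dev)
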