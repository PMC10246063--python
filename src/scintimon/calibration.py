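"""Three-part monitor calibration.

Part 1 — a multiplicative flat-field correction matrix on a ~1 mm mesh,
normalized to a central reference cell, built from an image of a uniform
luminescent screen; it removes the inverse-square optical-path falloff
and any other smooth response non-uniformity.

Part 2 — a degradation monitor: differential comparison of a current
calibration image against a reference image of the same screen, flagging
scintillator replacement once the mean signal loss exceeds a threshold
(1% by default).

Part 3 — the absolute gain chain ADC -> photoelectrons -> Gy.

The beam-plane/sensor homography (estimated by normalized DLT) lives in
:mod:`scintimon.geometry` and is re-exported here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json

import numpy as np

from .geometry import (  # noqa: F401  (re-exported calibration surface)
    DegenerateConfigurationError,
    Homography,
    estimate_homography,
    oblique_view_homography,
)

__all__ = [
    "CorrectionMatrix",
    "GainChain",
    "DeadRegionError",
    "Homography",
    "estimate_homography",
    "oblique_view_homography",
    "DegenerateConfigurationError",
    "build_correction_matrix",
    "apply_corrections",
    "degradation_map",
    "adc_to_dose",
]


class DeadRegionError(ValueError):
    """A mesh cell has non-positive mean amplitude."""

    def __init__(self, cells):
        self.cells = list(cells)
        super().__init__(f"dead or non-positive mesh cells: {self.cells}")


def _as_pixels(frame) -> np.ndarray:
    return np.asarray(frame.pixels if hasattr(frame, "pixels") else frame, dtype=float)


def _pedestal_of(frame, pedestal) -> float:
    if pedestal is not None:
        return float(pedestal)
    if hasattr(frame, "meta"):
        return float(frame.meta.get("pedestal_adc", 0.0))
    return 0.0


def _cell_means(residual: np.ndarray, cell_px: int) -> np.ndarray:
    h, w = residual.shape
    nr, nc = h // cell_px, w // cell_px
    trimmed = residual[: nr * cell_px, : nc * cell_px]
    return trimmed.reshape(nr, cell_px, nc, cell_px).mean(axis=(1, 3))


@dataclass
class CorrectionMatrix:
    """Per-cell multiplicative flat-field corrections.

    ``cells[i, j]`` multiplies pedestal-subtracted amplitudes in mesh
    cell (row i, col j); NaN marks cells dropped at the active-area
    boundary.  The reference cell is exactly 1.
    """

    mesh_mm: float
    cell_px: int
    cells: np.ndarray
    ref_cell: tuple[int, int]

    def __post_init__(self) -> None:
        valid = self.cells[np.isfinite(self.cells)]
        if np.any(valid <= 0):
            raise ValueError("corrections must be > 0")
        if not np.isclose(self.cells[self.ref_cell], 1.0, rtol=0, atol=1e-12):
            raise ValueError("reference-cell correction must be exactly 1")

    def save(self, csv_path, header_path) -> None:
        np.savetxt(csv_path, self.cells, delimiter=",")
        with open(header_path, "w") as fh:
            json.dump(
                {"mesh_mm": self.mesh_mm, "cell_px": self.cell_px,
                 "ref_cell": list(self.ref_cell)}, fh)

    @classmethod
    def load(cls, csv_path, header_path) -> "CorrectionMatrix":
        cells = np.atleast_2d(np.loadtxt(csv_path, delimiter=","))
        with open(header_path) as fh:
            hdr = json.load(fh)
        return cls(hdr["mesh_mm"], hdr["cell_px"], cells, tuple(hdr["ref_cell"]))


@dataclass(frozen=True)
class GainChain:
    """ADC -> PE -> Gy conversion gains at the calibration geometry."""

    adc_per_pe: float
    pe_per_Gy: float

    def __post_init__(self) -> None:
        if self.adc_per_pe <= 0 or self.pe_per_Gy <= 0:
            raise ValueError("gains must be > 0")


def build_correction_matrix(
    flat_field,
    mesh_mm: float = 1.0,
    ref_point_px: tuple[float, float] | None = None,
    px_per_mm: float = 4.0,
    pedestal: float | None = None,
    active_mask: np.ndarray | None = None,
) -> CorrectionMatrix:
    """Build the flat-field correction matrix from a calibration frame.

    Cell (i, j) gets correction mean(ref cell)/mean(cell); cells only
    partially inside ``active_mask`` are dropped (NaN), cells fully
    inside with non-positive mean raise :class:`DeadRegionError`.
    ``ref_point_px`` is an (x, y) pixel position; default frame center.
    """
    residual = _as_pixels(flat_field) - _pedestal_of(flat_field, pedestal)
    cell_px = max(1, int(round(mesh_mm * px_per_mm)))
    means = _cell_means(residual, cell_px)
    nr, nc = means.shape
    if active_mask is not None:
        cover = _cell_means(np.asarray(active_mask, dtype=float), cell_px)
        means = np.where(cover >= 1.0, means, np.nan)
    if ref_point_px is None:
        ref_point_px = (residual.shape[1] / 2.0, residual.shape[0] / 2.0)
    ref_cell = (min(int(ref_point_px[1] // cell_px), nr - 1),
                min(int(ref_point_px[0] // cell_px), nc - 1))
    if not np.isfinite(means[ref_cell]):
        raise ValueError("reference cell lies outside the active area")
    dead = np.argwhere(np.nan_to_num(means, nan=1.0) <= 0)
    if len(dead):
        raise DeadRegionError(map(tuple, dead))
    cells = means[ref_cell] / means
    cells[ref_cell] = 1.0
    return CorrectionMatrix(mesh_mm, cell_px, cells, ref_cell)


def _interp_correction(cm: CorrectionMatrix, shape: tuple[int, int]) -> np.ndarray:
    """Bilinear interpolation of cell corrections at every pixel."""
    cells = np.nan_to_num(cm.cells, nan=1.0)
    nr, nc = cells.shape
    h, w = shape
    # cell-center pixel coordinates
    yc = (np.arange(nr) + 0.5) * cm.cell_px - 0.5
    xc = (np.arange(nc) + 0.5) * cm.cell_px - 0.5
    yq = np.clip(np.arange(h, dtype=float), yc[0], yc[-1])
    xq = np.clip(np.arange(w, dtype=float), xc[0], xc[-1])
    iy = np.clip(np.searchsorted(yc, yq) - 1, 0, nr - 2) if nr > 1 else np.zeros(h, int)
    ix = np.clip(np.searchsorted(xc, xq) - 1, 0, nc - 2) if nc > 1 else np.zeros(w, int)
    if nr > 1:
        ty = (yq - yc[iy]) / (yc[iy + 1] - yc[iy])
    else:
        ty = np.zeros(h)
    if nc > 1:
        tx = (xq - xc[ix]) / (xc[ix + 1] - xc[ix])
    else:
        tx = np.zeros(w)
    iy1 = np.minimum(iy + 1, nr - 1)
    ix1 = np.minimum(ix + 1, nc - 1)
    c00 = cells[np.ix_(iy, ix)]
    c01 = cells[np.ix_(iy, ix1)]
    c10 = cells[np.ix_(iy1, ix)]
    c11 = cells[np.ix_(iy1, ix1)]
    ty = ty[:, None]
    tx = tx[None, :]
    return (c00 * (1 - ty) * (1 - tx) + c01 * (1 - ty) * tx
            + c10 * ty * (1 - tx) + c11 * ty * tx)


def apply_corrections(frame, cm: CorrectionMatrix, pedestal: float | None = None) -> np.ndarray:
    """Apply flat-field corrections; returns the corrected, pedestal-
    subtracted amplitude map (float)."""
    residual = _as_pixels(frame) - _pedestal_of(frame, pedestal)
    h, w = residual.shape
    if h < cm.cell_px * cm.cells.shape[0] or w < cm.cell_px * cm.cells.shape[1]:
        raise ValueError("frame smaller than the correction-matrix coverage")
    return residual * _interp_correction(cm, (h, w))


def degradation_map(
    current,
    reference,
    mesh_mm: float = 1.0,
    px_per_mm: float = 4.0,
    pedestal: float | None = None,
    replace_threshold: float = 0.01,
) -> tuple[np.ndarray, bool]:
    """Per-cell fractional signal loss of ``current`` vs ``reference``.

    Both frames must be pedestal-subtracted views of the same screen
    (pedestal from metadata is removed if present).  Returns the loss
    grid (1 - current/reference) and the replace flag, true when the
    area-weighted mean loss exceeds ``replace_threshold``.
    """
    cur = _as_pixels(current) - _pedestal_of(current, pedestal)
    ref = _as_pixels(reference) - _pedestal_of(reference, pedestal)
    if cur.shape != ref.shape:
        raise ValueError("frame geometries differ")
    cell_px = max(1, int(round(mesh_mm * px_per_mm)))
    cur_m = _cell_means(cur, cell_px)
    ref_m = _cell_means(ref, cell_px)
    bad = np.argwhere(ref_m <= 0)
    if len(bad):
        raise DeadRegionError(map(tuple, bad))
    loss = 1.0 - cur_m / ref_m
    replace = bool(loss.mean() > replace_threshold)
    return loss, replace


def adc_to_dose(integrated_adc: float, gc: GainChain) -> float:
    """Convert an integrated ADC signal to dose: Gy = ADC / g_ADC/PE / g_PE/Gy."""
    if gc is None:
        raise ValueError("gain chain not set")
    return integrated_adc / gc.adc_per_pe / gc.pe_per_Gy
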