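"""Planar projective geometry between the beam plane and the sensor.

The camera views the scintillator obliquely (roughly 40 degrees in the
prototype), so the beam plane (mm, origin at the scintillator center)
and the sensor plane (pixels) are related by a 3x3 homography.  The
treatment plan is transformed once into sensor coordinates at load time;
images are never warped during monitoring.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = ["Homography", "DegenerateConfigurationError", "estimate_homography", "oblique_view_homography"]


class DegenerateConfigurationError(ValueError):
    """Point configuration does not determine a homography."""


@dataclass(frozen=True)
class Homography:
    """3x3 projective map, stored with h[2,2] = 1."""

    h: np.ndarray = field()

    def __post_init__(self) -> None:
        m = np.asarray(self.h, dtype=float).reshape(3, 3)
        if m[2, 2] == 0:
            raise ValueError("h[2,2] must be nonzero for normalized storage")
        m = m / m[2, 2]
        det = np.linalg.det(m)
        if abs(det) < 1e-12:
            raise ValueError("homography must be invertible")
        object.__setattr__(self, "h", m)

    @classmethod
    def identity(cls) -> "Homography":
        return cls(np.eye(3))

    def map(self, points) -> np.ndarray:
        """Apply to (n, 2) points (or a single (2,) point)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        hom = np.column_stack([pts, np.ones(len(pts))])
        out = hom @ self.h.T
        out = out[:, :2] / out[:, 2:3]
        if np.asarray(points).ndim == 1:
            return out[0]
        return out

    def inverse(self) -> "Homography":
        return Homography(np.linalg.inv(self.h))

    def jacobian_det(self, points) -> np.ndarray:
        """|det J| of the map at the given source points.

        For q = (H p)/(h3 . p) the Jacobian determinant is
        det(H) / (h3 . p)^3; the absolute value is the local area
        magnification.
        """
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        w = pts @ self.h[2, :2] + self.h[2, 2]
        det = np.linalg.det(self.h)
        out = np.abs(det / w**3)
        if np.asarray(points).ndim == 1:
            return float(out[0])
        return out

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"h": self.h.ravel().tolist()}, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "Homography":
        with open(path) as fh:
            data = json.load(fh)
        return cls(np.asarray(data["h"], dtype=float).reshape(3, 3))


def _normalization(points: np.ndarray) -> np.ndarray:
    """Hartley similarity: centroid to origin, mean distance sqrt(2)."""
    centroid = points.mean(axis=0)
    d = np.linalg.norm(points - centroid, axis=1).mean()
    if d == 0:
        raise DegenerateConfigurationError("all points coincide")
    s = math.sqrt(2.0) / d
    return np.array(
        [[s, 0, -s * centroid[0]], [0, s, -s * centroid[1]], [0, 0, 1.0]]
    )


def estimate_homography(src_mm, dst_px) -> tuple[Homography, float]:
    """Estimate the beam-plane -> sensor homography by normalized DLT.

    Parameters
    ----------
    src_mm, dst_px : (n, 2) arrays of corresponding points, n >= 4.

    Returns
    -------
    (Homography, reprojection_rms) where the RMS is in destination units.

    Raises
    ------
    DegenerateConfigurationError
        Fewer than 4 pairs, or a configuration (e.g. >= n-1 collinear
        points) that leaves the DLT system rank deficient.
    """
    src = np.asarray(src_mm, dtype=float).reshape(-1, 2)
    dst = np.asarray(dst_px, dtype=float).reshape(-1, 2)
    if src.shape != dst.shape or len(src) < 4:
        raise DegenerateConfigurationError("need >= 4 point correspondences")

    t_src = _normalization(src)
    t_dst = _normalization(dst)
    s = (np.column_stack([src, np.ones(len(src))]) @ t_src.T)[:, :2]
    d = (np.column_stack([dst, np.ones(len(dst))]) @ t_dst.T)[:, :2]

    n = len(s)
    a = np.zeros((2 * n, 9))
    a[0::2, 0:2] = s
    a[0::2, 2] = 1.0
    a[0::2, 6:8] = -s * d[:, :1]
    a[0::2, 8] = -d[:, 0]
    a[1::2, 3:5] = s
    a[1::2, 5] = 1.0
    a[1::2, 6:8] = -s * d[:, 1:2]
    a[1::2, 8] = -d[:, 1]

    _, sv, vt = np.linalg.svd(a)
    if sv[-2] < 1e-9 * sv[0]:
        raise DegenerateConfigurationError(
            "rank-deficient DLT system (collinear or repeated points)"
        )
    h_norm = vt[-1].reshape(3, 3)
    h = np.linalg.inv(t_dst) @ h_norm @ t_src
    if abs(h[2, 2]) < 1e-12 * np.abs(h).max():
        raise DegenerateConfigurationError("degenerate solution (h33 ~ 0)")
    hom = Homography(h)
    rms = float(np.sqrt(np.mean(np.sum((hom.map(src) - dst) ** 2, axis=1))))
    return hom, rms


def oblique_view_homography(
    tilt_deg: float = 40.0,
    px_per_mm: float = 4.0,
    center_px: tuple[float, float] = (0.0, 0.0),
    view_distance_mm: float = 400.0,
) -> Homography:
    """Construct the homography of a camera viewing the plane at a tilt.

    The beam plane is tilted by ``tilt_deg`` about its x axis and imaged
    by a pinhole at ``view_distance_mm``; the result foreshortens the y
    axis and produces the characteristic trapezoidal footprint.  With
    ``tilt_deg=0`` this reduces to a pure scale + shift.
    """
    t = math.radians(tilt_deg)
    f = px_per_mm * view_distance_mm  # focal length in px x mm/mm
    # plane point (x, y) -> 3D (x, y cos t, d + y sin t) -> perspective divide
    h = np.array(
        [
            [f, 0.0, center_px[0] * view_distance_mm],
            [0.0, f * math.cos(t), center_px[1] * view_distance_mm],
            [0.0, math.sin(t), view_distance_mm],
        ]
    )
    return Homography(h / h[2, 2])
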