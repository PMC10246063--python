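"""Frame interchange: 16-bit grayscale TIFF with a JSON sidecar.

TIFF keeps the pixel payload inspectable with standard tools; the
sidecar (``<path>.json``) carries what TIFF tags do not: the sensor
model, per-frame acquisition metadata and any stream-level extras such
as the delivered-dose ledger.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict
from pathlib import Path

import numpy as np
import tifffile

from .simulate import Frame, SensorModel

__all__ = ["write_frames", "read_frames", "sidecar_path"]


def sidecar_path(path) -> Path:
    return Path(str(path) + ".json")


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def write_frames(frames, path, sensor: SensorModel | None = None, extra: dict | None = None) -> None:
    """Write a frame stream as a multi-page 16-bit TIFF plus sidecar."""
    frames = list(frames)
    if not frames:
        raise ValueError("no frames to write")
    stack = np.stack([f.pixels for f in frames])
    if stack.dtype != np.uint16:
        raise ValueError("frames must be 16-bit (uint16)")
    tifffile.imwrite(path, stack, photometric="minisblack")
    sidecar = {
        "sensor": asdict(sensor) if sensor is not None else None,
        "frames": [_jsonable(f.meta) for f in frames],
        "extra": _jsonable(extra) if extra else {},
    }
    with open(sidecar_path(path), "w") as fh:
        json.dump(sidecar, fh, indent=1)


def read_frames(path) -> tuple[list[Frame], SensorModel | None, dict]:
    """Read a frame stream; lossless inverse of :func:`write_frames`.

    A missing sidecar degrades to empty metadata with a warning.  Any
    bit depth other than 16-bit grayscale is rejected.
    """
    stack = tifffile.imread(path)
    if stack.dtype != np.uint16:
        raise ValueError(f"expected 16-bit grayscale TIFF, got dtype {stack.dtype}")
    if stack.ndim == 2:
        stack = stack[None, ...]
    if stack.ndim != 3:
        raise ValueError("expected single- or multi-page grayscale TIFF")
    sc = sidecar_path(path)
    sensor = None
    metas = [{} for _ in range(len(stack))]
    extra: dict = {}
    if sc.exists():
        with open(sc) as fh:
            sidecar = json.load(fh)
        if sidecar.get("sensor"):
            s = dict(sidecar["sensor"])
            if s.get("roi") is not None:
                s["roi"] = tuple(s["roi"])
            sensor = SensorModel(**s)
        metas = sidecar.get("frames", metas)
        if len(metas) < len(stack):
            metas = metas + [{} for _ in range(len(stack) - len(metas))]
        extra = sidecar.get("extra", {})
    else:
        warnings.warn(f"no sidecar at {sc}; using default metadata")
    return [Frame(stack[i].copy(), dict(metas[i])) for i in range(len(stack))], sensor, extra
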