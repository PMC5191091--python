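"""Reading and writing of B-scan series, time-course tables and overlay images.

A B-scan series is stored on disk as a multi-page 16-bit TIFF plus a JSON
sidecar with the same stem carrying pixel spacings, frame timestamps, the
reference-frame index and the dynamic-range window used for quantization.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import tifffile


@dataclass
class BScan:
    """A single cross-sectional OCT frame.

    ``intensity`` is a 2-D ``[z][x]`` array of normalized linear backscatter
    in [0, 1]; z (rows) increases downward into the tissue.  ``timestamp_s``
    is relative to drug application (negative = pre-application).
    """

    intensity: np.ndarray
    pixel_dz_um: float
    pixel_dx_um: float
    timestamp_s: float

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 2:
            raise ValueError("B-scan intensity must be 2-D [z][x]")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("B-scan intensity contains non-finite values")
        if self.pixel_dz_um <= 0 or self.pixel_dx_um <= 0:
            raise ValueError("pixel spacings must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensity.shape


@dataclass
class BScanSeries:
    """An ordered time series of B-scans sharing geometry.

    ``reference_index`` designates the frame acquired at drug application
    (t = 0); speckle variance is always computed against this frame.
    """

    frames: list[BScan]
    reference_index: int
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("series must contain at least one frame")
        shape = self.frames[0].shape
        dz, dx = self.frames[0].pixel_dz_um, self.frames[0].pixel_dx_um
        for f in self.frames:
            if f.shape != shape:
                raise ValueError("all frames must share one shape")
            if (f.pixel_dz_um, f.pixel_dx_um) != (dz, dx):
                raise ValueError("all frames must share pixel spacings")
        ts = self.timestamps_s
        if np.any(np.diff(ts) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if not 0 <= self.reference_index < len(self.frames):
            raise ValueError("reference_index out of range")
        if len(ts) > 1:
            interval = float(np.median(np.diff(ts)))
            if abs(ts[self.reference_index]) > interval:
                raise ValueError(
                    "reference frame timestamp must be 0 within one frame interval"
                )

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def timestamps_s(self) -> np.ndarray:
        return np.array([f.timestamp_s for f in self.frames])

    @property
    def reference(self) -> BScan:
        return self.frames[self.reference_index]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames[0].shape

    @property
    def pixel_dz_um(self) -> float:
        return self.frames[0].pixel_dz_um

    @property
    def pixel_dx_um(self) -> float:
        return self.frames[0].pixel_dx_um

    def pre_application(self) -> list[BScan]:
        return self.frames[: self.reference_index]

    def post_application(self) -> list[BScan]:
        """Frames strictly after the reference (the reference itself excluded)."""
        return self.frames[self.reference_index + 1 :]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_series(series: BScanSeries, path: str | Path) -> tuple[Path, Path]:
    """Write a series as multi-page 16-bit TIFF + JSON sidecar.

    Intensities are quantized into the dynamic-range window [0, 1]; the
    window is recorded in the sidecar so normalization is reproducible.
    """
    path = Path(path).with_suffix(".tif")
    lo, hi = 0.0, 1.0
    stack = np.stack([f.intensity for f in series.frames])
    quant = np.clip((stack - lo) / (hi - lo), 0.0, 1.0)
    quant = np.round(quant * 65535.0).astype(np.uint16)
    tifffile.imwrite(path, quant, photometric="minisblack")
    sidecar = {
        "pixel_dz_um": series.pixel_dz_um,
        "pixel_dx_um": series.pixel_dx_um,
        "timestamps_s": [float(t) for t in series.timestamps_s],
        "reference_index": series.reference_index,
        "dynamic_range": [lo, hi],
        "metadata": _jsonable(series.metadata),
    }
    sc_path = _sidecar_path(path)
    sc_path.write_text(json.dumps(sidecar, indent=2))
    return path, sc_path


def read_series(path: str | Path) -> BScanSeries:
    """Read a series written by :func:`write_series`.

    Raises ``FileNotFoundError`` naming the missing metadata sidecar, and
    ``ValueError`` on shape mismatch or non-monotone timestamps.
    """
    path = Path(path).with_suffix(".tif")
    sc_path = _sidecar_path(path)
    if not sc_path.exists():
        raise FileNotFoundError(f"missing metadata sidecar: {sc_path}")
    meta = json.loads(sc_path.read_text())
    stack = tifffile.imread(path)
    if stack.ndim == 2:
        stack = stack[None]
    lo, hi = meta["dynamic_range"]
    norm = stack.astype(float) / 65535.0 * (hi - lo) + lo
    ts = meta["timestamps_s"]
    if len(ts) != len(stack):
        raise ValueError("sidecar timestamp count does not match TIFF pages")
    frames = [
        BScan(norm[i], meta["pixel_dz_um"], meta["pixel_dx_um"], ts[i])
        for i in range(len(stack))
    ]
    return BScanSeries(frames, meta["reference_index"], meta.get("metadata", {}))


def write_timecourse_csv(tc, path: str | Path) -> Path:
    """Write a diffusion time course as CSV.

    Columns: ``time_s, region_label, mean_sv_sum, sd_sv_sum, com_depth_um``
    — one row per (time, region).  Undefined center-of-mass entries (total
    SV of zero) are written as empty cells.
    """
    import pandas as pd

    rows = []
    for label in tc.region_labels:
        mean, sd = tc.region_mean[label], tc.region_sd[label]
        for i, t in enumerate(tc.times_s):
            rows.append(
                {
                    "time_s": t,
                    "region_label": label,
                    "mean_sv_sum": mean[i],
                    "sd_sv_sum": sd[i],
                    "com_depth_um": tc.com_depth_um[i],
                }
            )
    df = pd.DataFrame(rows, columns=["time_s", "region_label", "mean_sv_sum", "sd_sv_sum", "com_depth_um"])
    path = Path(path)
    df.to_csv(path, index=False, na_rep="")
    return path


def write_overlay(bscan: BScan, sv, path: str | Path, alpha: float = 0.8) -> Path:
    """Merge structure (gray) with suprathreshold SV (red scale) into a PNG.

    Zero SV pixels show the pure grayscale structural image; suprathreshold
    SV is alpha-blended into the red channel, as in SV-OCT merged display.
    """
    sv_arr = np.asarray(sv.sv, dtype=float)
    if sv_arr.shape != bscan.shape:
        raise ValueError("SV image and B-scan shapes differ")
    gray = np.clip(bscan.intensity, 0.0, 1.0)
    rgb = np.stack([gray, gray, gray], axis=-1)
    svmax = sv_arr.max()
    if svmax > 0:
        w = alpha * np.clip(sv_arr / svmax, 0.0, 1.0)
        w = np.where(sv_arr > 0, w, 0.0)
        rgb[..., 0] = (1 - w) * rgb[..., 0] + w * 1.0
        rgb[..., 1] = (1 - w) * rgb[..., 1]
        rgb[..., 2] = (1 - w) * rgb[..., 2]
    out = np.round(np.clip(rgb, 0, 1) * 255).astype(np.uint8)
    path = Path(path).with_suffix(".png")
    iio.imwrite(path, out)
    return path


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
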