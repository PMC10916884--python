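"""Scan geometry: lateral scaling, resampling to a common scale, frame averaging.

OCT B-scans are acquired with a nominal scan length that assumes a standard
eye.  The true lateral extent scales with the participant's axial length, so
the per-pixel lateral scale must be corrected before any eccentricity-based
measurement.  All downstream analysis runs at a common scale (2.27 µm/px
axial, 5.26 µm/px lateral).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

logger = logging.getLogger(__name__)

#: common analysis scales, µm per pixel
TARGET_AXIAL_UM_PER_PX = 2.27
TARGET_LATERAL_UM_PER_PX = 5.26

#: assumed axial length of the OCT device's standard eye, mm
DEVICE_ASSUMED_AXIAL_MM = 24.0


@dataclass
class ScanMetadata:
    """Acquisition metadata needed to place a B-scan on a physical scale."""

    nominal_length_mm: float
    axial_length_mm: float
    n_ascans: int = 1000
    device_assumed_axial_mm: float = DEVICE_ASSUMED_AXIAL_MM
    native_axial_scale_um_per_px: float = TARGET_AXIAL_UM_PER_PX

    def __post_init__(self) -> None:
        if self.nominal_length_mm <= 0:
            raise ValueError("nominal scan length must be positive")
        if self.axial_length_mm <= 0:
            raise ValueError("axial length must be positive")
        if self.n_ascans < 2:
            raise ValueError("need at least 2 A-scans per B-scan")
        if self.device_assumed_axial_mm <= 0 or self.native_axial_scale_um_per_px <= 0:
            raise ValueError("scales must be positive")


@dataclass
class BScanImage:
    """A B-scan: rows are depth (increasing = deeper), columns are lateral."""

    data: np.ndarray
    axial_scale_um_per_px: float
    lateral_scale_um_per_px: float
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("B-scan must be a 2-D array")
        if self.axial_scale_um_per_px <= 0 or self.lateral_scale_um_per_px <= 0:
            raise ValueError("pixel scales must be positive")
        if np.any(self.data < 0):
            raise ValueError("intensities must be nonnegative")

    @property
    def n_depth(self) -> int:
        return self.data.shape[0]

    @property
    def n_lateral(self) -> int:
        return self.data.shape[1]

    def x_um(self) -> np.ndarray:
        """Signed lateral coordinate in µm, zero at the scan center."""
        center = (self.n_lateral - 1) / 2.0
        return (np.arange(self.n_lateral) - center) * self.lateral_scale_um_per_px

    def depth_um(self) -> np.ndarray:
        return np.arange(self.n_depth) * self.axial_scale_um_per_px


def compute_lateral_scale(meta: ScanMetadata) -> float:
    """Lateral scale in µm/px from nominal scan length and ocular axial length.

    The physical scan length is the nominal length times the ratio of the
    participant's axial length to the device's assumed axial length; dividing
    by the number of A-scans per B-scan gives µm per pixel.
    """
    length_mm = meta.nominal_length_mm * (
        meta.axial_length_mm / meta.device_assumed_axial_mm
    )
    return length_mm * 1000.0 / meta.n_ascans


MAX_UPSCALE = 20.0


def resample_image(
    img: BScanImage,
    target_axial: float = TARGET_AXIAL_UM_PER_PX,
    target_lateral: float = TARGET_LATERAL_UM_PER_PX,
) -> BScanImage:
    """Bicubic resample to the common axial/lateral scale.

    Total physical extent is preserved to within one output pixel; edges are
    clamped (nearest) during interpolation.
    """
    if target_axial <= 0 or target_lateral <= 0:
        raise ValueError("target scales must be positive")
    zoom_ax = img.axial_scale_um_per_px / target_axial
    zoom_lat = img.lateral_scale_um_per_px / target_lateral
    if max(zoom_ax, zoom_lat) > MAX_UPSCALE:
        raise ValueError(
            f"refusing to upscale more than {MAX_UPSCALE}x "
            f"(requested {max(zoom_ax, zoom_lat):.1f}x)"
        )
    if abs(zoom_ax - 1.0) < 1e-12 and abs(zoom_lat - 1.0) < 1e-12:
        return BScanImage(img.data.copy(), target_axial, target_lateral,
                          flags=list(img.flags))
    out = ndimage.zoom(img.data, (zoom_ax, zoom_lat), order=3, mode="nearest",
                       grid_mode=True)
    out = np.clip(out, 0.0, None)  # cubic overshoot can go slightly negative
    return BScanImage(out, target_axial, target_lateral, flags=list(img.flags))


def average_frames(frames: list[BScanImage], max_frames: int = 19) -> BScanImage:
    """Pixelwise mean of registered frames, truncated to ``max_frames``.

    Frames must share shape and scales; registration happens upstream.
    """
    if not frames:
        raise ValueError("no frames supplied")
    shape = frames[0].data.shape
    ax, lat = frames[0].axial_scale_um_per_px, frames[0].lateral_scale_um_per_px
    for f in frames[1:]:
        if f.data.shape != shape:
            raise ValueError("frames differ in shape")
        if (f.axial_scale_um_per_px, f.lateral_scale_um_per_px) != (ax, lat):
            raise ValueError("frames differ in pixel scale")
    used = frames[:max_frames]
    flags: list[str] = []
    if len(frames) > max_frames:
        logger.warning(
            "averaging truncated to first %d of %d frames", max_frames, len(frames)
        )
        warnings.warn(
            f"more than {max_frames} frames supplied; extra frames ignored",
            stacklevel=2,
        )
        flags.append("frames_truncated")
    mean = np.mean([f.data for f in used], axis=0)
    return BScanImage(mean, ax, lat, flags=flags)
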