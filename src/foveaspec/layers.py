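"""Retinal layer thickness profiles and parafovea-normalized ratios.

Foveal specialization is quantified relative to the parafovea so that
between-individual variation in absolute retinal thickness cancels out:

* IRL ratio — mean inner-retinal-layer thickness (ILM to INL/OPL) at ±1 mm
  divided by the foveal IRL thickness.  A formed pit gives values well
  above 1; a flat retina gives 1.
* ONL ratio — outer-nuclear-layer thickness (HFL-outer boundary to ELM) at
  the fovea divided by the mean at ±1.75 mm.  Foveal ONL thickening gives
  values above 1.

The OS ratio (foveal outer-segment elongation) is computed from reflectivity
profiles in :mod:`foveaspec.reflectivity`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: canonical surface order, top (inner) to bottom (outer)
SURFACES = ("ILM", "INL_OPL", "HFL_outer", "ELM", "EZ", "IZ", "RPE")

IRL_SMOOTH_WINDOW_PX = 30
IRL_GRID_STEP_UM = 100.0
ONL_GRID_STEP_UM = 50.0
ONL_GRID_EXTENT_UM = 2000.0
IRL_ECC_MM = 1.0
ONL_ECC_MM = 1.75


@dataclass
class LayerSegmentation:
    """Per-lateral-pixel depth (µm from image top) of named retinal surfaces.

    ``x_um`` is the signed lateral coordinate in µm (scan-centered; after
    left-eye mirroring, nasal is +x).
    """

    x_um: np.ndarray
    surfaces: dict[str, np.ndarray]
    lateral_scale_um_per_px: float
    laterality: str = "OD"

    def __post_init__(self) -> None:
        self.x_um = np.asarray(self.x_um, dtype=float)
        missing = [s for s in SURFACES if s not in self.surfaces]
        if missing:
            raise ValueError(f"segmentation missing surfaces: {missing}")
        n = self.x_um.size
        self.surfaces = {k: np.asarray(v, dtype=float) for k, v in self.surfaces.items()}
        for k, v in self.surfaces.items():
            if v.size != n:
                raise ValueError(f"surface {k} length {v.size} != x length {n}")
            if np.any(~np.isfinite(v)):
                raise ValueError(f"surface {k} contains non-finite depths")
        if self.lateral_scale_um_per_px <= 0:
            raise ValueError("lateral scale must be positive")
        if self.laterality not in ("OD", "OS"):
            raise ValueError("laterality must be 'OD' or 'OS'")
        self.validate_ordering()

    def validate_ordering(self) -> None:
        """Depths must weakly increase in anatomical order at every x."""
        for upper, lower in zip(SURFACES[:-1], SURFACES[1:]):
            if np.any(self.surfaces[lower] - self.surfaces[upper] < -1e-9):
                raise ValueError(
                    f"surface ordering violated: {lower} above {upper} somewhere"
                )

    def depth_at(self, surface: str, x_um: float | np.ndarray) -> np.ndarray:
        """Linearly interpolated depth of ``surface`` at lateral position(s)."""
        return np.interp(x_um, self.x_um, self.surfaces[surface])

    def mirrored(self) -> "LayerSegmentation":
        """Flip the lateral axis (used to make nasal +x for left eyes)."""
        return LayerSegmentation(
            x_um=-self.x_um[::-1],
            surfaces={k: v[::-1].copy() for k, v in self.surfaces.items()},
            lateral_scale_um_per_px=self.lateral_scale_um_per_px,
            laterality=self.laterality,
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"x_um": self.x_um})
        for s in SURFACES:
            df[s] = self.surfaces[s]
        return df


@dataclass
class ThicknessProfile:
    """A layer thickness sampled on a fovea-centered eccentricity grid."""

    ecc_um: np.ndarray
    thickness_um: np.ndarray
    layer: str
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ecc_um = np.asarray(self.ecc_um, dtype=float)
        self.thickness_um = np.asarray(self.thickness_um, dtype=float)
        if np.any(np.diff(self.ecc_um) <= 0):
            raise ValueError("eccentricity grid must be strictly increasing")
        if np.any(self.thickness_um < 0):
            raise ValueError("negative thickness in profile")

    def at(self, ecc_um: float) -> float:
        if ecc_um < self.ecc_um[0] - 1e-9 or ecc_um > self.ecc_um[-1] + 1e-9:
            raise ValueError(f"eccentricity {ecc_um} µm outside profile grid")
        return float(np.interp(ecc_um, self.ecc_um, self.thickness_um))


@dataclass
class FovealMetrics:
    """The three specialization ratios plus supporting quantities for one eye."""

    irl_ratio: float
    os_ratio: float
    onl_ratio: float
    max_os_um: float
    fovea_x_um: float
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name in ("irl_ratio", "os_ratio", "onl_ratio"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be positive and finite, got {v}")

    def as_dict(self) -> dict:
        return {
            "irl_ratio": self.irl_ratio,
            "os_ratio": self.os_ratio,
            "onl_ratio": self.onl_ratio,
            "max_os_um": self.max_os_um,
            "fovea_x_um": self.fovea_x_um,
            "flags": list(self.flags),
        }


def moving_average(values: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average; the window truncates at the edges."""
    s = pd.Series(np.asarray(values, dtype=float))
    return s.rolling(window, center=True, min_periods=1).mean().to_numpy()


def _fovea_centered_grid(seg: LayerSegmentation, fovea_x_um: float,
                         step_um: float, extent_um: float | None) -> np.ndarray:
    lo = seg.x_um[0] - fovea_x_um
    hi = seg.x_um[-1] - fovea_x_um
    if extent_um is not None:
        lo, hi = max(lo, -extent_um), min(hi, extent_um)
    kmin = int(np.ceil(lo / step_um - 1e-9))
    kmax = int(np.floor(hi / step_um + 1e-9))
    return np.arange(kmin, kmax + 1) * step_um


def irl_thickness_profile(
    seg: LayerSegmentation,
    fovea_x_um: float,
    smooth_window_px: int = IRL_SMOOTH_WINDOW_PX,
    grid_step_um: float = IRL_GRID_STEP_UM,
) -> ThicknessProfile:
    """IRL thickness (ILM to INL/OPL), smoothed then put on a 100-µm grid.

    Smoothing is a centered ``smooth_window_px`` moving average in pixel
    space (truncated at scan edges); the smoothed profile is linearly
    interpolated onto a grid centered at the fovea located by the
    outer-segment Gaussian fit.
    """
    if not (seg.x_um[0] <= fovea_x_um <= seg.x_um[-1]):
        raise ValueError("fovea location outside the scan")
    raw = seg.surfaces["INL_OPL"] - seg.surfaces["ILM"]
    smoothed = moving_average(raw, smooth_window_px)
    grid = _fovea_centered_grid(seg, fovea_x_um, grid_step_um, None)
    thick = np.interp(grid + fovea_x_um, seg.x_um, smoothed)
    return ThicknessProfile(
        grid, thick, "IRL",
        provenance={"smooth_window_px": smooth_window_px,
                    "grid_step_um": grid_step_um,
                    "fovea_x_um": fovea_x_um},
    )


def irl_ratio(profile: ThicknessProfile, ecc_mm: float = IRL_ECC_MM) -> tuple[float, list[str]]:
    """Parafoveal (±``ecc_mm``) mean IRL thickness over foveal IRL thickness.

    Falls back to a single side (flagged ``irl_one_sided``) when the grid
    does not reach the eccentricity on one side.
    """
    ecc = ecc_mm * 1000.0
    foveal = profile.at(0.0)
    if foveal <= 0:
        raise ValueError("foveal IRL thickness is nonpositive")
    sides, flags = [], []
    for sign in (+1, -1):
        try:
            sides.append(profile.at(sign * ecc))
        except ValueError:
            pass
    if not sides:
        raise ValueError(f"parafoveal IRL at ±{ecc:.0f} µm unavailable on both sides")
    if len(sides) == 1:
        flags.append("irl_one_sided")
    return float(np.mean(sides)) / foveal, flags


def onl_thickness_profile(
    seg: LayerSegmentation,
    fovea_x_um: float,
    grid_step_um: float = ONL_GRID_STEP_UM,
    extent_um: float = ONL_GRID_EXTENT_UM,
) -> ThicknessProfile:
    """ONL thickness (HFL-outer boundary to ELM) on a 50-µm grid within ±2 mm."""
    raw = seg.surfaces["ELM"] - seg.surfaces["HFL_outer"]
    if np.any(raw < 0):
        raise ValueError("negative ONL thickness; segmentation failed QC")
    grid = _fovea_centered_grid(seg, fovea_x_um, grid_step_um, extent_um)
    thick = np.interp(grid + fovea_x_um, seg.x_um, raw)
    return ThicknessProfile(
        grid, thick, "ONL",
        provenance={"grid_step_um": grid_step_um, "fovea_x_um": fovea_x_um},
    )


def locate_fovea_onl(seg: LayerSegmentation) -> tuple[float, list[str]]:
    """Foveal center for the ONL stage: x maximizing the ONL-to-IZ distance.

    Ties are broken toward the scan center; an (essentially) flat distance
    profile is flagged degenerate.
    """
    dist = seg.surfaces["IZ"] - seg.surfaces["HFL_outer"]
    dmax = dist.max()
    flags: list[str] = []
    at_max = np.flatnonzero(dist >= dmax - 1e-9)
    center = 0.5 * (seg.x_um[0] + seg.x_um[-1])
    x = seg.x_um[at_max[np.argmin(np.abs(seg.x_um[at_max] - center))]]
    if dmax - dist.min() < 1e-6:
        flags.append("onl_fovea_degenerate")
    return float(x), flags


def onl_ratio(profile: ThicknessProfile, ecc_mm: float = ONL_ECC_MM) -> tuple[float, list[str]]:
    """Foveal ONL thickness over the parafoveal (±``ecc_mm``) mean."""
    ecc = ecc_mm * 1000.0
    sides, flags = [], []
    for sign in (+1, -1):
        try:
            sides.append(profile.at(sign * ecc))
        except ValueError:
            pass
    if not sides:
        raise ValueError(f"parafoveal ONL at ±{ecc:.0f} µm unavailable on both sides")
    if len(sides) == 1:
        flags.append("onl_one_sided")
    para = float(np.mean(sides))
    if para <= 0:
        raise ValueError("parafoveal ONL thickness is nonpositive")
    return profile.at(0.0) / para, flags
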