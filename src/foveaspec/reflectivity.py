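"""Longitudinal reflectivity profiles (LRPs) and outer-segment metrics.

The photoreceptor outer-segment (OS) length at a retinal location is the
axial distance between the ellipsoid zone (EZ) and interdigitation zone (IZ)
reflectivity peaks.  OS length is sampled on a dense grid around its apparent
maximum, a single-term Gaussian ``L(x) = a·exp(−((x−b)/c)²)`` is fit to the
samples, and its peak gives both the maximum OS length (``a``) and the
location of the incipient fovea (``b``).  The OS ratio is the maximum OS
length over the mean parafoveal OS length at ±1.75 mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .layers import LayerSegmentation
from .preprocess import BScanImage

LRP_WIDTH_PX = 5
OS_SAMPLE_SPACING_UM = 25.0
OS_SAMPLE_HALFSPAN_UM = 250.0
OS_PARAFOVEA_MM = 1.75
#: half-width of the EZ/IZ search window around a segmentation-provided depth
SEARCH_HALFWINDOW_UM = 25.0
#: coarse scan spacing used to seed the apparent maximum OS length
COARSE_SCAN_SPACING_UM = 100.0


@dataclass
class LRP:
    """Depth-reflectivity profile averaged over a narrow lateral window."""

    center_x_um: float
    width_px: int
    depth_um: np.ndarray
    reflectivity: np.ndarray
    ez_depth_um: float | None = None
    iz_depth_um: float | None = None

    def __post_init__(self) -> None:
        if self.width_px % 2 == 0:
            raise ValueError("LRP width must be odd")
        if (
            self.ez_depth_um is not None
            and self.iz_depth_um is not None
            and not self.ez_depth_um < self.iz_depth_um
        ):
            raise ValueError("EZ must be shallower than IZ")


@dataclass
class OSLengthFit:
    """Gaussian fit of OS length vs. retinal location."""

    x_um: np.ndarray
    os_length_um: np.ndarray
    a_um: float          # peak (maximum) OS length
    b_um: float          # fovea location
    c_um: float          # Gaussian width
    residual_rms: float
    converged: bool
    flags: list[str] = field(default_factory=list)


def extract_lrp(img: BScanImage, center_x_um: float, width_px: int = LRP_WIDTH_PX) -> LRP:
    """Mean A-scan over ``width_px`` columns centered at ``center_x_um``."""
    if width_px % 2 == 0:
        raise ValueError("LRP width must be odd")
    x = img.x_um()
    col = int(round((center_x_um - x[0]) / img.lateral_scale_um_per_px))
    half = width_px // 2
    if col - half < 0 or col + half >= img.n_lateral:
        raise ValueError(
            f"LRP window at x={center_x_um:.0f} µm falls outside the image"
        )
    profile = img.data[:, col - half : col + half + 1].mean(axis=1)
    return LRP(center_x_um, width_px, img.depth_um(), profile)


def _refine_parabolic(depth: np.ndarray, y: np.ndarray, i: int) -> float:
    """3-point parabolic sub-pixel refinement of a local maximum at index i."""
    if i == 0 or i == y.size - 1:
        return float(depth[i])
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    denom = y0 - 2 * y1 + y2
    if denom >= 0:  # not locally concave; keep grid position
        return float(depth[i])
    delta = 0.5 * (y0 - y2) / denom
    step = depth[i + 1] - depth[i]
    return float(depth[i] + np.clip(delta, -0.5, 0.5) * step)


def _window_peak(lrp: LRP, lo_um: float, hi_um: float) -> float | None:
    mask = (lrp.depth_um >= lo_um) & (lrp.depth_um <= hi_um)
    idx = np.flatnonzero(mask)
    if idx.size < 3:
        return None
    y = lrp.reflectivity
    local = idx[np.argmax(y[idx])]
    left = y[local - 1] if local > 0 else -np.inf
    right = y[local + 1] if local < y.size - 1 else -np.inf
    # require a strict local maximum: flat profiles carry no band
    if not (y[local] > left and y[local] > right):
        return None
    return _refine_parabolic(lrp.depth_um, y, local)


def detect_ez_iz_peaks(
    lrp: LRP,
    ez_window_um: tuple[float, float],
    iz_window_um: tuple[float, float],
) -> tuple[float | None, float | None]:
    """Locate the EZ and IZ reflectivity peaks within their depth windows.

    Each peak is the strict local maximum inside its window, refined by
    3-point parabolic interpolation.  A window with no local maximum (e.g.
    a flat profile) yields ``None`` for that peak.
    """
    if not (ez_window_um[0] < ez_window_um[1] and iz_window_um[0] < iz_window_um[1]):
        raise ValueError("search windows must be increasing (lo, hi) pairs")
    ez = _window_peak(lrp, *ez_window_um)
    iz = _window_peak(lrp, *iz_window_um)
    if ez is not None and iz is not None and not ez < iz:
        return None, None
    return ez, iz


def _seg_windows(seg: LayerSegmentation, x_um: float,
                 half_um: float = SEARCH_HALFWINDOW_UM):
    """±25 µm windows around the segmented EZ/IZ depths, clamped midway to
    the neighboring ELM and RPE bands so their peaks cannot be captured."""
    ez = float(seg.depth_at("EZ", x_um))
    iz = float(seg.depth_at("IZ", x_um))
    elm = float(seg.depth_at("ELM", x_um))
    rpe = float(seg.depth_at("RPE", x_um))
    mid = 0.5 * (ez + iz)
    ez_win = (max(ez - half_um, 0.5 * (elm + ez)), min(ez + half_um, mid))
    iz_win = (max(iz - half_um, mid), min(iz + half_um, 0.5 * (iz + rpe)))
    return ez_win, iz_win


def os_length_at(
    img: BScanImage,
    seg: LayerSegmentation,
    x_um: float,
    width_px: int = LRP_WIDTH_PX,
) -> float | None:
    """OS length (IZ − EZ peak depth, µm) at one location, or None if missing."""
    try:
        lrp = extract_lrp(img, x_um, width_px)
    except ValueError:
        return None
    ez_win, iz_win = _seg_windows(seg, x_um)
    ez, iz = detect_ez_iz_peaks(lrp, ez_win, iz_win)
    if ez is None or iz is None:
        return None
    return iz - ez


def find_apparent_max(
    img: BScanImage,
    seg: LayerSegmentation,
    spacing_um: float = COARSE_SCAN_SPACING_UM,
) -> float:
    """Deterministic seed for the OS-length maximum: coarse argmax scan.

    Replaces the observer's subjective pick with an argmax over a coarse
    grid spanning the scan interior.
    """
    margin = OS_SAMPLE_HALFSPAN_UM + LRP_WIDTH_PX * img.lateral_scale_um_per_px
    x = img.x_um()
    grid = np.arange(x[0] + margin, x[-1] - margin + 1e-9, spacing_um)
    best_x, best_len = None, -np.inf
    tie = 1e-9
    for xi in grid:
        L = os_length_at(img, seg, xi)
        if L is None:
            continue
        # ties break toward the scan center (flat profiles have no peak)
        if L > best_len + tie or (abs(L - best_len) <= tie and
                                  abs(xi) < abs(best_x)):
            best_x, best_len = xi, L
    if best_x is None:
        raise ValueError("no OS length measurable anywhere in the scan")
    return float(best_x)


def sample_os_lengths(
    img: BScanImage,
    seg: LayerSegmentation,
    apparent_max_x_um: float,
    spacing_um: float = OS_SAMPLE_SPACING_UM,
    halfspan_um: float = OS_SAMPLE_HALFSPAN_UM,
    max_missing_frac: float = 0.3,
) -> tuple[np.ndarray, np.ndarray]:
    """OS lengths every ``spacing_um`` within ±``halfspan_um`` of the seed.

    With the defaults (25 µm spacing, 250 µm half-span) this yields 21
    sample locations.  Raises if more than ``max_missing_frac`` of them are
    unmeasurable.
    """
    k = int(round(halfspan_um / spacing_um))
    xs = apparent_max_x_um + np.arange(-k, k + 1) * spacing_um
    lengths = np.array([os_length_at(img, seg, xi) for xi in xs], dtype=object)
    ok = np.array([L is not None for L in lengths])
    if (~ok).sum() > max_missing_frac * xs.size:
        raise ValueError(
            f"{(~ok).sum()} of {xs.size} OS-length samples missing "
            f"(> {max_missing_frac:.0%} allowed)"
        )
    return xs[ok], lengths[ok].astype(float)


def _gauss(x, a, b, c):
    return a * np.exp(-(((x - b) / c) ** 2))


def fit_gaussian_oslength(x_um: np.ndarray, os_length_um: np.ndarray) -> OSLengthFit:
    """Least-squares single-term Gaussian fit of OS length vs. location.

    Initialization: ``a`` = max sample, ``b`` = argmax location, ``c`` = half
    the sample span.  Flat or non-converging data fall back to the raw
    maximum (flagged ``fallback_flat``).
    """
    x = np.asarray(x_um, dtype=float)
    L = np.asarray(os_length_um, dtype=float)
    if x.size < 5:
        raise ValueError("need at least 5 OS-length samples to fit")
    flags: list[str] = []
    spread = L.max() - L.min()
    if spread < 1e-9 * max(1.0, abs(L.max())):
        # flat data: raw maximum, ties toward x = 0
        at_max = np.flatnonzero(L >= L.max() - 1e-12)
        b = float(x[at_max[np.argmin(np.abs(x[at_max]))]])
        return OSLengthFit(x, L, float(L.max()), b, np.inf, 0.0, False,
                           ["fallback_flat"])
    p0 = (L.max(), x[np.argmax(L)], max((x.max() - x.min()) / 2.0, 1.0))
    try:
        import warnings

        from scipy.optimize import OptimizeWarning

        with warnings.catch_warnings():
            # the parameter covariance is unused; suppress its degeneracy
            # warning on noise-free data
            warnings.simplefilter("ignore", OptimizeWarning)
            popt, _ = curve_fit(_gauss, x, L, p0=p0, maxfev=200 * (x.size + 1),
                                xtol=1e-10, ftol=1e-10)
        a, b, c = popt
        c = abs(c)
        if not (np.isfinite(a) and a > 0 and np.isfinite(c) and
                c < 100 * (x.max() - x.min())):
            raise RuntimeError("degenerate Gaussian")
        resid = L - _gauss(x, a, b, c)
        rms = float(np.sqrt(np.mean(resid**2)))
        return OSLengthFit(x, L, float(a), float(b), float(c), rms, True, flags)
    except RuntimeError:
        a, b = float(L.max()), float(x[np.argmax(L)])
        return OSLengthFit(x, L, a, b, np.inf, float(np.std(L)), False,
                           ["fallback_flat"])


def os_ratio(
    img: BScanImage,
    seg: LayerSegmentation,
    fit: OSLengthFit,
    parafovea_mm: float = OS_PARAFOVEA_MM,
) -> tuple[float, list[str]]:
    """Maximum OS length over the mean parafoveal OS length at ±1.75 mm.

    Each parafoveal value comes from a single 5-px LRP.  If only one side is
    measurable the ratio uses that side alone (flagged ``os_one_sided``).
    """
    ecc = parafovea_mm * 1000.0
    sides = []
    for sign in (+1, -1):
        L = os_length_at(img, seg, fit.b_um + sign * ecc)
        if L is not None:
            sides.append(L)
    if not sides:
        raise ValueError(f"parafoveal OS length unmeasurable at ±{ecc:.0f} µm")
    flags = list(fit.flags)
    if len(sides) == 1:
        flags.append("os_one_sided")
    para = float(np.mean(sides))
    if para <= 0:
        raise ValueError("parafoveal OS length is nonpositive")
    return fit.a_um / para, flags


def measure_os(
    img: BScanImage,
    seg: LayerSegmentation,
    parafovea_mm: float = OS_PARAFOVEA_MM,
) -> tuple[OSLengthFit, float, list[str]]:
    """Full OS pipeline: seed, dense sampling, Gaussian fit, OS ratio."""
    seed_x = find_apparent_max(img, seg)
    xs, lengths = sample_os_lengths(img, seg, seed_x)
    fit = fit_gaussian_oslength(xs, lengths)
    ratio, flags = os_ratio(img, seg, fit, parafovea_mm)
    return fit, ratio, flags
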