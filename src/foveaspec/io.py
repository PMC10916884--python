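"""File formats: segmentation CSV, B-scan TIFF with JSON sidecar, cohort CSV.

All text files are UTF-8, comma-separated with a header row and '.' decimal.
Segmentation CSV columns are ``x_px`` followed by one depth-µm column per
surface (depth 0 = top of image).  B-scans are 16-bit grayscale TIFFs whose
physical scales live in a ``<name>.json`` sidecar.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .layers import SURFACES, LayerSegmentation
from .preprocess import BScanImage

COHORT_COLUMNS = [
    "id", "age_years", "sex", "age18",
    "irl_ratio", "os_ratio", "onl_ratio", "grade", "bcva_logmar",
]


def write_segmentation_csv(seg: LayerSegmentation, path: str | Path) -> None:
    df = pd.DataFrame({"x_px": np.arange(seg.x_um.size)})
    for s in SURFACES:
        df[s] = seg.surfaces[s]
    df.to_csv(path, index=False)


def read_segmentation_csv(
    path: str | Path,
    lateral_scale_um_per_px: float,
    laterality: str = "OD",
) -> LayerSegmentation:
    df = pd.read_csv(path)
    missing = [s for s in SURFACES if s not in df.columns]
    if missing:
        raise ValueError(f"segmentation CSV missing columns: {missing}")
    n = len(df)
    center = (n - 1) / 2.0
    x_um = (df["x_px"].to_numpy(dtype=float) - center) * lateral_scale_um_per_px
    seg = LayerSegmentation(
        x_um=x_um,
        surfaces={s: df[s].to_numpy(dtype=float) for s in SURFACES},
        lateral_scale_um_per_px=lateral_scale_um_per_px,
        laterality=laterality,
    )
    return seg.mirrored() if laterality == "OS" else seg


def write_bscan_tiff(img: BScanImage, path: str | Path,
                     metadata: dict | None = None) -> None:
    """16-bit grayscale TIFF plus a JSON sidecar holding the scales."""
    path = Path(path)
    data = img.data
    peak = data.max() if data.max() > 0 else 1.0
    scaled = np.round(data / peak * 65535.0).astype(np.uint16)
    tifffile.imwrite(path, scaled)
    sidecar = {
        "axial_scale_um_per_px": img.axial_scale_um_per_px,
        "lateral_scale_um_per_px": img.lateral_scale_um_per_px,
        "intensity_peak": float(peak),
    }
    if metadata:
        sidecar.update(metadata)
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_bscan(path: str | Path) -> BScanImage:
    """Read a TIFF/PNG B-scan; scales come from the JSON sidecar."""
    path = Path(path)
    sidecar_path = path.with_suffix(".json")
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing metadata sidecar {sidecar_path}")
    meta = json.loads(sidecar_path.read_text())
    if path.suffix.lower() in (".tif", ".tiff"):
        data = tifffile.imread(path).astype(float)
    else:
        from PIL import Image

        data = np.asarray(Image.open(path).convert("I")).astype(float)
    if "intensity_peak" in meta:
        data = data / 65535.0 * meta["intensity_peak"]
    return BScanImage(
        data,
        axial_scale_um_per_px=meta["axial_scale_um_per_px"],
        lateral_scale_um_per_px=meta["lateral_scale_um_per_px"],
    )


def write_cohort_csv(cohort: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in COHORT_COLUMNS if c in cohort.columns]
    cols += [c for c in cohort.columns if c not in cols]
    cohort[cols].to_csv(path, index=False)


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"grade": str})
    required = {"irl_ratio", "os_ratio", "onl_ratio", "bcva_logmar"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"cohort CSV missing columns: {sorted(missing)}")
    return df
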