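"""File formats: OME-TIFF slides, 0/1 TIFF masks, CSV tables.

Slides travel as multi-page OME-TIFF with channel order
(nuclear, epithelial, drug) and the pixel size recorded in the OME
metadata. Masks are 0/1 uint8 TIFFs, nucleus centers and FOV plans are
plain CSV (0-based row/col pixel coordinates), and reports are JSON.
"""

from __future__ import annotations

import json
import logging
import os
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .acquisition import FOVPlan
from .errors import MissingCalibrationError, MissingChannelError
from .segmentation import BinaryMask, NucleusSet
from .synthetic_tissue import GroundTruth, PixelCalibration, SlideImage

logger = logging.getLogger(__name__)

CHANNEL_ORDER = ("nuclear", "epithelial", "drug")

# stain-name fallbacks for channel-role mapping when reading foreign files
ROLE_ALIASES = {
    "nuclear": ("nuclear", "dapi", "hoechst", "nucleus"),
    "epithelial": ("epithelial", "epcam", "epithelium"),
    "drug": ("drug", "647", "a647", "antibody"),
}


def save_slide(slide: SlideImage, path) -> Path:
    """Write a slide as OME-TIFF (CYX, float32, pixel size in um)."""
    path = Path(path)
    stack = np.stack([slide.channels[r] for r in CHANNEL_ORDER]).astype(np.float32)
    mpp = slide.calibration.microns_per_pixel
    tifffile.imwrite(
        path,
        stack,
        ome=True,
        photometric="minisblack",
        metadata={
            "axes": "CYX",
            "Channel": {"Name": list(CHANNEL_ORDER)},
            "PhysicalSizeX": mpp,
            "PhysicalSizeXUnit": "µm",
            "PhysicalSizeY": mpp,
            "PhysicalSizeYUnit": "µm",
        },
    )
    return path


def _ome_channel_names(tf: tifffile.TiffFile) -> list[str]:
    if not tf.ome_metadata:
        return []
    meta = tifffile.xml2dict(tf.ome_metadata)
    try:
        channels = meta["OME"]["Image"]["Pixels"]["Channel"]
    except (KeyError, TypeError):
        return []
    if isinstance(channels, dict):
        channels = [channels]
    return [str(c.get("Name", "")) for c in channels]


def _ome_pixel_size(tf: tifffile.TiffFile) -> float | None:
    if not tf.ome_metadata:
        return None
    meta = tifffile.xml2dict(tf.ome_metadata)
    try:
        return float(meta["OME"]["Image"]["Pixels"]["PhysicalSizeX"])
    except (KeyError, TypeError, ValueError):
        return None


def _role_for_name(name: str) -> str | None:
    low = name.lower()
    for role, aliases in ROLE_ALIASES.items():
        if any(a in low for a in aliases):
            return role
    return None


def load_slide(
    path,
    channel_map: dict[str, int] | None = None,
    calibration_um_per_px: float | None = None,
) -> SlideImage:
    """Read an OME-TIFF slide, mapping channels to roles.

    Roles come from an explicit ``channel_map`` (role -> page index) or
    else from OME channel names. A config calibration overrides file
    metadata (with a warning when the two disagree); with neither a
    :class:`MissingCalibrationError` is raised.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        names = _ome_channel_names(tf)
        meta_mpp = _ome_pixel_size(tf)
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise MissingChannelError(f"expected a CYX stack, got shape {data.shape}")

    if channel_map is None:
        channel_map = {}
        for idx, name in enumerate(names):
            role = _role_for_name(name)
            if role is not None and role not in channel_map:
                channel_map[role] = idx
    missing = [r for r in CHANNEL_ORDER if r not in channel_map]
    if missing:
        raise MissingChannelError(
            f"{path.name}: no channel for role(s) {missing}; "
            f"file channels: {names or data.shape[0]}"
        )
    for role, idx in channel_map.items():
        if not (0 <= idx < data.shape[0]):
            raise MissingChannelError(f"channel index {idx} for {role!r} out of range")

    if calibration_um_per_px is not None:
        if meta_mpp is not None and abs(meta_mpp - calibration_um_per_px) > 1e-9:
            warnings.warn(
                f"config pixel size {calibration_um_per_px} overrides file "
                f"metadata {meta_mpp}",
                stacklevel=2,
            )
        mpp = calibration_um_per_px
    elif meta_mpp is not None:
        mpp = meta_mpp
    else:
        raise MissingCalibrationError(f"{path.name}: no pixel size in metadata or config")

    channels = {role: np.maximum(data[idx].astype(float), 0.0)
                for role, idx in channel_map.items()}
    return SlideImage(channels=channels, calibration=PixelCalibration(mpp))


def save_mask(mask: BinaryMask | np.ndarray, path) -> Path:
    path = Path(path)
    m = mask.mask if isinstance(mask, BinaryMask) else np.asarray(mask).astype(bool)
    tifffile.imwrite(path, m.astype(np.uint8), photometric="minisblack")
    return path


def load_mask(path, calibration: PixelCalibration) -> BinaryMask:
    return BinaryMask(tifffile.imread(path) > 0, calibration)


def save_points_csv(points: NucleusSet | np.ndarray, path) -> Path:
    """Nucleus centers as CSV (row_px, col_px), matching point-click exports."""
    path = Path(path)
    centers = points.centers if isinstance(points, NucleusSet) else np.asarray(points)
    pd.DataFrame(centers.reshape(-1, 2), columns=["row_px", "col_px"]).to_csv(
        path, index=False
    )
    return path


def load_points_csv(path) -> NucleusSet:
    df = pd.read_csv(path)
    return NucleusSet(centers=df[["row_px", "col_px"]].to_numpy(dtype=float))


def save_ground_truth(truth: GroundTruth, outdir) -> dict[str, Path]:
    """Ground truth as label/float TIFFs plus a nucleus-center CSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "epithelium_mask": outdir / "truth_epithelium_mask.tif",
        "specific_drug": outdir / "truth_specific_drug.tif",
        "interstitial_drug": outdir / "truth_interstitial_drug.tif",
        "vignette_field": outdir / "truth_vignette_field.tif",
        "nucleus_centers": outdir / "truth_nucleus_centers.csv",
    }
    tifffile.imwrite(paths["epithelium_mask"], truth.epithelium_mask.astype(np.uint8))
    for key in ("specific_drug", "interstitial_drug", "vignette_field"):
        tifffile.imwrite(paths[key], getattr(truth, key).astype(np.float32))
    save_points_csv(truth.nucleus_centers, paths["nucleus_centers"])
    return paths


def save_fov_plan(plan: FOVPlan, path) -> Path:
    path = Path(path)
    h, w = plan.fov_size_px
    rows = [
        {"tile_id": i, "row0": r, "col0": c, "height": h, "width": w}
        for i, (r, c) in enumerate(plan.origins)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def load_fov_plan(path, overlap_frac: float) -> FOVPlan:
    df = pd.read_csv(path)
    size = (int(df["height"].iloc[0]), int(df["width"].iloc[0]))
    origins = tuple((int(r), int(c)) for r, c in zip(df["row0"], df["col0"]))
    return FOVPlan(fov_size_px=size, overlap_frac=overlap_frac, origins=origins)


def write_json_atomic(obj: dict, path) -> Path:
    """Write JSON via a temp file + rename so readers never see a torso."""
    path = Path(path)
    tmp = path.with_suffix(path.suffix + ".tmp")
    tmp.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_json_default))
    os.replace(tmp, path)
    return path


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
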