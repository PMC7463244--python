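"""Two-pass whole-slide acquisition emulation.

High-content slide readers image a slide in two passes: a fast
low-magnification survey of the nuclear channel locates the tissue
(the region of interest, ROI), and the ROI is then re-imaged at high
magnification as a grid of overlapping camera fields of view (FOVs).
Each FOV carries the same multiplicative illumination (vignetting)
profile; a retrospective flat-field correction estimated from the FOV
stack removes it, and the corrected FOVs are blended into a seamless
montage for analysis.

Conventions: 0-based (row, col) pixel coordinates, half-open boxes,
row-major tile order. FOV plan origins are expressed in the ROI frame.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import filters, measure

from .errors import EmptyImageError, InvalidParameterError, ShapeMismatchError

logger = logging.getLogger(__name__)

DEFAULT_OVERLAP_FRAC = 0.10  # overlap between adjacent FOVs
DEFAULT_MIN_AREA_PX = 500  # smallest low-res component kept as tissue


@dataclass(frozen=True)
class ROIBox:
    """Half-open pixel box ``[top, top+height) x [left, left+width)``."""

    top: int
    left: int
    height: int
    width: int

    def __post_init__(self):
        if self.height <= 0 or self.width <= 0:
            raise InvalidParameterError("ROIBox height and width must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.height, self.width)

    def slices(self) -> tuple[slice, slice]:
        return (
            slice(self.top, self.top + self.height),
            slice(self.left, self.left + self.width),
        )


@dataclass(frozen=True)
class FOVPlan:
    """Row-major grid of overlapping tiles covering a ROI.

    ``origins`` are (row, col) tile corners in the ROI frame; the last
    row/column of tiles is clamped so the grid ends exactly at the ROI
    edge.
    """

    fov_size_px: tuple[int, int]
    overlap_frac: float
    origins: tuple[tuple[int, int], ...]

    @property
    def n_tiles(self) -> int:
        return len(self.origins)

    @property
    def roi_shape(self) -> tuple[int, int]:
        h, w = self.fov_size_px
        return (
            max(o[0] for o in self.origins) + h,
            max(o[1] for o in self.origins) + w,
        )


@dataclass(frozen=True)
class IlluminationField:
    """Strictly positive per-FOV illumination profile, normalized to mean 1."""

    field: np.ndarray = field(repr=False)

    def __post_init__(self):
        f = np.asarray(self.field, dtype=float)
        if not np.all(f > 0):
            raise InvalidParameterError("illumination field must be strictly positive")
        if abs(f.mean() - 1.0) > 1e-6:
            raise InvalidParameterError("illumination field must have mean 1")
        object.__setattr__(self, "field", f)


def _threshold(image: np.ndarray, method) -> float:
    if callable(method):
        return float(method(image))
    if isinstance(method, (int, float)):
        return float(method)
    if method == "otsu":
        return float(filters.threshold_otsu(image))
    if method == "mean":
        return float(image.mean())
    raise InvalidParameterError(f"unknown threshold method {method!r}")


def prescan_roi(
    lowres_nuclear: np.ndarray,
    threshold_method="otsu",
    min_area_px: int = DEFAULT_MIN_AREA_PX,
    downsample: int = 1,
) -> list[ROIBox]:
    """Survey the low-magnification nuclear channel for tissue regions.

    The image is thresholded (Otsu by default), connected foreground
    components with at least ``min_area_px`` low-res pixels are kept,
    and their bounding boxes are scaled by ``downsample`` into the
    high-magnification frame.

    Returns an empty list when no foreground is found.
    """
    img = np.asarray(lowres_nuclear, dtype=float)
    if img.size == 0:
        raise EmptyImageError("pre-scan image is empty")
    if downsample < 1:
        raise InvalidParameterError("downsample factor must be >= 1")
    if img.max() == img.min():
        # constant image: no contrast, no tissue (covers the all-zero case)
        return []
    thr = _threshold(img, threshold_method)
    fg = img > thr
    labels = measure.label(fg, connectivity=2)
    boxes: list[ROIBox] = []
    for region in measure.regionprops(labels):
        if region.area < min_area_px:
            continue
        r0, c0, r1, c1 = region.bbox
        boxes.append(
            ROIBox(
                top=r0 * downsample,
                left=c0 * downsample,
                height=(r1 - r0) * downsample,
                width=(c1 - c0) * downsample,
            )
        )
    boxes.sort(key=lambda b: (b.top, b.left))
    logger.info("prescan found %d ROI(s)", len(boxes))
    return boxes


def merge_roi_boxes(boxes: list[ROIBox]) -> ROIBox:
    """Bounding box of a nonempty list of ROI boxes."""
    if not boxes:
        raise EmptyImageError("no ROI boxes to merge")
    top = min(b.top for b in boxes)
    left = min(b.left for b in boxes)
    bottom = max(b.top + b.height for b in boxes)
    right = max(b.left + b.width for b in boxes)
    return ROIBox(top, left, bottom - top, right - left)


def _axis_origins(roi_size: int, fov_size: int, stride: int) -> list[int]:
    if fov_size >= roi_size:
        return [0]
    origins = list(range(0, roi_size - fov_size + 1, stride))
    if origins[-1] != roi_size - fov_size:
        origins.append(roi_size - fov_size)  # clamp last tile to the edge
    return origins


def plan_fovs(
    roi: ROIBox,
    fov_size_px: tuple[int, int],
    overlap_frac: float = DEFAULT_OVERLAP_FRAC,
) -> FOVPlan:
    """Lay out a row-major grid of FOVs covering ``roi``.

    The stride between adjacent tiles is ``round(size * (1 - overlap_frac))``
    per axis; the final row/column is clamped so tiles end exactly at the
    ROI edge, guaranteeing full coverage. A FOV larger than the ROI yields
    a single-tile plan.
    """
    if not (0 <= overlap_frac < 1):
        raise InvalidParameterError("overlap_frac must be in [0, 1)")
    fh, fw = int(fov_size_px[0]), int(fov_size_px[1])
    if fh <= 0 or fw <= 0:
        raise InvalidParameterError("fov size must be positive")
    strides = (max(1, round(fh * (1 - overlap_frac))), max(1, round(fw * (1 - overlap_frac))))
    rows = _axis_origins(roi.height, fh, strides[0])
    cols = _axis_origins(roi.width, fw, strides[1])
    origins = tuple((r, c) for r in rows for c in cols)
    return FOVPlan(fov_size_px=(fh, fw), overlap_frac=float(overlap_frac), origins=origins)


def crop_fovs(image: np.ndarray, plan: FOVPlan) -> list[np.ndarray]:
    """Cut the planned tiles out of an image given in the ROI frame."""
    fh, fw = plan.fov_size_px
    h, w = image.shape
    if h < fh or w < fw:
        raise ShapeMismatchError("image smaller than one FOV")
    return [np.array(image[r : r + fh, c : c + fw]) for r, c in plan.origins]


def flatfield_correct(
    fovs: list[np.ndarray],
    smooth_sigma_px: float | None = None,
) -> tuple[list[np.ndarray], IlluminationField]:
    """Estimate and remove the shared illumination profile of a FOV stack.

    The field is the smoothed per-pixel median across FOVs, normalized to
    mean 1 — a retrospective multi-image estimate that needs no reference
    image. With a single FOV the input is returned unchanged under a unit
    field (warned). A median that reaches zero anywhere is floored at
    1e-6 of the field mean (warned).
    """
    if len(fovs) == 0:
        raise EmptyImageError("no FOVs to correct")
    shape = fovs[0].shape
    for f in fovs:
        if f.shape != shape:
            raise ShapeMismatchError("FOVs differ in shape")
    if len(fovs) == 1:
        warnings.warn("single FOV: flat-field correction skipped", stacklevel=2)
        return [np.array(fovs[0], dtype=float)], IlluminationField(np.ones(shape))
    stack = np.stack([np.asarray(f, dtype=float) for f in fovs])
    med = np.median(stack, axis=0)
    if smooth_sigma_px is None:
        smooth_sigma_px = min(shape) / 8.0
    fld = ndimage.gaussian_filter(med, smooth_sigma_px, mode="nearest")
    floor = 1e-6 * max(fld.mean(), np.finfo(float).tiny)
    if np.any(fld <= 0):
        warnings.warn("degenerate illumination field: flooring non-positive pixels", stacklevel=2)
        fld = np.maximum(fld, floor)
    mean = fld.mean()
    if mean <= 0:
        warnings.warn("degenerate illumination field: using unit field", stacklevel=2)
        fld = np.ones(shape)
        mean = 1.0
    fld = fld / mean
    corrected = [stack[i] / fld for i in range(len(fovs))]
    return corrected, IlluminationField(fld)


def _feather_ramp(size: int, margin: int) -> np.ndarray:
    """Per-axis blend weight: linear ramp of ``margin`` px at both ends."""
    i = np.arange(size, dtype=float)
    w = np.minimum.reduce([i + 1.0, size - i, np.full(size, margin + 1.0)])
    return w / (margin + 1.0)


def stitch(fovs: list[np.ndarray], plan: FOVPlan) -> np.ndarray:
    """Blend planned FOVs into a single montage over the ROI.

    Each tile is weighted by a separable linear feather ramp over the
    overlap margins; the output is the weight-normalized average, so a
    pixel covered by exactly one tile reproduces that tile exactly and
    seams are continuous.
    """
    if len(fovs) != len(plan.origins):
        raise ShapeMismatchError(
            f"plan has {len(plan.origins)} tiles but {len(fovs)} FOVs were given"
        )
    fh, fw = plan.fov_size_px
    for f in fovs:
        if f.shape != (fh, fw):
            raise ShapeMismatchError("FOV shape does not match the plan")
    out_shape = plan.roi_shape
    margin_r = max(fh - max(1, round(fh * (1 - plan.overlap_frac))), 0)
    margin_c = max(fw - max(1, round(fw * (1 - plan.overlap_frac))), 0)
    weight = np.outer(_feather_ramp(fh, margin_r), _feather_ramp(fw, margin_c))
    acc = np.zeros(out_shape)
    wacc = np.zeros(out_shape)
    ncov = np.zeros(out_shape, dtype=int)
    for (r, c), tile in zip(plan.origins, fovs):
        acc[r : r + fh, c : c + fw] += weight * np.asarray(tile, dtype=float)
        wacc[r : r + fh, c : c + fw] += weight
        ncov[r : r + fh, c : c + fw] += 1
    out = acc / wacc
    # single-coverage pixels reproduce their tile bit-exactly
    for (r, c), tile in zip(plan.origins, fovs):
        window = np.s_[r : r + fh, c : c + fw]
        single = ncov[window] == 1
        out[window][single] = np.asarray(tile, dtype=float)[single]
    return out
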