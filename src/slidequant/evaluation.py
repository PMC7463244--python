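"""Validation statistics for segmentation and detection.

Two field-standard checks: Intersection-Over-Union (IOU) between a
predicted and a ground-truth mask, and the tile-based comparison of two
nucleus counts — the annotated region is gridded into squares of 104 um
across, nuclei are counted per square for both sources, and the squared
Pearson correlation (R^2) of the paired counts summarizes agreement.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .acquisition import ROIBox
from .errors import EmptyInputError, InvalidParameterError, ShapeMismatchError
from .segmentation import BinaryMask, NucleusSet
from .synthetic_tissue import PixelCalibration

logger = logging.getLogger(__name__)

DEFAULT_TILE_SIZE_UM = 104.0


@dataclass(frozen=True)
class EvalConfig:
    tile_size_um: float = DEFAULT_TILE_SIZE_UM
    expected_tiles: int | None = None
    match_radius_um: float = 5.0

    def __post_init__(self):
        if self.tile_size_um <= 0:
            raise InvalidParameterError("tile_size_um must be > 0")


@dataclass
class EvalReport:
    iou: float | None
    tile_pairs: list[tuple[int, int, int]]  # (tile_id, count_a, count_b)
    r_squared: float | None

    def __post_init__(self):
        for name in ("iou", "r_squared"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0):
                raise InvalidParameterError(f"{name} must be in [0, 1]")

    def to_dict(self) -> dict:
        return {
            "iou": self.iou,
            "r_squared": self.r_squared,
            "tile_pairs": [list(t) for t in self.tile_pairs],
        }


def iou(pred: BinaryMask | np.ndarray, truth: BinaryMask | np.ndarray) -> float:
    """Intersection-Over-Union of two binary masks.

    |pred AND truth| / |pred OR truth|: 1 for identical nonempty masks,
    0 for disjoint ones. Undefined (error) when both masks are empty.
    """
    p = pred.mask if isinstance(pred, BinaryMask) else np.asarray(pred).astype(bool)
    t = truth.mask if isinstance(truth, BinaryMask) else np.asarray(truth).astype(bool)
    if p.shape != t.shape:
        raise ShapeMismatchError("mask shapes differ")
    union = int(np.logical_or(p, t).sum())
    if union == 0:
        raise EmptyInputError("IOU undefined: both masks are empty")
    inter = int(np.logical_and(p, t).sum())
    return inter / union


def tile_nucleus_counts(
    points_a: NucleusSet,
    points_b: NucleusSet,
    region: ROIBox,
    calibration: PixelCalibration,
    tile_size_um: float = DEFAULT_TILE_SIZE_UM,
) -> list[tuple[int, int, int]]:
    """Per-tile paired nucleus counts over a gridded region.

    The region is divided into floor(h/t) x floor(w/t) full square tiles
    of ``tile_size_um`` across (half-open, so every point lies in exactly
    one tile); points outside the full-tile area are dropped with a
    warning. Returns (tile_id, count_a, count_b) rows in row-major order.
    """
    if tile_size_um <= 0:
        raise InvalidParameterError("tile_size_um must be > 0")
    t_px = int(round(calibration.to_px(tile_size_um)))
    n_rows, n_cols = region.height // t_px, region.width // t_px
    if n_rows == 0 or n_cols == 0:
        raise InvalidParameterError(
            f"region {region.height}x{region.width} px holds no full "
            f"{t_px} px tile"
        )

    def counts(points: NucleusSet) -> np.ndarray:
        c = np.zeros(n_rows * n_cols, dtype=int)
        if len(points) == 0:
            return c
        rel = np.asarray(points.centers, dtype=float) - [region.top, region.left]
        ti = np.floor(rel / t_px).astype(int)
        inside = (
            (rel[:, 0] >= 0) & (rel[:, 1] >= 0)
            & (ti[:, 0] < n_rows) & (ti[:, 1] < n_cols)
        )
        dropped = int((~inside).sum())
        if dropped:
            warnings.warn(f"{dropped} point(s) outside the full-tile grid dropped",
                          stacklevel=3)
        flat = ti[inside, 0] * n_cols + ti[inside, 1]
        np.add.at(c, flat, 1)
        return c

    ca, cb = counts(points_a), counts(points_b)
    return [(i, int(a), int(b)) for i, (a, b) in enumerate(zip(ca, cb))]


def r_squared(x, y) -> float:
    """Squared Pearson correlation of two paired count series."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ShapeMismatchError("x and y must be equal-length 1D series")
    if len(x) < 3:
        raise InvalidParameterError("need at least 3 pairs")
    if x.std() == 0 or y.std() == 0:
        raise InvalidParameterError("zero variance: correlation undefined")
    r = stats.pearsonr(x, y).statistic
    return float(min(r * r, 1.0))


def evaluate_nucleus_counts(
    points_a: NucleusSet,
    points_b: NucleusSet,
    region: ROIBox,
    calibration: PixelCalibration,
    config: EvalConfig | None = None,
) -> EvalReport:
    """Tile both point sets over ``region`` and correlate the counts."""
    config = config or EvalConfig()
    pairs = tile_nucleus_counts(points_a, points_b, region, calibration,
                                config.tile_size_um)
    if config.expected_tiles is not None and len(pairs) != config.expected_tiles:
        warnings.warn(
            f"{len(pairs)} tiles laid out, expected {config.expected_tiles}",
            stacklevel=2,
        )
    a = np.array([p[1] for p in pairs], dtype=float)
    b = np.array([p[2] for p in pairs], dtype=float)
    r2 = None
    try:
        r2 = r_squared(a, b)
    except InvalidParameterError as exc:
        warnings.warn(f"R^2 unavailable: {exc}", stacklevel=2)
    return EvalReport(iou=None, tile_pairs=pairs, r_squared=r2)
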