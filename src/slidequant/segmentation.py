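"""Nucleus detection and epithelium segmentation.

Two interchangeable backends produce the same domain objects
(:class:`NucleusSet`, :class:`BinaryMask`):

* a deterministic classical baseline — Laplacian-of-Gaussian blob
  detection for nuclei and smoothed Otsu thresholding with
  morphological cleanup for the epithelium — used by default;
* a small trainable encoder–decoder (2 resolution levels with skip
  connections, NumPy forward/backward) optimizing a weighted soft-max
  cross-entropy, mirroring the original U-Net training protocol at
  desk scale (default learning rate 1e-5; 6,000 iterations for
  epithelium, 10,000 for nuclei, both scalable down).
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import morphology

from .acquisition import _threshold
from .errors import InvalidParameterError, ShapeMismatchError
from .synthetic_tissue import PixelCalibration

logger = logging.getLogger(__name__)

DEFAULT_NUCLEUS_RADIUS_UM = 3.5  # half the 7-um whole-cell proxy
DEFAULT_MIN_SEPARATION_UM = 5.0

MODEL_FORMAT_VERSION = "slidequant-segmodel-1"


@dataclass
class NucleusSet:
    """Detected or annotated nucleus centers, (row, col) pixel coordinates."""

    centers: np.ndarray  # (n, 2)
    scores: np.ndarray | None = None

    def __post_init__(self):
        self.centers = np.asarray(self.centers, dtype=float).reshape(-1, 2)
        if self.scores is not None:
            self.scores = np.asarray(self.scores, dtype=float).reshape(-1)
            if len(self.scores) != len(self.centers):
                raise ShapeMismatchError("scores and centers lengths differ")

    def __len__(self) -> int:
        return len(self.centers)


@dataclass
class BinaryMask:
    """0/1 segmentation mask with pixel calibration."""

    mask: np.ndarray
    calibration: PixelCalibration

    def __post_init__(self):
        m = np.asarray(self.mask)
        if m.dtype != bool:
            uniq = np.unique(m)
            if not np.all(np.isin(uniq, (0, 1))):
                raise InvalidParameterError("mask values must be 0 or 1")
            m = m.astype(bool)
        self.mask = m

    @property
    def area_px(self) -> int:
        return int(self.mask.sum())

    @property
    def area_um2(self) -> float:
        return self.calibration.to_um2(self.area_px)


# ---------------------------------------------------------------------------
# Classical baseline backend
# ---------------------------------------------------------------------------


def _greedy_local_maxima(
    response: np.ndarray,
    min_sep_px: float,
    threshold_rel: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Local maxima of ``response`` above ``threshold_rel * max``, greedily
    suppressed within ``min_sep_px``; ties broken by (row, col) order."""
    peak = float(response.max(initial=0.0))
    if peak <= 0:
        return np.empty((0, 2), dtype=int), np.empty(0)
    maxfilt = ndimage.maximum_filter(response, size=3, mode="constant", cval=-np.inf)
    cand = np.argwhere((response >= maxfilt) & (response >= threshold_rel * peak) & (response > 0))
    if len(cand) == 0:
        return np.empty((0, 2), dtype=int), np.empty(0)
    scores = response[cand[:, 0], cand[:, 1]]
    # strongest first; lexicographic (row, col) on equal scores
    order = np.lexsort((cand[:, 1], cand[:, 0], -scores))
    cand, scores = cand[order], scores[order]
    accepted: list[int] = []
    acc = np.empty((0, 2), dtype=float)
    d2 = min_sep_px**2
    for i, p in enumerate(cand):
        if len(accepted) and np.min(np.sum((acc - p) ** 2, axis=1)) < d2:
            continue
        accepted.append(i)
        acc = cand[accepted].astype(float)
    return cand[accepted], scores[accepted]


def detect_nuclei_baseline(
    nuclear: np.ndarray,
    calibration: PixelCalibration,
    expected_radius_um: float = DEFAULT_NUCLEUS_RADIUS_UM,
    min_separation_um: float = DEFAULT_MIN_SEPARATION_UM,
    threshold_rel: float = 0.1,
) -> NucleusSet:
    """Single-scale Laplacian-of-Gaussian blob detector for nuclei.

    The response is the scale-normalized negated LoG at sigma matched to
    ``expected_radius_um``; centers are its local maxima above
    ``threshold_rel`` of the global peak, with greedy suppression so no
    two accepted centers fall within ``min_separation_um``. Fully
    deterministic; ties resolved lexicographically.
    """
    if expected_radius_um <= 0:
        raise InvalidParameterError("expected_radius_um must be > 0")
    r_px = calibration.to_px(expected_radius_um)
    if r_px < 1:
        raise InvalidParameterError(
            f"expected radius {expected_radius_um} um is below 1 px at "
            f"{calibration.microns_per_pixel} um/px"
        )
    sigma = r_px / math.sqrt(2.0)
    img = np.asarray(nuclear, dtype=float)
    response = -(sigma**2) * ndimage.gaussian_laplace(img, sigma, mode="reflect")
    centers, scores = _greedy_local_maxima(
        response, calibration.to_px(min_separation_um), threshold_rel
    )
    return NucleusSet(centers=centers, scores=scores)


def segment_epithelium_baseline(
    epithelial: np.ndarray,
    calibration: PixelCalibration,
    smooth_sigma_um: float = 1.5,
    threshold_method="otsu",
    min_object_um2: float = 100.0,
    fill_holes_um2: float = 50.0,
) -> BinaryMask:
    """Smoothed-threshold epithelium segmentation with size cleanup.

    The marker channel is Gaussian-smoothed, thresholded (Otsu by
    default), objects smaller than ``min_object_um2`` are removed and
    holes smaller than ``fill_holes_um2`` are filled. The hole budget is
    kept small so crypt lumens — genuine holes far larger than noise
    speckle — survive. A constant image has no threshold: an all-zero
    mask is returned with a warning.
    """
    img = np.asarray(epithelial, dtype=float)
    if img.size == 0:
        raise InvalidParameterError("empty image")
    if img.max() == img.min():
        warnings.warn("constant image: returning empty epithelium mask", stacklevel=2)
        return BinaryMask(np.zeros(img.shape, dtype=bool), calibration)
    smoothed = ndimage.gaussian_filter(img, calibration.to_px(smooth_sigma_um), mode="reflect")
    mask = smoothed > _threshold(smoothed, threshold_method)
    px_per_um2 = 1.0 / calibration.microns_per_pixel**2
    # remove areas strictly below the um^2 floors (max_size removes <= its value)
    min_obj_px = max(int(math.ceil(min_object_um2 * px_per_um2)) - 1, 0)
    min_hole_px = max(int(math.ceil(fill_holes_um2 * px_per_um2)) - 1, 0)
    mask = morphology.remove_small_objects(mask, max_size=min_obj_px)
    mask = morphology.remove_small_holes(mask, max_size=min_hole_px)
    return BinaryMask(mask, calibration)


# ---------------------------------------------------------------------------
# Weighted soft-max cross-entropy
# ---------------------------------------------------------------------------


def weighted_softmax_xent(
    scores: np.ndarray,
    labels: np.ndarray,
    weights: np.ndarray,
) -> float:
    """Per-pixel weighted soft-max cross-entropy.

    ``scores`` has shape (..., C); ``labels`` integer class indices and
    ``weights`` non-negative, both of shape (...). Returns

        sum_p w_p * (-log softmax(scores_p)[label_p]) / sum_p w_p,

    which is invariant to adding a constant to all class scores at a
    pixel and to rescaling all weights.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    weights = np.asarray(weights, dtype=float)
    if scores.shape[:-1] != labels.shape or labels.shape != weights.shape:
        raise ShapeMismatchError("scores/labels/weights shapes disagree")
    if np.any(weights < 0):
        raise InvalidParameterError("weights must be >= 0")
    wsum = weights.sum()
    if wsum == 0:
        raise InvalidParameterError("weights must not be all zero")
    shifted = scores - scores.max(axis=-1, keepdims=True)
    logz = np.log(np.exp(shifted).sum(axis=-1))
    picked = np.take_along_axis(shifted, labels[..., None].astype(int), axis=-1)[..., 0]
    return float((weights * (logz - picked)).sum() / wsum)


def border_weight_map(labels: np.ndarray, border_px: int = 3, border_weight: float = 3.0) -> np.ndarray:
    """Uniform weights with extra emphasis within ``border_px`` of label
    boundaries, sharpening thin structures during training."""
    lab = np.asarray(labels).astype(bool)
    edge = lab ^ ndimage.binary_erosion(lab)
    near = ndimage.binary_dilation(edge, iterations=max(border_px, 1))
    w = np.ones(lab.shape)
    w[near] = border_weight
    return w


# ---------------------------------------------------------------------------
# Trainable encoder-decoder backend (NumPy)
# ---------------------------------------------------------------------------


@dataclass
class TrainingConfig:
    """Optimization settings for the trainable backend.

    Defaults follow the original fine-tuning protocol (learning rate
    1e-5; 6,000 iterations for epithelium, 10,000 for nuclei); both are
    scalable down for desk-scale runs.
    """

    learning_rate: float = 1e-5
    iterations: int = 6000
    tile_size_px: int = 64
    batch_size: int = 4
    seed: int = 0
    widths: tuple[int, int] = (8, 16)

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise InvalidParameterError("learning_rate must be > 0")
        if self.iterations < 1:
            raise InvalidParameterError("iterations must be >= 1")


@dataclass
class SegModelState:
    """Serializable parameters of the trainable encoder-decoder."""

    arch: dict
    params: dict[str, np.ndarray]
    norm: tuple[float, float]  # (mean, sd) of training intensities
    classes: tuple[str, str] = ("background", "foreground")
    version: str = MODEL_FORMAT_VERSION
    loss_trace: np.ndarray | None = field(default=None, repr=False)

    def save(self, path):
        meta = {
            "arch": self.arch,
            "norm": list(self.norm),
            "classes": list(self.classes),
            "version": self.version,
        }
        np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 **self.params)

    @classmethod
    def load(cls, path) -> "SegModelState":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            if meta["version"] != MODEL_FORMAT_VERSION:
                raise InvalidParameterError(f"unsupported model version {meta['version']}")
            params = {k: data[k] for k in data.files if k != "__meta__"}
        return cls(
            arch=meta["arch"],
            params=params,
            norm=tuple(meta["norm"]),
            classes=tuple(meta["classes"]),
        )


def _conv_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray):
    """Same-padded 3x3 (or 1x1) convolution. x: (C,H,W), w: (Co,Ci,k,k)."""
    co, ci, k, _ = w.shape
    pad = k // 2
    xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad)))
    h, wd = x.shape[1:]
    windows = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(1, 2))
    cols = windows.transpose(0, 3, 4, 1, 2).reshape(ci * k * k, h * wd)
    out = (w.reshape(co, -1) @ cols + b[:, None]).reshape(co, h, wd)
    return out, cols


def _conv_backward(dout: np.ndarray, cols: np.ndarray, w: np.ndarray, x_shape):
    co, ci, k, _ = w.shape
    h, wd = x_shape[1:]
    dflat = dout.reshape(co, -1)
    dw = (dflat @ cols.T).reshape(w.shape)
    db = dflat.sum(axis=1)
    dcols = (w.reshape(co, -1).T @ dflat).reshape(ci, k, k, h, wd)
    pad = k // 2
    dxp = np.zeros((ci, h + 2 * pad, wd + 2 * pad))
    for i in range(k):
        for j in range(k):
            dxp[:, i : i + h, j : j + wd] += dcols[:, i, j]
    dx = dxp[:, pad : pad + h, pad : pad + wd] if pad else dxp
    return dx, dw, db


def _maxpool2(x: np.ndarray):
    c, h, w = x.shape
    xr = x.reshape(c, h // 2, 2, w // 2, 2)
    out = xr.max(axis=(2, 4))
    mask = xr == out[:, :, None, :, None]
    return out, mask


def _maxpool2_backward(dout: np.ndarray, mask: np.ndarray):
    c, h2, w2 = dout.shape
    # route gradient to (all tied) max positions
    counts = mask.sum(axis=(2, 4))
    d = (dout / counts)[:, :, None, :, None] * mask
    return d.reshape(c, h2 * 2, w2 * 2)


def _upsample2(x: np.ndarray) -> np.ndarray:
    return np.repeat(np.repeat(x, 2, axis=1), 2, axis=2)


def _upsample2_backward(dout: np.ndarray) -> np.ndarray:
    c, h, w = dout.shape
    return dout.reshape(c, h // 2, 2, w // 2, 2).sum(axis=(2, 4))


def _init_params(rng: np.random.Generator, widths: tuple[int, int], in_ch: int = 1,
                 n_classes: int = 2) -> dict[str, np.ndarray]:
    w1, w2 = widths
    shapes = {
        "enc1a": (w1, in_ch, 3, 3),
        "enc1b": (w1, w1, 3, 3),
        "enc2a": (w2, w1, 3, 3),
        "enc2b": (w2, w2, 3, 3),
        "dec1a": (w1, w1 + w2, 3, 3),
        "head": (n_classes, w1, 1, 1),
    }
    params = {}
    for name, shp in shapes.items():
        fan_in = shp[1] * shp[2] * shp[3]
        params[f"{name}_w"] = rng.normal(0, math.sqrt(2.0 / fan_in), shp)
        params[f"{name}_b"] = np.zeros(shp[0])
    return params


def _forward(params: dict, x: np.ndarray, want_cache: bool = False):
    """x: (1, H, W) normalized input, H and W even. Returns logits (2, H, W)."""
    cache: dict = {"x": x}

    def conv_relu(name, inp):
        z, cols = _conv_forward(inp, params[f"{name}_w"], params[f"{name}_b"])
        a = np.maximum(z, 0)
        if want_cache:
            cache[name] = (cols, z, inp.shape)
        return a

    e1 = conv_relu("enc1b", conv_relu("enc1a", x))
    p1, pool_mask = _maxpool2(e1)
    e2 = conv_relu("enc2b", conv_relu("enc2a", p1))
    up = _upsample2(e2)
    cat = np.concatenate([e1, up], axis=0)
    d1 = conv_relu("dec1a", cat)
    logits, head_cols = _conv_forward(d1, params["head_w"], params["head_b"])
    if want_cache:
        cache.update(pool_mask=pool_mask, e1_ch=e1.shape[0],
                     head=(head_cols, logits, d1.shape))
    return logits, cache


def _backward_full(params: dict, cache: dict, dlogits: np.ndarray) -> dict:
    grads = {}

    def conv_relu_back(name, dout):
        cols, z, in_shape = cache[name]
        dz = dout * (z > 0)
        dx, dw, db = _conv_backward(dz, cols, params[f"{name}_w"], in_shape)
        grads[f"{name}_w"], grads[f"{name}_b"] = dw, db
        return dx

    head_cols, _, d1_shape = cache["head"]
    dd1, grads["head_w"], grads["head_b"] = _conv_backward(
        dlogits, head_cols, params["head_w"], d1_shape
    )
    dcat = conv_relu_back("dec1a", dd1)
    n1 = cache["e1_ch"]
    de1 = dcat[:n1].copy()
    de2 = _upsample2_backward(dcat[n1:])
    dp1 = conv_relu_back("enc2a", conv_relu_back("enc2b", de2))
    de1 += _maxpool2_backward(dp1, cache["pool_mask"])
    conv_relu_back("enc1a", conv_relu_back("enc1b", de1))
    return grads


def train_unet_lite(
    tiles: list[tuple[np.ndarray, np.ndarray, np.ndarray | None]],
    config: TrainingConfig | None = None,
) -> SegModelState:
    """Train the small encoder-decoder on labeled tiles.

    ``tiles`` holds (image, label, weight) triples; labels are binary
    (or 2-class) maps and weights optional per-pixel maps (uniform when
    None). Each iteration samples a batch of tiles, accumulates the
    gradient of the weighted soft-max cross-entropy and takes an Adam
    step. Seeded and reproducible on fixed hardware; the loss trace is
    stored on the returned state for monitoring.
    """
    config = config or TrainingConfig()
    if len(tiles) == 0:
        raise InvalidParameterError("need at least one labeled tile")
    prepared = []
    for img, lab, wgt in tiles:
        img = np.asarray(img, dtype=float)
        lab = np.asarray(lab).astype(int)
        if img.shape != lab.shape:
            raise ShapeMismatchError("tile image and label shapes differ")
        if img.shape[0] % 2 or img.shape[1] % 2:
            raise ShapeMismatchError("tile sides must be even")
        if not np.all(np.isin(np.unique(lab), (0, 1))):
            raise InvalidParameterError("labels must be binary (2-class)")
        wgt = np.ones(lab.shape) if wgt is None else np.asarray(wgt, dtype=float)
        if wgt.shape != lab.shape:
            raise ShapeMismatchError("tile weight shape differs")
        prepared.append((img, lab, wgt))

    mean = float(np.mean([t[0].mean() for t in prepared]))
    sd = float(np.mean([t[0].std() for t in prepared])) or 1.0
    rng = np.random.default_rng(config.seed)
    params = _init_params(rng, config.widths)
    m = {k: np.zeros_like(v) for k, v in params.items()}
    v = {k: np.zeros_like(v) for k, v in params.items()}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    trace = np.empty(config.iterations)

    for it in range(config.iterations):
        idx = rng.integers(0, len(prepared), size=min(config.batch_size, len(prepared)))
        grads_sum = {k: np.zeros_like(p) for k, p in params.items()}
        loss_sum = 0.0
        for i in idx:
            img, lab, wgt = prepared[i]
            x = ((img - mean) / sd)[None]
            logits, cache = _forward(params, x, want_cache=True)
            scores = logits.transpose(1, 2, 0)
            loss = weighted_softmax_xent(scores, lab, wgt)
            if not math.isfinite(loss):
                raise InvalidParameterError(f"non-finite loss at iteration {it}")
            loss_sum += loss
            shifted = scores - scores.max(axis=-1, keepdims=True)
            expd = np.exp(shifted)
            prob = expd / expd.sum(axis=-1, keepdims=True)
            onehot = np.eye(2)[lab]
            dscores = (wgt[..., None] * (prob - onehot)) / wgt.sum()
            g = _backward_full(params, cache, dscores.transpose(2, 0, 1))
            for k in grads_sum:
                grads_sum[k] += g[k]
        nb = len(idx)
        trace[it] = loss_sum / nb
        t = it + 1
        for k in params:
            gk = grads_sum[k] / nb
            m[k] = beta1 * m[k] + (1 - beta1) * gk
            v[k] = beta2 * v[k] + (1 - beta2) * gk**2
            mhat = m[k] / (1 - beta1**t)
            vhat = v[k] / (1 - beta2**t)
            params[k] -= config.learning_rate * mhat / (np.sqrt(vhat) + eps)

    logger.info("trained %d iterations, loss %.4f -> %.4f",
                config.iterations, trace[0], trace[-1])
    return SegModelState(
        arch={"levels": 2, "widths": list(config.widths), "in_channels": 1, "n_classes": 2},
        params=params,
        norm=(mean, sd),
        loss_trace=trace,
    )


def seg_infer(
    model: SegModelState,
    image: np.ndarray,
    mode: str = "mask",
    calibration: PixelCalibration | None = None,
    min_separation_um: float = DEFAULT_MIN_SEPARATION_UM,
    threshold_rel: float = 0.1,
) -> BinaryMask | NucleusSet:
    """Run the trained backend on an image.

    ``mode="mask"`` returns the argmax class map; ``mode="points"``
    extracts local maxima of the foreground probability with the same
    greedy suppression as the baseline detector. Deterministic given the
    model.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2 or img.size == 0:
        raise ShapeMismatchError("expected a nonempty 2D image")
    mean, sd = model.norm
    h, w = img.shape
    ph, pw = h + h % 2, w + w % 2
    padded = np.pad(img, ((0, ph - h), (0, pw - w)), mode="reflect")
    logits, _ = _forward(model.params, ((padded - mean) / sd)[None])
    logits = logits[:, :h, :w]
    if mode == "mask":
        cal = calibration or PixelCalibration(1.0)
        return BinaryMask(np.argmax(logits, axis=0) == 1, cal)
    if mode == "points":
        cal = calibration or PixelCalibration(1.0)
        shifted = logits - logits.max(axis=0, keepdims=True)
        expd = np.exp(shifted)
        prob_fg = expd[1] / expd.sum(axis=0)
        centers, scores = _greedy_local_maxima(
            prob_fg, cal.to_px(min_separation_um), threshold_rel
        )
        return NucleusSet(centers=centers, scores=scores)
    raise InvalidParameterError(f"unknown inference mode {mode!r}")
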