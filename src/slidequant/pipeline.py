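"""Pipeline driver: simulate/ingest -> prescan -> plan -> correct ->
stitch -> segment -> quantify -> evaluate, with a reproducible manifest.

Configuration is a flat YAML document; a run writes every stage's
artifacts under one output directory plus a ``manifest.json`` (config
snapshot, package version, seed, per-stage outputs and timings) written
atomically at the end. Identical config + seed reproduces identical
outputs with the deterministic (baseline) segmentation backend.
"""

from __future__ import annotations

import dataclasses
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage

from . import __version__
from . import acquisition as acq
from . import evaluation as ev
from . import io as sqio
from . import quantification as quant
from . import segmentation as seg
from . import synthetic_tissue as synth
from .errors import InvalidParameterError, StageError

logger = logging.getLogger(__name__)

PRESCAN_DOWNSAMPLE = 4  # 20x/5x magnification ratio between the two passes


@dataclass
class PipelineConfig:
    """Everything one pipeline run needs; exactly one input source.

    Either ``input_path`` (an OME-TIFF slide) or ``synth`` (parameters
    for the synthetic generator) must be set, never both.
    """

    outdir: str = "slidequant_out"
    seed: int = 0
    input_path: str | None = None
    synth: synth.SynthParams | None = None
    channel_map: dict[str, int] | None = None
    calibration_um_per_px: float | None = None
    # acquisition
    fov_size_px: tuple[int, int] = (256, 256)
    overlap_frac: float = 0.10
    threshold_method: str = "otsu"
    min_area_px: int = 500
    survey_smooth_px: float = 6.0  # low-res px; ~crypt scale so tissue blobs merge
    # segmentation (baseline backend)
    backend: str = "baseline"
    expected_nucleus_radius_um: float = seg.DEFAULT_NUCLEUS_RADIUS_UM
    min_separation_um: float = seg.DEFAULT_MIN_SEPARATION_UM
    detect_threshold_rel: float = 0.1
    smooth_sigma_um: float = 1.5
    # quantification / evaluation
    quant: quant.QuantConfig = field(default_factory=quant.QuantConfig)
    evaluate: bool = True
    tile_size_um: float = ev.DEFAULT_TILE_SIZE_UM
    tissue_label: str = "synthetic"
    time_h: float | None = None
    log_level: str = "INFO"

    def __post_init__(self):
        if (self.input_path is None) == (self.synth is None):
            raise InvalidParameterError(
                "exactly one of input_path or synth must be set"
            )
        if self.backend not in ("baseline",):
            raise InvalidParameterError(f"unknown backend {self.backend!r}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(doc)

    @classmethod
    def from_dict(cls, doc: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise InvalidParameterError(f"unknown config keys: {sorted(unknown)}")
        doc = dict(doc)
        if "synth" in doc and isinstance(doc["synth"], dict) and doc["synth"]:
            sp = dict(doc["synth"])
            if "calibration" in sp and not isinstance(sp["calibration"],
                                                      synth.PixelCalibration):
                sp["calibration"] = synth.PixelCalibration(float(sp["calibration"]))
            if "pk" in sp and isinstance(sp["pk"], dict):
                sp["pk"] = synth.PKParams(**sp["pk"])
            for key in ("slide_size_px", "crypt_radius_um", "nucleus_radius_um",
                        "noise", "fov_size_px"):
                if key in sp:
                    sp[key] = tuple(sp[key])
            doc["synth"] = synth.SynthParams(**sp)
        elif doc.get("synth") is not None and not isinstance(doc["synth"],
                                                             synth.SynthParams):
            raise InvalidParameterError("synth must be a mapping of SynthParams fields")
        if "quant" in doc and isinstance(doc["quant"], dict):
            q = dict(doc["quant"])
            if "background" in q and isinstance(q["background"], dict):
                q["background"] = quant.BackgroundModel(**q["background"])
            doc["quant"] = quant.QuantConfig(**q)
        for key in ("fov_size_px",):
            if key in doc:
                doc[key] = tuple(doc[key])
        return cls(**doc)

    def snapshot(self) -> dict:
        def enc(value):
            if dataclasses.is_dataclass(value) and not isinstance(value, type):
                return {k: enc(v) for k, v in dataclasses.asdict(value).items()}
            if isinstance(value, tuple):
                return list(value)
            if isinstance(value, np.ndarray):
                return value.tolist()
            return value

        return {f.name: enc(getattr(self, f.name)) for f in dataclasses.fields(self)}


@dataclass
class RunManifest:
    config: dict
    version: str
    seed: int
    outputs: dict[str, list[str]]
    timings_s: dict[str, float]
    results: dict

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute all stages and write artifacts + manifest under ``outdir``."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, list[str]] = {}
    timings: dict[str, float] = {}
    results: dict = {}

    def stage(name):
        class _Timer:
            def __enter__(self):
                self.t0 = time.perf_counter()
                logger.info("stage %s started", name)
                return self

            def __exit__(self, exc_type, exc, tb):
                timings[name] = round(time.perf_counter() - self.t0, 4)
                if exc is not None and not isinstance(exc, StageError):
                    raise StageError(name, str(exc)) from exc
                return False

        return _Timer()

    truth = None
    with stage("ingest"):
        if config.synth is not None:
            params = dataclasses.replace(config.synth, seed=config.seed)
            slide, truth = synth.generate_slide(params)
            time_h = config.time_h if config.time_h is not None else params.time_h
            slide_path = sqio.save_slide(slide, outdir / "slide.ome.tif")
            gt_paths = sqio.save_ground_truth(truth, outdir)
            outputs["ingest"] = [str(slide_path)] + [str(p) for p in gt_paths.values()]
        else:
            if not Path(config.input_path).exists():
                raise FileNotFoundError(f"input path {config.input_path} does not exist")
            slide = sqio.load_slide(config.input_path, config.channel_map,
                                    config.calibration_um_per_px)
            time_h = config.time_h
            outputs["ingest"] = [str(config.input_path)]
    cal = slide.calibration

    with stage("prescan"):
        lowres = synth.lowres_prescan_image(slide, PRESCAN_DOWNSAMPLE)
        # coarse survey: merge individual nuclei into tissue-scale blobs
        lowres = ndimage.gaussian_filter(lowres, config.survey_smooth_px, mode="reflect")
        boxes = acq.prescan_roi(lowres, config.threshold_method,
                                config.min_area_px, downsample=PRESCAN_DOWNSAMPLE)
        if not boxes:
            raise InvalidParameterError("no tissue found in the pre-scan")
        roi = acq.merge_roi_boxes(boxes)
        # ROI may not exceed the slide
        h, w = slide.shape
        roi = acq.ROIBox(roi.top, roi.left,
                         min(roi.height, h - roi.top), min(roi.width, w - roi.left))
        results["roi"] = dataclasses.asdict(roi)
        results["n_roi_boxes"] = len(boxes)

    with stage("plan"):
        fov = (min(config.fov_size_px[0], roi.height),
               min(config.fov_size_px[1], roi.width))
        plan = acq.plan_fovs(roi, fov, config.overlap_frac)
        plan_path = sqio.save_fov_plan(plan, outdir / "fov_plan.csv")
        outputs["plan"] = [str(plan_path)]
        results["n_tiles"] = plan.n_tiles

    montage = {}
    with stage("correct_stitch"):
        for role in ("nuclear", "epithelial", "drug"):
            tiles = acq.crop_fovs(slide.channels[role][roi.slices()], plan)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                corrected, _ = acq.flatfield_correct(tiles)
            montage[role] = np.maximum(acq.stitch(corrected, plan), 0.0)
        mslide = synth.SlideImage(channels=montage, calibration=cal)
        mpath = sqio.save_slide(mslide, outdir / "montage.ome.tif")
        outputs["correct_stitch"] = [str(mpath)]

    with stage("segment"):
        nuclei = seg.detect_nuclei_baseline(
            montage["nuclear"], cal,
            config.expected_nucleus_radius_um, config.min_separation_um,
            config.detect_threshold_rel,
        )
        epi = seg.segment_epithelium_baseline(
            montage["epithelial"], cal, config.smooth_sigma_um,
            config.threshold_method,
        )
        npath = sqio.save_points_csv(nuclei, outdir / "nuclei.csv")
        epath = sqio.save_mask(epi, outdir / "epithelium_mask.tif")
        outputs["segment"] = [str(npath), str(epath)]
        results["n_nuclei"] = len(nuclei)
        results["epithelium_area_um2"] = epi.area_um2

    with stage("quantify"):
        context = _background_context(slide.channels["drug"], roi)
        qres = quant.quantify(
            montage["drug"], nuclei, epi, cal, config.quant,
            background_context=context,
            time_h=time_h, tissue_label=config.tissue_label,
        )
        tpaths = _write_quant(qres, outdir)
        outputs["quantify"] = [str(p) for p in tpaths]
        results["specific_total"] = qres.specific_total
        results["nonspecific_total"] = qres.nonspecific_total
        results["occupancy"] = qres.occupancy

    if config.evaluate and truth is not None:
        with stage("evaluate"):
            epi_iou = ev.iou(epi.mask, truth.epithelium_mask[roi.slices()])
            planted = truth.nucleus_centers - [roi.top, roi.left]
            inside = ((planted >= 0).all(axis=1)
                      & (planted[:, 0] < roi.height) & (planted[:, 1] < roi.width))
            planted_set = seg.NucleusSet(centers=planted[inside])
            local_roi = acq.ROIBox(0, 0, roi.height, roi.width)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                report = ev.evaluate_nucleus_counts(
                    planted_set, nuclei, local_roi, cal,
                    ev.EvalConfig(tile_size_um=config.tile_size_um),
                )
            report.iou = epi_iou
            rpath = sqio.write_json_atomic(report.to_dict(), outdir / "eval_report.json")
            outputs["evaluate"] = [str(rpath)]
            results["iou"] = epi_iou
            results["r_squared"] = report.r_squared

    manifest = RunManifest(
        config=config.snapshot(),
        version=__version__,
        seed=config.seed,
        outputs=outputs,
        timings_s=timings,
        results=results,
    )
    sqio.write_json_atomic(manifest.to_dict(), outdir / "manifest.json")
    return manifest


def _background_context(drug: np.ndarray, roi) -> np.ndarray:
    """Drug-channel pixels on tissue-free glass outside the ROI; falls back
    to the dimmest decile of the whole channel when the ROI fills the slide."""
    mask = np.ones(drug.shape, dtype=bool)
    mask[roi.slices()] = False
    outside = drug[mask]
    if outside.size >= 1000:
        return outside
    warnings.warn("ROI covers the slide: using dimmest decile as background",
                  stacklevel=2)
    flat = np.sort(drug.ravel())
    return flat[: max(len(flat) // 10, 1)]


def _write_quant(qres: quant.QuantResult, outdir: Path) -> list[Path]:
    region_path = outdir / "region_table.csv"
    qres.region_table.to_csv(region_path, index=False, float_format="%.8g")
    edges, counts = qres.histogram
    hist_path = outdir / "density_histogram.csv"
    pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
    ).to_csv(hist_path, index=False, float_format="%.8g")
    summary_path = outdir / "summary.csv"
    pd.DataFrame(
        [
            {
                "tissue_label": qres.meta.get("tissue_label", ""),
                "time_h": qres.meta.get("time_h"),
                "occupancy": qres.occupancy,
                "specific_total": qres.specific_total,
                "nonspecific_total": qres.nonspecific_total,
            }
        ]
    ).to_csv(summary_path, index=False, float_format="%.10g")
    return [region_path, hist_path, summary_path]
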