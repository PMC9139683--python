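"""End-to-end three-step orchestration: ROI crop, segmentation, key measures.

Step 1 detects the optic disc and derives a square crop window; Step 2
segments disc and cup inside the crop and remaps the masks to full-frame
coordinates; Step 3 computes the screening measures and, when ground truth
is available, their errors. Each stage has an oracle mode (ground truth
substituted for the stage's output) so the later stages can be exercised
and tested in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import measures as M
from .mapnet import MapNetSegmenter
from .preprocess import map_back, resize_pair
from .roi import (
    DEFAULT_ROI_FACTOR,
    CropWindow,
    IntensityDetector,
    OracleDetector,
    crop_window,
    detect_candidates,
    extract_crop,
    select_roi,
)
from .synthetic import LabeledFundus

__all__ = ["PipelineConfig", "ImageResult", "run_pipeline", "load_segmenter",
           "save_segmenter"]


@dataclass
class PipelineConfig:
    """Configuration for one pipeline run."""

    roi_factor: float = DEFAULT_ROI_FACTOR
    detector: str = "oracle"            # oracle | intensity | external
    external_detector: object = None    # callable image -> [RoiCandidate]
    oracle_segmentation: bool = False   # use GT masks as the segmentation
    disc_model: object = None           # MapNetSegmenter or checkpoint path
    cup_model: object = None
    seed: int = 0

    def __post_init__(self):
        if self.roi_factor <= 0:
            raise ValueError("roi_factor must be positive")
        if self.detector not in ("oracle", "intensity", "external"):
            raise ValueError(f"unknown detector {self.detector!r}")
        if self.detector == "external" and self.external_detector is None:
            raise ValueError("external detector selected but none supplied")


@dataclass
class ImageResult:
    """Per-image pipeline output."""

    index: int
    failed: bool = False
    failure_reason: str = ""
    window: CropWindow | None = None
    disc_mask: np.ndarray | None = None
    cup_mask: np.ndarray | None = None
    measures: M.KeyMeasures | None = None
    errors: M.MeasureErrors | None = None
    radius_errors: dict = field(default_factory=dict)  # adrre/acrre/arrre
    seg_overlap: dict = field(default_factory=dict)    # JI/DC per structure


def save_segmenter(est: MapNetSegmenter, path) -> None:
    """Save a fitted segmenter as .npz weights plus a JSON config sidecar."""
    path = Path(path)
    state = est.model_.get_state()
    np.savez_compressed(path, *state)
    path.with_suffix(".json").write_text(est.config_.to_json())


def load_segmenter(path) -> MapNetSegmenter:
    """Load a segmenter saved by :func:`save_segmenter`."""
    from .mapnet import MapNet, MapNetConfig, TrainingRun

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(
            f"model checkpoint not found: {path} — train one with "
            f"MapNetSegmenter.fit or the `fundusseg train` command")
    cfg = MapNetConfig.from_json(path.with_suffix(".json").read_text())
    with np.load(path) as data:
        state = [data[k] for k in data.files]
    est = MapNetSegmenter(config=cfg, seed=cfg.seed)
    est.config_ = cfg
    est.model_ = MapNet(cfg)
    est.model_.set_state(state)
    est.training_run_ = TrainingRun(seed=cfg.seed, config=cfg)
    return est


def _resolve_model(model) -> MapNetSegmenter:
    if isinstance(model, (str, Path)):
        return load_segmenter(model)
    return model


def _profile_errors(gt_disc, gt_cup, est_disc, est_cup) -> dict:
    """Average disc/cup/rim radius ratio errors, sharing the GT disc centroid."""
    center = M.centroid(gt_disc)
    out = {}
    gt_d = M.radius_profile(gt_disc, center)
    est_d = M.radius_profile(est_disc, center)
    out["adrre"] = M.average_radius_ratio_errors(M.radius_ratio_errors(gt_d, est_d)[0])
    if gt_cup is not None and np.any(gt_cup) and np.any(est_cup):
        gt_c = M.radius_profile(gt_cup, center)
        est_c = M.radius_profile(est_cup, center)
        out["acrre"] = M.average_radius_ratio_errors(M.radius_ratio_errors(gt_c, est_c)[0])
        gt_rim = M.rim_profile(gt_d, gt_c)
        est_rim = M.rim_profile(est_d, est_c)
        try:
            out["arrre"] = M.average_radius_ratio_errors(
                M.radius_ratio_errors(gt_rim, est_rim)[0])
        except ValueError:  # rim entirely zero (cup == disc)
            pass
    return out


def run_pipeline(images: list[LabeledFundus], config: PipelineConfig,
                 ) -> list[ImageResult]:
    """Run the three-step pipeline over a collection of images.

    Images for which the detector finds no candidate are recorded as failed
    and the run continues. With ``oracle_segmentation`` the ground-truth
    masks stand in for Step 2, exercising Step 3 alone (all errors 0).
    """
    disc_model = cup_model = None
    if not config.oracle_segmentation:
        disc_model = _resolve_model(config.disc_model)
        cup_model = _resolve_model(config.cup_model)
        if disc_model is None:
            raise ValueError("no disc model supplied and oracle_segmentation is off")

    results = []
    for i, sample in enumerate(images):
        res = ImageResult(index=i)
        results.append(res)

        if config.detector == "oracle":
            if sample.disc_mask is None:
                res.failed, res.failure_reason = True, "no ground truth for oracle detector"
                continue
            detector = OracleDetector(sample.disc_mask)
        elif config.detector == "intensity":
            detector = IntensityDetector()
        else:
            detector = config.external_detector

        cands = detect_candidates(sample.image, detector)
        if not cands:
            res.failed, res.failure_reason = True, "detector returned no ROI"
            continue
        roi = select_roi(cands)
        window = crop_window(roi, config.roi_factor, sample.image.shape[:2])
        res.window = window

        full_shape = sample.image.shape[:2]
        if config.oracle_segmentation:
            res.disc_mask = np.asarray(sample.disc_mask) > 0
            res.cup_mask = None if sample.cup_mask is None else np.asarray(sample.cup_mask) > 0
        else:
            crop = extract_crop(sample.image, window)
            side = disc_model.config_.input_side
            crop_r, _ = resize_pair(crop, np.zeros(crop.shape[:2], np.uint8), side)
            res.disc_mask = map_back(disc_model.predict(crop_r[None])[0], window,
                                     full_shape) > 0
            if cup_model is not None:
                res.cup_mask = map_back(cup_model.predict(crop_r[None])[0], window,
                                        full_shape) > 0

        if res.disc_mask is None or not res.disc_mask.any():
            res.failed, res.failure_reason = True, "empty disc segmentation"
            continue
        res.measures = M.key_measures(res.disc_mask, res.cup_mask)

        if sample.disc_mask is not None:
            gt_meas = M.key_measures(sample.disc_mask, sample.cup_mask)
            res.errors = M.measure_errors(gt_meas, res.measures, index=i)
            res.radius_errors = _profile_errors(
                sample.disc_mask, sample.cup_mask, res.disc_mask, res.cup_mask)
            from .evaluation import confusion_counts, seg_metrics

            res.seg_overlap["disc"] = seg_metrics(
                confusion_counts(sample.disc_mask, res.disc_mask))
            if sample.cup_mask is not None and res.cup_mask is not None:
                res.seg_overlap["cup"] = seg_metrics(
                    confusion_counts(sample.cup_mask, res.cup_mask))
    return results
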