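"""Pipeline orchestration, configuration, logging, and image/result I/O.

Runs the three stages in order — Doppler initial axis, Gabor/B-mode axis
refinement, two-step tip localization — on a co-registered power Doppler /
B-mode image pair, and provides PNG/TIFF reading (with normalization to
[0, 1] by bit-depth maximum) plus lossless JSON round-tripping of results.
All computation downstream of the phantom generator is deterministic.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import bmode_axis, doppler_axis, tip_localization
from .core import ImageGrid, LineEstimate
from .doppler_axis import DbscanParams
from .evaluation import LocalizationResult

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline",
           "read_image_pair", "read_image", "write_result", "read_result"]

logger = logging.getLogger("needleloc")


class PipelineError(RuntimeError):
    """A stage-level failure, carrying the stage name as provenance."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass(frozen=True)
class PipelineConfig:
    """Physical and algorithmic parameters of one localization run.

    Defaults correspond to the reference operating point: 18G needle
    (1.27 mm) at 0.25 mm/px, density clustering at (R=6 px, M=100 px),
    1-degree Radon angular sampling, tip search within 2 diameters, and a
    3 mm axis-error failure threshold.
    """

    pixel_spacing: float = 0.25       # mm per pixel
    needle_diameter: float = 1.27     # mm
    dbscan: DbscanParams = field(default_factory=DbscanParams)
    radon_angle_step: float = 1.0     # degrees
    tip_search_multiplier: float = 2.0
    failure_threshold: float = 3.0    # mm
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if min(self.pixel_spacing, self.needle_diameter,
               self.radon_angle_step, self.tip_search_multiplier,
               self.failure_threshold) <= 0:
            raise ValueError("all physical quantities must be positive")

    @property
    def needle_diameter_px(self) -> float:
        return self.needle_diameter / self.pixel_spacing

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "dbscan" in d and isinstance(d["dbscan"], dict):
            d["dbscan"] = DbscanParams(**d["dbscan"])
        return cls(**d)


def run_pipeline(doppler: ImageGrid, bmode: ImageGrid,
                 config: PipelineConfig = PipelineConfig()) -> LocalizationResult:
    """Localize the needle axis and tip in one image pair.

    A trial with no usable Doppler evidence returns a flagged failure
    result (axis along the top image row, entry/tip at the origin) rather
    than raising; genuine I/O or configuration problems do raise.
    """
    logging.basicConfig()
    logger.setLevel(config.log_level)
    if doppler.shape != bmode.shape:
        raise PipelineError("input", "images not co-registered: shapes differ")

    # ---- stage 1: Doppler initial axis + ROIs ----
    threshold, degenerate = doppler_axis.intermeans_threshold(doppler)
    logger.info("intermeans threshold: %.6g (degenerate=%s)", threshold, degenerate)
    if degenerate and threshold == 0.0:
        return _failure_result("no Doppler evidence")
    pre = doppler_axis.preprocess_doppler(doppler, threshold)
    clusters = doppler_axis.cluster_doppler(pre, config.dbscan)
    logger.info("clusters: %d", len(clusters))
    if not clusters:
        return _failure_result("no Doppler evidence")
    axis0 = doppler_axis.initial_axis(clusters, doppler.shape, doppler=pre,
                                      angle_step=config.radon_angle_step)
    logger.info("initial axis: angle %.2f deg", axis0.angle_deg)
    ellipses = [doppler_axis.fit_ellipse(c) for c in clusters]
    rois = doppler_axis.filter_rois(ellipses, axis0)
    logger.info("ROIs kept: %d of %d", len(rois), len(ellipses))
    if not rois:
        return _failure_result("no Doppler evidence")

    # ---- stage 2: Gabor-enhanced B-mode axis refinement ----
    gp = bmode_axis.GaborParams.for_needle(axis0.angle_deg,
                                           config.needle_diameter,
                                           config.pixel_spacing)
    filtered = bmode_axis.masked_gabor_filter(bmode, rois, gp)
    try:
        axis1 = bmode_axis.refine_axis(filtered, axis0.angle_deg)
    except ValueError:
        logger.warning("B-mode refinement impossible; keeping initial axis")
        axis1 = axis0
    logger.info("refined axis rho: %.2f px", axis1.theta_rho(bmode.shape)[1])

    # ---- stage 3: tip localization ----
    d_px = config.needle_diameter_px
    profile = tip_localization.compute_axis_profiles(doppler, bmode, axis1, d_px)
    tip0, low_conf_pd = tip_localization.doppler_tip_estimate(profile)
    tip = tip_localization.bmode_tip_refine(profile, tip0, d_px,
                                            config.tip_search_multiplier)
    logger.info("tip indices: doppler %d, refined %d", tip0, tip.refined_tip_index)

    flags = []
    if low_conf_pd or tip.low_confidence:
        flags.append("low_confidence_tip")
    return LocalizationResult(axis=profile.axis, entry=profile.entry,
                              tip=tip.tip_pixel, flags=tuple(flags))


def _failure_result(reason: str) -> LocalizationResult:
    logger.warning("localization failure: %s", reason)
    axis = LineEstimate(point=(0.0, 0.0), direction=(0.0, 1.0))
    return LocalizationResult(axis=axis, entry=(0.0, 0.0), tip=(0.0, 0.0),
                              flags=("failed", reason))


# ---------------------------------------------------------------- I/O ----

def read_image(path: str | Path, pixel_spacing: float) -> ImageGrid:
    """Read an 8/16-bit grayscale PNG/TIFF, normalized to [0, 1]."""
    import imageio.v3 as iio

    arr = np.asarray(iio.imread(Path(path)))
    if arr.ndim == 3:
        if arr.shape[2] == 1:
            arr = arr[:, :, 0]
        else:
            raise ValueError(f"{path}: expected grayscale, got {arr.shape[2]} channels")
    if arr.dtype == np.uint8:
        scale = 255.0
    elif arr.dtype == np.uint16:
        scale = 65535.0
    else:
        raise ValueError(f"{path}: unsupported dtype {arr.dtype}; expected 8/16-bit")
    return ImageGrid(arr.astype(float) / scale, pixel_spacing)


def read_image_pair(doppler_path: str | Path, bmode_path: str | Path,
                    pixel_spacing: float) -> tuple[ImageGrid, ImageGrid]:
    doppler = read_image(doppler_path, pixel_spacing)
    bmode = read_image(bmode_path, pixel_spacing)
    if doppler.shape != bmode.shape:
        raise ValueError("images not co-registered: shapes differ")
    return doppler, bmode


def result_to_dict(result: LocalizationResult) -> dict:
    return {
        "axis": {"point": list(result.axis.point),
                 "direction": list(result.axis.direction)},
        "entry": list(result.entry),
        "tip": list(result.tip),
        "flags": list(result.flags),
    }


def result_from_dict(d: dict) -> LocalizationResult:
    axis = LineEstimate(point=tuple(d["axis"]["point"]),
                        direction=tuple(d["axis"]["direction"]))
    return LocalizationResult(axis=axis, entry=tuple(d["entry"]),
                              tip=tuple(d["tip"]), flags=tuple(d["flags"]))


def write_result(result: LocalizationResult, path: str | Path) -> None:
    Path(path).write_text(json.dumps(result_to_dict(result), indent=2,
                                     sort_keys=True))


def read_result(path: str | Path) -> LocalizationResult:
    return result_from_dict(json.loads(Path(path).read_text()))
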