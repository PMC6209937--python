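"""Localization error metrics and batch scoring.

Metrics follow the standard needle-localization conventions:

* *axis error* — the ground-truth entry and tip points are orthogonally
  projected onto the estimated axis; the axis error is the larger of the
  two point-to-projection distances, in mm.
* *angle error* — undirected difference between estimated and true line
  angles (lines are 180-degree periodic), in degrees.
* *tip error* — Euclidean distance between estimated and true tip, mm.
* *failure* — a trial whose axis error is not smaller than 3 mm.

Batch scoring reports the failure rate over all trials and mean +- sd of
each error over the successful trials only, per insertion-angle bin:
shallow [0, 20], moderate (20, 40], steep (40, 65] degrees, and the full
range.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import LineEstimate
from .phantom import NeedleTruth

__all__ = ["LocalizationResult", "ErrorReport", "axis_error", "angle_error",
           "tip_error", "score_trial", "batch_score", "FAILURE_THRESHOLD_MM",
           "ANGLE_BINS"]

FAILURE_THRESHOLD_MM = 3.0

#: (name, lower, upper); lower edge open except for the first bin
ANGLE_BINS: tuple[tuple[str, float, float], ...] = (
    ("shallow", 0.0, 20.0),
    ("moderate", 20.0, 40.0),
    ("steep", 40.0, 65.0),
    ("all", 0.0, 65.0),
)


@dataclass(frozen=True)
class LocalizationResult:
    """Estimated needle for one trial."""

    axis: LineEstimate
    entry: tuple[float, float]
    tip: tuple[float, float]
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.axis.distance_to(self.tip) > 0.5:
            raise ValueError("tip must lie on the axis (within 0.5 px)")

    @property
    def failed(self) -> bool:
        return "failed" in self.flags


@dataclass(frozen=True)
class ErrorReport:
    """Scored errors of one trial."""

    angle_error: float  # degrees
    axis_error: float   # mm
    tip_error: float    # mm
    failed: bool

    def __post_init__(self) -> None:
        if min(self.angle_error, self.axis_error, self.tip_error) < 0:
            raise ValueError("errors must be non-negative")
        if self.failed != (self.axis_error >= FAILURE_THRESHOLD_MM):
            raise ValueError("failed flag inconsistent with the 3 mm rule")


def axis_error(truth: NeedleTruth, axis: LineEstimate, pixel_spacing: float) -> float:
    """max of the truth entry/tip distances to the estimated axis, in mm."""
    d_entry = axis.distance_to(truth.entry)
    d_tip = axis.distance_to(truth.tip)
    return max(d_entry, d_tip) * pixel_spacing


def angle_error(truth: NeedleTruth, axis: LineEstimate) -> float:
    """Undirected line-angle difference in degrees, in [0, 90]."""
    delta = abs(axis.angle_deg - truth.angle) % 180.0
    return min(delta, 180.0 - delta)


def tip_error(truth: NeedleTruth, result: LocalizationResult, pixel_spacing: float) -> float:
    """Euclidean tip-to-tip distance in mm."""
    return math.hypot(result.tip[0] - truth.tip[0],
                      result.tip[1] - truth.tip[1]) * pixel_spacing


def score_trial(truth: NeedleTruth, result: LocalizationResult,
                pixel_spacing: float) -> ErrorReport:
    ax = axis_error(truth, result.axis, pixel_spacing)
    return ErrorReport(angle_error=angle_error(truth, result.axis),
                       axis_error=ax,
                       tip_error=tip_error(truth, result, pixel_spacing),
                       failed=ax >= FAILURE_THRESHOLD_MM)


def batch_score(reports: list[ErrorReport], truths: list[NeedleTruth],
                angle_bins=ANGLE_BINS) -> pd.DataFrame:
    """Per-bin failure rates and success-only error statistics.

    Bins with no trials are omitted from the table (absent, not zero).
    Standard deviations use the population convention (ddof=0) and are NaN
    for single-trial bins.
    """
    if len(reports) != len(truths):
        raise ValueError("reports and truths must be matched lists")
    rows = []
    angles = np.array([t.angle for t in truths])
    for name, lo, hi in angle_bins:
        if name == "all" or lo == 0.0:
            sel = (angles >= lo) & (angles <= hi)
        else:
            sel = (angles > lo) & (angles <= hi)
        n = int(sel.sum())
        if n == 0:
            continue
        binned = [r for r, s in zip(reports, sel) if s]
        n_fail = sum(r.failed for r in binned)
        successes = [r for r in binned if not r.failed]
        row = {"bin": name, "n": n,
               "failure_rate_pct": 100.0 * n_fail / n}
        for metric in ("angle_error", "axis_error", "tip_error"):
            vals = np.array([getattr(r, metric) for r in successes])
            row[f"{metric}_mean"] = float(vals.mean()) if vals.size else np.nan
            row[f"{metric}_sd"] = float(vals.std()) if vals.size else np.nan
        rows.append(row)
    return pd.DataFrame(rows)
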