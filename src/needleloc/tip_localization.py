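"""Stage 3: needle-tip localization along the refined axis.

A rectangular window (length = twice the needle diameter, width = one
diameter, long side along the axis) slides one pixel at a time along the
refined axis, starting at the needle's entry point into the imaged field.
The window-averaged power Doppler and B-mode intensities, IPD(l) and
IBM(l), drive a two-step tip estimate:

1. *Doppler step detection.*  IPD(l) is binarized at its own mean Th
   (B(l) = 1 where IPD >= Th).  The separation score
   ``S(l) = [sum_{i<=l} B(i) + sum_{i>l} (1 - B(i))] / L``
   counts the fraction of samples consistent with "needle before l,
   background after l"; its global argmax (ties toward larger l, the
   deeper candidate) is the approximate tip.
2. *B-mode refinement.*  Within two needle diameters of the approximate
   tip, the strongest drop of the forward difference of IBM(l) marks the
   needle-to-tissue transition; the tip is placed at the last needle-like
   sample before the drop.  If no drop exists there, the Doppler estimate
   stands and the result is flagged low-confidence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates

from .core import ImageGrid, LineEstimate

__all__ = ["AxisProfile", "TipResult", "entry_point", "compute_axis_profiles",
           "windowed_profile", "doppler_tip_estimate", "bmode_tip_refine"]


@dataclass(frozen=True)
class AxisProfile:
    """Window-averaged intensity profiles along a localized axis."""

    axis: LineEstimate
    entry: tuple[float, float]
    ipd: np.ndarray            # mean power Doppler intensity per sample l
    ibm: np.ndarray            # mean B-mode intensity per sample l
    window_length: float       # px, = 2 x needle diameter
    window_width: float        # px, = needle diameter

    def __post_init__(self) -> None:
        if len(self.ipd) != len(self.ibm) or len(self.ipd) < 2:
            raise ValueError("profiles must have equal length L >= 2")
        if abs(self.window_length - 2.0 * self.window_width) > 1e-9:
            raise ValueError("window length must be twice the window width")

    def __len__(self) -> int:
        return len(self.ipd)

    def sample_point(self, l: int) -> tuple[float, float]:
        """(row, col) of profile sample ``l`` (unit steps from the entry)."""
        dr, dc = self._step
        return (self.entry[0] + l * dr, self.entry[1] + l * dc)

    @property
    def _step(self) -> tuple[float, float]:
        dr, dc = self.axis.direction
        return (dr, dc)


@dataclass(frozen=True)
class TipResult:
    """Doppler-approximate and B-mode-refined tip along the axis."""

    doppler_tip_index: int
    refined_tip_index: int
    tip_pixel: tuple[float, float]
    search_radius: float       # px, = 2 x needle diameter
    low_confidence: bool = False

    def __post_init__(self) -> None:
        if abs(self.refined_tip_index - self.doppler_tip_index) > self.search_radius:
            raise ValueError("refined tip outside the allowed search radius")


def entry_point(axis: LineEstimate, shape: tuple[int, int]) -> tuple[float, float]:
    """Where the axis enters the imaged field.

    Returns the intersection of the axis with the image boundary that has
    the smallest row (shallowest point); row ties break toward the
    smallest column.
    """
    pts = axis.clip_to_image(shape)
    if not pts:
        raise ValueError("axis does not intersect the image")
    return min(pts)


def windowed_profile(image: ImageGrid, axis: LineEstimate,
                     entry: tuple[float, float], n_samples: int,
                     window_length: float, window_width: float,
                     subsample: float = 0.5) -> np.ndarray:
    """Mean image intensity over an oriented sliding window.

    The window (length along the axis, width across it) is centered at
    unit-spaced samples l = 0..n_samples-1 along the axis from ``entry``.
    Pixels are sampled bilinearly on a ``subsample``-spaced grid (0.5 px
    gives 4 samples per pixel area); grid points outside the image are
    excluded from the mean.
    """
    dr, dc = axis.direction
    nr, nc_ = -dc, dr  # unit normal
    # midpoint-rule sample offsets in the window frame
    n_len = max(1, int(round(window_length / subsample)))
    n_wid = max(1, int(round(window_width / subsample)))
    off_len = (np.arange(n_len) + 0.5) / n_len * window_length - window_length / 2.0
    off_wid = (np.arange(n_wid) + 0.5) / n_wid * window_width - window_width / 2.0
    ol, ow = np.meshgrid(off_len, off_wid, indexing="ij")
    # offsets in (row, col) for one window
    orow = ol * dr + ow * nr
    ocol = ol * dc + ow * nc_
    ls = np.arange(n_samples)[:, None, None]
    rows = entry[0] + ls * dr + orow[None]
    cols = entry[1] + ls * dc + ocol[None]
    h, w = image.shape
    valid = (rows >= 0) & (rows <= h - 1) & (cols >= 0) & (cols <= w - 1)
    coords = np.stack([rows.ravel(), cols.ravel()])
    vals = map_coordinates(image.intensities, coords, order=1, mode="constant",
                           cval=0.0).reshape(rows.shape)
    vals = np.where(valid, vals, 0.0)
    counts = valid.sum(axis=(1, 2))
    sums = vals.sum(axis=(1, 2))
    with np.errstate(invalid="ignore", divide="ignore"):
        prof = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    return prof


def compute_axis_profiles(doppler: ImageGrid, bmode: ImageGrid,
                          axis: LineEstimate, needle_diameter_px: float) -> AxisProfile:
    """IPD(l) and IBM(l) along the axis from the entry point.

    Both profiles use the same windower (length = 2 diameters, width = 1
    diameter); sampling proceeds in unit steps until the axis leaves the
    image.
    """
    if doppler.shape != bmode.shape:
        raise ValueError("images not co-registered: shapes differ")
    entry = entry_point(axis, doppler.shape)
    pts = axis.clip_to_image(doppler.shape)
    exit_pt = max(pts) if len(pts) > 1 else pts[0]
    span = float(np.hypot(exit_pt[0] - entry[0], exit_pt[1] - entry[1]))
    window_length = 2.0 * needle_diameter_px
    if span < window_length:
        raise ValueError("axis shorter than one window")
    n_samples = int(span) + 1
    # re-orient the axis so samples march from the entry into the image
    direction = np.array([exit_pt[0] - entry[0], exit_pt[1] - entry[1]]) / span
    oriented = LineEstimate(point=entry, direction=tuple(direction))
    ipd = windowed_profile(doppler, oriented, entry, n_samples,
                           window_length, needle_diameter_px)
    ibm = windowed_profile(bmode, oriented, entry, n_samples,
                           window_length, needle_diameter_px)
    return AxisProfile(axis=oriented, entry=entry, ipd=ipd, ibm=ibm,
                       window_length=window_length,
                       window_width=needle_diameter_px)


def separation_score(b: np.ndarray) -> np.ndarray:
    """S(l) for a binary vector: fraction of samples consistent with a
    needle-before-l / background-after-l split."""
    b = np.asarray(b, dtype=float)
    L = len(b)
    before = np.cumsum(b)                    # sum_{i<=l} B(i)
    after = np.cumsum((1.0 - b)[::-1])[::-1]  # sum_{i>=l} (1-B(i))
    after_excl = after - (1.0 - b)           # sum_{i>l} (1-B(i))
    return (before + after_excl) / L


def doppler_tip_estimate(profile: AxisProfile) -> tuple[int, bool]:
    """Approximate tip index from the Doppler profile.

    Returns (index, low_confidence); low confidence is flagged when the
    binarized profile shows no termination (all samples above threshold).
    """
    ipd = profile.ipd
    th = float(ipd.mean())
    b = (ipd >= th).astype(float)
    s = separation_score(b)
    # ties toward the largest l (deepest point)
    idx = int(len(s) - 1 - np.argmax(s[::-1]))
    return idx, bool(b.all())


def bmode_tip_refine(profile: AxisProfile, doppler_tip_index: int,
                     needle_diameter_px: float,
                     search_multiplier: float = 2.0) -> TipResult:
    """Refine the tip with the strongest B-mode intensity drop.

    Searches the signed forward difference D(l) = IBM(l+1) - IBM(l) within
    ``|l - doppler_tip_index| < 2 x diameter`` for its most negative value
    (ties toward larger l); the tip is the sample before the drop.  With no
    negative difference in the window the Doppler estimate is kept and the
    result flagged low-confidence.
    """
    ibm = profile.ibm
    search_radius = search_multiplier * needle_diameter_px
    d = np.diff(ibm)  # d[l] = ibm[l+1] - ibm[l], defined for l = 0..L-2
    ls = np.arange(len(d))
    in_window = np.abs(ls - doppler_tip_index) < search_radius
    low_confidence = False
    if in_window.any() and np.min(d[in_window]) < 0:
        dw = np.where(in_window, d, np.inf)
        best = np.min(dw)
        idx = int(np.max(np.nonzero(dw == best)[0]))  # deepest tie
    else:
        idx = doppler_tip_index
        low_confidence = True
    return TipResult(doppler_tip_index=doppler_tip_index,
                     refined_tip_index=idx,
                     tip_pixel=profile.sample_point(idx),
                     search_radius=search_radius,
                     low_confidence=low_confidence)
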