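"""Synthetic ultrasound phantom: seeded power Doppler + B-mode image pairs.

The generator emulates the imaging situation the localization pipeline is
built for: a biopsy needle, mechanically excited by a buzzer at its base,
imaged simultaneously in B-mode (bright but angle-dependent, partially
visible shaft in speckle) and in power Doppler (irregular high-intensity
vibration responses concentrated along the shaft and densest near the tip,
with spurious off-needle responses).  All randomness flows from a single
integer seed, so an identical config produces bit-identical image pairs.

The phantom uses a rectangular (linear-array-like) pixel grid; the
localization math operates on pixel grids regardless of probe geometry, so
no scan conversion is modeled.  Speckle is Rayleigh-distributed
multiplicative noise, log-compressed into [0, 1].
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .core import ImageGrid, line_angle_deg

__all__ = ["PhantomConfig", "NeedleTruth", "generate_phantom_pair",
           "batch_configs", "write_phantom_pair"]


@dataclass(frozen=True)
class PhantomConfig:
    """Parameters of one synthetic needle-imaging trial.

    Geometry mirrors a 90 mm imaging depth at 0.25 mm/px.  The needle
    enters at the left image edge and descends to the right at
    ``insertion_angle`` degrees from horizontal (0-65, the studied range);
    the tip lies ``insertion_depth`` mm along the shaft and must stay
    inside the image.  ``visibility_falloff`` linearly attenuates the
    B-mode needle brightness per degree of insertion angle, emulating the
    loss of specular reflection at steep beam-needle angles.
    """

    image_height_px: int = 360
    image_width_px: int = 480
    pixel_spacing: float = 0.25          # mm per pixel
    needle_diameter: float = 1.27        # mm (18G)
    insertion_angle: float = 20.0        # degrees from horizontal
    entry_point: tuple[float, float] = (40.0, 0.0)  # (row, col) px, left edge
    insertion_depth: float = 60.0        # mm along the needle
    needle_brightness: float = 0.9       # peak B-mode intensity, [0, 1] scale
    visibility_falloff: float = 0.008    # brightness fraction lost per degree
    speckle_scale: float = 0.35          # Rayleigh scale of the speckle field
    n_distractors: int = 3               # linear reflectors not collinear with needle
    doppler_blob_count: int = 30         # vibration blobs along the needle
    doppler_blob_jitter: float = 2.0     # mm lateral scatter of blob centers
    doppler_blob_offset: float = 1.0     # mm systematic displacement of blobs
                                         # toward the deep side of the shaft
                                         # (Doppler blooming below the needle)
    n_spurious_blobs: int = 4            # off-needle Doppler blobs
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_height_px <= 0 or self.image_width_px <= 0:
            raise ValueError("image dimensions must be positive")
        if not (self.pixel_spacing > 0 and self.needle_diameter > 0):
            raise ValueError("pixel_spacing and needle_diameter must be positive")
        if not (0.0 <= self.insertion_angle <= 65.0):
            raise ValueError("insertion_angle must lie in [0, 65] degrees")
        if self.insertion_depth <= 0:
            raise ValueError("insertion_depth must be positive")
        tip = self._tip_px()
        if not (0 <= tip[0] <= self.image_height_px - 1 and 0 <= tip[1] <= self.image_width_px - 1):
            raise ValueError("needle tip falls outside the image; reduce depth or angle")

    def _direction(self) -> tuple[float, float]:
        a = math.radians(self.insertion_angle)
        return (math.sin(a), math.cos(a))

    def _tip_px(self) -> tuple[float, float]:
        d = self._direction()
        length_px = self.insertion_depth / self.pixel_spacing
        return (self.entry_point[0] + length_px * d[0], self.entry_point[1] + length_px * d[1])


@dataclass(frozen=True)
class NeedleTruth:
    """Ground-truth needle geometry of a phantom trial."""

    entry: tuple[float, float]   # (row, col) px
    tip: tuple[float, float]     # (row, col) px
    angle: float                 # degrees from horizontal
    diameter: float              # mm

    def __post_init__(self) -> None:
        d = (self.tip[0] - self.entry[0], self.tip[1] - self.entry[1])
        recomputed = line_angle_deg(np.asarray(d))
        if abs((recomputed - self.angle + 90.0) % 180.0 - 90.0) > 1e-9:
            raise ValueError("stored angle inconsistent with entry->tip direction")


def _segment_distance(rows: np.ndarray, cols: np.ndarray,
                      p0: tuple[float, float], p1: tuple[float, float]) -> np.ndarray:
    """Distance from each (row, col) grid point to the segment p0-p1."""
    p0a, p1a = np.asarray(p0, float), np.asarray(p1, float)
    seg = p1a - p0a
    L2 = float(seg @ seg)
    dr = rows - p0a[0]
    dc = cols - p0a[1]
    t = np.clip((dr * seg[0] + dc * seg[1]) / max(L2, 1e-12), 0.0, 1.0)
    return np.hypot(dr - t * seg[0], dc - t * seg[1])


def _log_compress(amplitude: np.ndarray, gain: float = 30.0) -> np.ndarray:
    """Map non-negative echo amplitude to display intensity in [0, 1]."""
    return np.log1p(gain * amplitude) / math.log1p(gain * 3.0)


def generate_phantom_pair(config: PhantomConfig, *, return_blobs: bool = False):
    """Generate a (bmode, doppler, truth) triple for one trial.

    Returns
    -------
    bmode, doppler : ImageGrid
        Co-registered images, intensities in [0, 1].
    truth : NeedleTruth
        Exact needle geometry used to draw the images.
    blobs : list of (center_px, axial_fraction, sigma_along_px), only if
        ``return_blobs``: on-needle Doppler blobs recorded before
        rasterization.
    """
    rng = np.random.default_rng(config.seed)
    h, w = config.image_height_px, config.image_width_px
    rows, cols = np.mgrid[0:h, 0:w].astype(float)
    entry = (float(config.entry_point[0]), float(config.entry_point[1]))
    tip = config._tip_px()
    diam_px = config.needle_diameter / config.pixel_spacing
    direction = np.asarray(config._direction())
    length_px = config.insertion_depth / config.pixel_spacing

    # ---- B-mode: reflectivity scene x Rayleigh speckle, log-compressed ----
    reflectivity = np.ones((h, w))
    needle_amp = config.needle_brightness * max(
        0.15, 1.0 - config.visibility_falloff * config.insertion_angle)
    d_needle = _segment_distance(rows, cols, entry, tip)
    # soft-edged capsule of width ~= the needle diameter
    needle_mask = np.clip(diam_px / 2.0 + 0.5 - d_needle, 0.0, 1.0)
    reflectivity += 2.0 * needle_amp * needle_mask

    for _ in range(config.n_distractors):
        # linear reflector at an angle well away from the needle's
        while True:
            ang = rng.uniform(0.0, 180.0)
            if abs((ang - config.insertion_angle + 90.0) % 180.0 - 90.0) >= 10.0:
                break
        c0 = np.array([rng.uniform(0.15 * h, 0.9 * h), rng.uniform(0.1 * w, 0.9 * w)])
        half = rng.uniform(0.08, 0.2) * min(h, w)
        dvec = np.array([math.sin(math.radians(ang)), math.cos(math.radians(ang))])
        dd = _segment_distance(rows, cols, tuple(c0 - half * dvec), tuple(c0 + half * dvec))
        dist_mask = np.clip(diam_px / 2.0 + 0.5 - dd, 0.0, 1.0)
        reflectivity += 2.0 * rng.uniform(0.3, 0.6) * dist_mask

    speckle = rng.rayleigh(scale=config.speckle_scale, size=(h, w))
    bmode = np.clip(_log_compress(reflectivity * speckle), 0.0, 1.0)

    # ---- power Doppler: sparse noise + elliptical blobs along the shaft ----
    doppler = rng.exponential(scale=0.015, size=(h, w))
    blob_centers = []

    def add_blob(center: np.ndarray, amp: float, s_along: float, s_across: float,
                 ang_deg: float) -> None:
        th = math.radians(ang_deg)
        u = np.array([math.sin(th), math.cos(th)])
        v = np.array([-math.cos(th), math.sin(th)])
        dr = rows - center[0]
        dc = cols - center[1]
        cu = dr * u[0] + dc * u[1]
        cv = dr * v[0] + dc * v[1]
        doppler_local = amp * np.exp(-0.5 * ((cu / s_along) ** 2 + (cv / s_across) ** 2))
        np.maximum(doppler, doppler_local, out=doppler)

    n_blobs = config.doppler_blob_count
    if n_blobs > 0:
        # stratified midpoints along the shaft (gap-free coverage) plus extra
        # mass near the tip, emulating the strongest vibration at the free
        # distal end; the excited tip itself always responds
        n_strat = max(1, n_blobs // 2)
        t_strat = (np.arange(n_strat) + 0.5) / n_strat
        n_tipside = n_blobs - n_strat
        t_tip = 1.0 - 0.45 * rng.uniform(0.0, 1.0, n_tipside) ** 2
        ts = np.concatenate([t_strat, t_tip])
        ts[-1] = 1.0
        # blob centers ride a systematic deep-side displacement (Doppler
        # blooming below the shaft) plus random scatter, together staying
        # within doppler_blob_jitter of the axis for the large majority
        offset_px = config.doppler_blob_offset / config.pixel_spacing
        jitter_sd_px = max(1e-6, 0.25 * (config.doppler_blob_jitter
                                         - config.doppler_blob_offset)
                           / config.pixel_spacing)
        normal = np.array([-direction[1], direction[0]])
        deep = normal if normal[0] > 0 else -normal  # points toward larger row
        if abs(normal[0]) < 1e-9:
            deep = normal
        for t in ts:
            s_along = rng.uniform(1.4, 2.4) / config.pixel_spacing
            center = np.asarray(entry) + t * length_px * direction
            center = center + (offset_px + rng.normal(0.0, jitter_sd_px)) * deep
            blob_centers.append((center.copy(), float(t), float(s_along)))
            add_blob(center,
                     amp=rng.uniform(0.5, 1.0),
                     s_along=s_along,
                     s_across=rng.uniform(0.5, 0.9) * diam_px,
                     ang_deg=config.insertion_angle + rng.normal(0.0, 8.0))

    min_off_axis = 10.0 * diam_px
    for _ in range(config.n_spurious_blobs):
        for _attempt in range(200):
            center = np.array([rng.uniform(0, h - 1), rng.uniform(0, w - 1)])
            if _segment_distance(center[0:1], center[1:2], entry, tip)[0] >= min_off_axis:
                break
        add_blob(center,
                 amp=rng.uniform(0.3, 0.8),
                 s_along=rng.uniform(0.8, 1.6) / config.pixel_spacing,
                 s_across=rng.uniform(0.8, 1.6) / config.pixel_spacing,
                 ang_deg=rng.uniform(0.0, 180.0))

    doppler = np.clip(doppler, 0.0, 1.0)

    truth = NeedleTruth(entry=entry, tip=tip, angle=config.insertion_angle,
                        diameter=config.needle_diameter)
    bgrid = ImageGrid(bmode, config.pixel_spacing)
    dgrid = ImageGrid(doppler, config.pixel_spacing)
    if return_blobs:
        return bgrid, dgrid, truth, blob_centers
    return bgrid, dgrid, truth


def batch_configs(n_trials: int = 30, seed: int = 0,
                  angle_range: tuple[float, float] = (0.0, 65.0),
                  depth_range: tuple[float, float] = (40.0, 80.0)) -> list[PhantomConfig]:
    """Configurations for a batch evaluation protocol.

    Insertion angles are evenly spaced over ``angle_range`` (covering the
    shallow, moderate and steep bins) and depths evenly cover
    ``depth_range``; the angle-depth pairing is shuffled deterministically
    from ``seed``, and trial i uses phantom seed ``seed * n_trials + i``.
    """
    rng = np.random.default_rng(seed)
    angles = np.linspace(angle_range[0], angle_range[1], n_trials)
    depths = np.linspace(depth_range[0], depth_range[1], n_trials)
    rng.shuffle(depths)
    return [PhantomConfig(insertion_angle=float(a), insertion_depth=float(d),
                          seed=seed * n_trials + i)
            for i, (a, d) in enumerate(zip(angles, depths))]


def write_phantom_pair(config: PhantomConfig, out_dir: str | Path) -> dict[str, str]:
    """Write the image pair as 16-bit PNGs plus a JSON truth sidecar."""
    import imageio.v3 as iio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bmode, doppler, truth = generate_phantom_pair(config)
    paths = {}
    for name, grid in (("bmode", bmode), ("doppler", doppler)):
        arr16 = np.round(grid.intensities * 65535.0).astype(np.uint16)
        p = out / f"{name}.png"
        iio.imwrite(p, arr16)
        paths[name] = str(p)
    sidecar = {
        "entry": list(truth.entry),
        "tip": list(truth.tip),
        "angle_deg": truth.angle,
        "diameter_mm": truth.diameter,
        "pixel_spacing_mm": config.pixel_spacing,
    }
    tp = out / "truth.json"
    tp.write_text(json.dumps(sidecar, indent=2))
    paths["truth"] = str(tp)
    return paths
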