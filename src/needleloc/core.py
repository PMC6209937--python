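"""Shared geometric primitives for the needle-localization pipeline.

Coordinate convention, used everywhere in this package:

* pixel coordinates are ``(row, col)``, 0-based, row 0 at the top of the
  image (the transducer face / shallowest depth);
* a line's *angle from horizontal* ``alpha`` is the angle of its direction
  vector ``(dr, dc) = (sin alpha, cos alpha)`` in degrees, so a horizontal
  line has ``alpha = 0`` and a needle descending to the right has
  ``0 < alpha < 90``;
* the Radon integration angle ``theta`` relates to the line angle by
  ``theta = (90 - alpha) mod 180``: a line at angle ``alpha`` produces its
  sinogram peak at integration angle ``theta``;
* the signed Radon offset ``rho`` is measured from the image center
  ``(nrows // 2, ncols // 2)`` along the line normal
  ``(x, y) = (col - cc, cr - row)``, i.e. the line is
  ``x cos(theta) + y sin(theta) = rho``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = ["ImageGrid", "LineEstimate", "EllipseROI", "line_angle_deg", "wrap_angle_180"]


def wrap_angle_180(angle_deg: float) -> float:
    """Reduce a line angle to the canonical range [0, 180)."""
    return float(angle_deg) % 180.0


def line_angle_deg(direction: np.ndarray) -> float:
    """Angle from horizontal (degrees, in [0, 180)) of a (dr, dc) direction."""
    dr, dc = float(direction[0]), float(direction[1])
    return wrap_angle_180(math.degrees(math.atan2(dr, dc)))


@dataclass(frozen=True)
class ImageGrid:
    """A 2D intensity image together with its isotropic pixel spacing.

    Parameters
    ----------
    intensities
        2D array of finite, non-negative reals, row-major, row 0 at top.
    pixel_spacing
        Physical size of one pixel in mm (isotropic).
    """

    intensities: np.ndarray
    pixel_spacing: float

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities, dtype=float)
        if arr.ndim != 2 or arr.size == 0:
            raise ValueError("intensities must be a non-empty 2D array")
        if not np.all(np.isfinite(arr)) or np.any(arr < 0):
            raise ValueError("intensities must be finite and non-negative")
        if not (self.pixel_spacing > 0):
            raise ValueError("pixel_spacing must be positive")
        object.__setattr__(self, "intensities", arr)

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensities.shape

    def mm_to_px(self, mm: float) -> float:
        return mm / self.pixel_spacing

    def px_to_mm(self, px: float) -> float:
        return px * self.pixel_spacing


@dataclass(frozen=True)
class LineEstimate:
    """A straight axis in image coordinates.

    Stored as a point on the line plus a unit direction; the equivalent
    Radon parameterization ``(theta, rho)`` relative to a given image shape
    is available through :meth:`theta_rho`.  The direction is normalized so
    that ``dr >= 0`` (pointing deeper into the image); for horizontal lines
    ``dc > 0``.
    """

    point: tuple[float, float]
    direction: tuple[float, float]

    def __post_init__(self) -> None:
        d = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(d)
        if n == 0:
            raise ValueError("direction must be non-zero")
        d = d / n
        if d[0] < 0 or (d[0] == 0 and d[1] < 0):
            d = -d
        object.__setattr__(self, "direction", (float(d[0]), float(d[1])))
        object.__setattr__(self, "point", (float(self.point[0]), float(self.point[1])))

    @property
    def angle_deg(self) -> float:
        """Angle from horizontal in [0, 180)."""
        return line_angle_deg(np.asarray(self.direction))

    @property
    def normal(self) -> tuple[float, float]:
        """A unit normal (dr, dc) to the line."""
        dr, dc = self.direction
        return (-dc, dr)

    def distance_to(self, pt: tuple[float, float]) -> float:
        """Perpendicular distance (px) from a (row, col) point to the line."""
        nr, nc = self.normal
        return abs((pt[0] - self.point[0]) * nr + (pt[1] - self.point[1]) * nc)

    def project(self, pt: tuple[float, float]) -> tuple[float, float]:
        """Orthogonal projection of a (row, col) point onto the line."""
        dr, dc = self.direction
        t = (pt[0] - self.point[0]) * dr + (pt[1] - self.point[1]) * dc
        return (self.point[0] + t * dr, self.point[1] + t * dc)

    def point_at(self, t: float) -> tuple[float, float]:
        """Point at signed arclength ``t`` (px) from ``self.point``."""
        return (self.point[0] + t * self.direction[0], self.point[1] + t * self.direction[1])

    def theta_rho(self, shape: tuple[int, int]) -> tuple[float, float]:
        """Radon parameters (theta deg in [0,180), signed rho px) for ``shape``."""
        theta = wrap_angle_180(90.0 - self.angle_deg)
        cr, cc = shape[0] // 2, shape[1] // 2
        th = math.radians(theta)
        x = self.point[1] - cc
        y = cr - self.point[0]
        rho = x * math.cos(th) + y * math.sin(th)
        return (theta, rho)

    @classmethod
    def from_theta_rho(cls, theta_deg: float, rho_px: float, shape: tuple[int, int]) -> "LineEstimate":
        """Build the line ``x cos(theta) + y sin(theta) = rho`` for an image shape."""
        cr, cc = shape[0] // 2, shape[1] // 2
        th = math.radians(theta_deg)
        # foot of the normal from the image center
        x0, y0 = rho_px * math.cos(th), rho_px * math.sin(th)
        point = (cr - y0, cc + x0)
        direction = (math.cos(th), math.sin(th))  # (dr, dc); see module docstring
        return cls(point=point, direction=direction)

    def clip_to_image(self, shape: tuple[int, int]) -> list[tuple[float, float]]:
        """Intersections of the infinite line with the image rectangle.

        Returns 0, 1 or 2 boundary points (row, col), sorted by (row, col).
        The rectangle spans pixel centers [0, nrows-1] x [0, ncols-1].
        """
        nrows, ncols = shape
        p = np.asarray(self.point)
        d = np.asarray(self.direction)
        ts: list[float] = []
        eps = 1e-9
        if abs(d[0]) > eps:
            ts += [(0 - p[0]) / d[0], (nrows - 1 - p[0]) / d[0]]
        if abs(d[1]) > eps:
            ts += [(0 - p[1]) / d[1], (ncols - 1 - p[1]) / d[1]]
        pts = []
        for t in ts:
            q = p + t * d
            if -eps <= q[0] <= nrows - 1 + eps and -eps <= q[1] <= ncols - 1 + eps:
                q = (float(np.clip(q[0], 0, nrows - 1)), float(np.clip(q[1], 0, ncols - 1)))
                if not any(abs(q[0] - r) < 1e-6 and abs(q[1] - c) < 1e-6 for r, c in pts):
                    pts.append(q)
        return sorted(pts)


@dataclass(frozen=True)
class EllipseROI:
    """Elliptical stand-in for an irregular Doppler cluster.

    ``orientation`` is the major-axis angle from horizontal in degrees;
    axis lengths are full lengths (not semi-axes), in pixels.
    """

    center: tuple[float, float]
    major_axis_length: float
    minor_axis_length: float
    orientation: float = 0.0

    def __post_init__(self) -> None:
        if not (self.major_axis_length >= self.minor_axis_length > 0):
            raise ValueError("require major_axis_length >= minor_axis_length > 0")

    def contains(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        """Vectorized interior test (quadratic form <= 1) on pixel centers."""
        a = self.major_axis_length / 2.0
        b = self.minor_axis_length / 2.0
        th = math.radians(self.orientation)
        # major-axis unit vector in (row, col); orientation measured from horizontal
        ur, uc = math.sin(th), math.cos(th)
        dr = np.asarray(rows, dtype=float) - self.center[0]
        dc = np.asarray(cols, dtype=float) - self.center[1]
        u = dr * ur + dc * uc          # coordinate along major axis
        v = -dr * uc + dc * ur         # coordinate along minor axis
        return (u / a) ** 2 + (v / b) ** 2 <= 1.0

    def intersects_line(self, line: LineEstimate) -> bool:
        """Exact line-ellipse intersection test; tangency counts as hit.

        The infinite line hits the ellipse iff the perpendicular distance
        from the ellipse center to the line does not exceed the ellipse's
        support radius along the line normal,
        ``h = sqrt((a n.u)^2 + (b n.v)^2)`` with u, v the ellipse axes.
        """
        a = self.major_axis_length / 2.0
        b = self.minor_axis_length / 2.0
        th = math.radians(self.orientation)
        ur, uc = math.sin(th), math.cos(th)
        nr, nc = line.normal
        nu = nr * ur + nc * uc
        nv = -nr * uc + nc * ur
        support = math.hypot(a * nu, b * nv)
        dist = line.distance_to(self.center)
        return dist <= support + 1e-12
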