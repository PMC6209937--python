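"""Stage 2: B-mode refinement of the needle axis.

The initial axis from the Doppler stage is accurate to within the spatial
scatter of the vibration responses; the B-mode image, where the needle is
a thin bright line, supports a sharper estimate.  A single Gabor filter
tuned to the needle's width (wavelength = needle diameter in pixels) and to
the initial axis orientation enhances needle-like structures; the filter
response is kept only inside the Doppler-derived ellipse ROIs and zeroed
elsewhere, so distractor reflectors outside the Doppler evidence cannot
compete.  A Radon projection at the (fixed) initial angle then re-estimates
the axis offset.

Gabor geometry.  The kernel is a 2D Gaussian envelope times a complex
carrier, ``g = exp(-(x'^2/sigma_x^2 + y'^2/sigma_y^2)/2) exp(j 2 pi x'/lambda)``.
``theta`` names the orientation of the lines the filter enhances (the
needle axis): ``y'`` runs along that orientation and ``x'`` across it, so
the carrier oscillates across the shaft, whose width matches ``lambda``.
The envelope widths are calibrated so that it falls to 50% of its peak at
``(x'=lambda/2, y'=0)`` and at ``(x'=0, y'=lambda)``:

    sigma_x = lambda / (2 sqrt(2 ln 2)),  sigma_y = lambda / sqrt(2 ln 2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve
from skimage.transform import radon

from .core import EllipseROI, ImageGrid, LineEstimate

__all__ = ["GaborParams", "build_gabor_kernel", "gabor_envelope",
           "roi_mask", "masked_gabor_filter", "refine_axis"]

_HWHM = 2.0 * math.sqrt(2.0 * math.log(2.0))  # FWHM / sigma for a Gaussian


@dataclass(frozen=True)
class GaborParams:
    """Orientation (degrees from horizontal) and wavelength (px) of the
    needle-enhancement Gabor filter; the envelope deviations follow from
    the wavelength via the 50%-amplitude calibration."""

    theta: float
    wavelength: float

    def __post_init__(self) -> None:
        if self.wavelength < 1.0:
            raise ValueError("needle thinner than one pixel: wavelength < 1 px")

    @property
    def sigma_x(self) -> float:
        """Envelope deviation across the enhanced line: lambda/(2 sqrt(2 ln 2))."""
        return self.wavelength / _HWHM

    @property
    def sigma_y(self) -> float:
        """Envelope deviation along the enhanced line: lambda/sqrt(2 ln 2)."""
        return 2.0 * self.wavelength / _HWHM

    @classmethod
    def for_needle(cls, axis_angle_deg: float, needle_diameter_mm: float,
                   pixel_spacing_mm: float) -> "GaborParams":
        """Filter matched to a needle: wavelength = diameter in pixels."""
        return cls(theta=axis_angle_deg,
                   wavelength=needle_diameter_mm / pixel_spacing_mm)


def gabor_envelope(params: GaborParams, x_prime: float, y_prime: float) -> float:
    """Gaussian envelope factor of the Gabor kernel at rotated coordinates."""
    return math.exp(-0.5 * ((x_prime / params.sigma_x) ** 2
                            + (y_prime / params.sigma_y) ** 2))


def build_gabor_kernel(params: GaborParams) -> np.ndarray:
    """Complex Gabor kernel on an odd-sized grid truncated at +-3 sigma.

    The kernel value at the origin is exactly ``1 + 0j``.
    """
    half = int(math.ceil(3.0 * max(params.sigma_x, params.sigma_y)))
    ys, xs = np.mgrid[-half:half + 1, -half:half + 1].astype(float)
    # (xs, ys) = (col offset, row offset); y' along the enhanced orientation
    th = math.radians(params.theta)
    along = xs * math.cos(th) + ys * math.sin(th)      # y': along the line
    across = -xs * math.sin(th) + ys * math.cos(th)    # x': across the line
    envelope = np.exp(-0.5 * ((across / params.sigma_x) ** 2
                              + (along / params.sigma_y) ** 2))
    carrier = np.exp(1j * 2.0 * math.pi * across / params.wavelength)
    return envelope * carrier


def roi_mask(shape: tuple[int, int], rois: list[EllipseROI]) -> np.ndarray:
    """Boolean union of ellipse interiors, evaluated on pixel centers."""
    rows, cols = np.mgrid[0:shape[0], 0:shape[1]]
    mask = np.zeros(shape, dtype=bool)
    for roi in rois:
        mask |= roi.contains(rows, cols)
    return mask


def masked_gabor_filter(bmode: ImageGrid, rois: list[EllipseROI],
                        params: GaborParams) -> ImageGrid:
    """Gabor-filter the B-mode image and zero everything outside the ROIs.

    The filter response is the complex magnitude of the full-image
    convolution (zero-padded borders); masking afterwards is identical to
    filtering inside the ROIs except within a kernel-width of the ROI
    borders.
    """
    if not rois:
        raise ValueError("no candidate regions: empty ROI list")
    kernel = build_gabor_kernel(params)
    response = np.abs(fftconvolve(bmode.intensities, kernel, mode="same"))
    response[~roi_mask(bmode.shape, rois)] = 0.0
    return ImageGrid(response, bmode.pixel_spacing)


def refine_axis(filtered: ImageGrid, theta_init_deg: float) -> LineEstimate:
    """Re-estimate the axis offset from the filtered image at a fixed angle.

    Computes the Radon projection at the initial axis's integration angle
    only and returns the line at the maximizing offset; the returned line
    angle equals ``theta_init_deg`` exactly.  Offset ties break toward the
    smallest signed rho.
    """
    arr = filtered.intensities
    if not np.any(arr > 0):
        raise ValueError("refinement impossible: filtered image is all zero")
    radon_theta = (90.0 - theta_init_deg) % 180.0
    sino = radon(arr, theta=np.array([radon_theta]), circle=False,
                 preserve_range=True)[:, 0]
    r_idx = int(np.argmax(sino))  # first occurrence == smallest rho
    rho = float(r_idx - sino.shape[0] // 2)
    line = LineEstimate.from_theta_rho(radon_theta, rho, arr.shape)
    return line
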