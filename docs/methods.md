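# Methods

This note records the model behind `needleloc`, the parameters that matter,
what the synthetic phantom does and does not emulate, and the numerical
choices made where the design was genuinely open.

## Problem model

A straight, rigid needle of diameter $d$ mm is inserted into tissue at an
angle $\alpha \in [0^\circ, 65^\circ]$ from the skin surface (the horizontal
image axis) to a depth of 40–80 mm along the shaft. Two co-registered 2D
images of the scene exist on a common pixel grid with isotropic spacing $s$
mm/px: a power Doppler image $I_{PD}$, in which vibration of the buzzer-excited
needle produces irregular high-intensity blobs concentrated along (and
systematically displaced to the deep side of) the shaft, and a B-mode image
$I_{BM}$, in which the shaft is a thin bright line whose visibility decreases
with insertion angle. The task is to estimate the needle axis (a line in
image coordinates) and the tip position.

Coordinates are `(row, col)`, row 0 at the transducer face; a line's angle is
measured from the horizontal, and the Radon integration angle is
$\theta = (90^\circ - \alpha) \bmod 180^\circ$. All physical parameters are
given in mm and converted to pixels exactly once, at configuration load.

## Stage 1 — Doppler initial axis

* **Intermeans threshold.** $T_{k+1} = \tfrac12(\mu_{<T_k} + \mu_{\ge T_k})$
  starting from the global mean, iterated until the step falls below half an
  intensity unit (scaled to the image's dynamic range for normalized images)
  or 100 iterations. A constant image is returned unchanged with a
  degenerate flag. Pixels *strictly below* the threshold are zeroed; the
  rest are unaltered, so the output contains no value in $(0, T)$.
* **Density clustering.** Nonzero pixels within Euclidean distance $R$ are
  connected; connected groups with fewer than $M$ pixels are discarded as
  noise. $M$ is the minimum number of pixels per cluster (not a core-point
  neighbor count): that is what makes a 12×12 solid block at $R=6$, $M=100$
  one cluster of 144 pixels rather than 140 plus noise corners. Defaults
  $R = 6$ px, $M = 100$, the values tuned on ex vivo tissue imagery;
  both are overridable through `DbscanParams`.
* **Radon peak.** The clustered pixels keep their Doppler intensities (so
  the maximal line integral honors "strongest" as well as "longest");
  everything else is zero. The sinogram is computed over
  $[0^\circ, 180^\circ)$ at $1^\circ$ steps — $\theta$ and $\theta+180^\circ$
  produce mirror-image projections, so the half range is lossless — and the
  global peak $(\theta, \rho)$ is converted to a line analytically rather
  than via an inverse transform, which is numerically needless for a single
  peak. Ties break toward the smallest $\theta$, then the smallest signed
  $\rho$.
* **Ellipse ROIs.** Each cluster is replaced by the ellipse with the same
  normalized second central moments: centroid center, axes $4\sqrt{\lambda_i}$
  from the eigen-decomposition of the coordinate covariance, minor axis
  floored at 1 px for collinear clusters. An ellipse survives iff the
  initial axis meets it, tested exactly: center-to-line distance at most the
  ellipse's support radius along the line normal (tangency counts).

## Stage 2 — B-mode refinement

The Gabor kernel is a Gaussian envelope times a complex carrier,

$$g(x', y') = \exp\!\left(-\tfrac12\left(\tfrac{x'^2}{\sigma_x^2} +
\tfrac{y'^2}{\sigma_y^2}\right)\right) e^{j 2\pi x' / \lambda},$$

with $y'$ along the orientation being enhanced (the initial axis) and $x'$
across it: the carrier oscillates across the shaft, whose width sets
$\lambda = d/s$ px. Both envelope widths follow from requiring 50% amplitude
at $(x'{=}\lambda/2, y'{=}0)$ and $(x'{=}0, y'{=}\lambda)$:
$\sigma_x = \lambda/(2\sqrt{2\ln 2})$, $\sigma_y = \lambda/\sqrt{2\ln 2}$.
These two conditions are the normative definition here; the response is the
complex magnitude of the convolution (phase-invariant along the needle), the
kernel support is truncated at $\pm3\sigma_{\max}$ on an odd grid, and
convolution uses zero padding. A sub-pixel wavelength ($d < s$) is rejected.

Filtering is applied to the full image and then masked to zero outside the
union of ROI interiors (quadratic-form test on pixel centers) — identical to
filtering only inside the ROIs except within one kernel width of an ROI
border, where the full-image variant uses the true image content rather than
an artificial zero boundary.

The Radon projection of the masked response is evaluated at the single
integration angle of the initial axis and its maximizing offset (ties toward
the smallest signed $\rho$) gives the refined axis. The angle is *inherited*,
not re-estimated: the Doppler stage fixes $\theta$ to the $1^\circ$ grid and
stage 2 corrects only the lateral offset. If the masked response is
identically zero the initial axis is kept and logged.

## Stage 3 — tip localization

The entry point is the axis–boundary intersection with the smallest row
(ties toward the smallest column). From there, a window of length $2d$ and
width $d$ (long side along the axis) slides in unit steps; the window means
of both images are taken over a $0.5$ px bilinear sub-grid (4 samples per
pixel area, for rotation robustness), excluding sub-samples outside the
image. The threshold on $\bar I_{PD}$ is its own mean over the full profile;
the separation score

$$S(l) = \frac{\sum_{i \le l} B(i) + \sum_{i > l} (1 - B(i))}{L}$$

(upper summation bound $L-1$, the last valid index; denominator $L$) is
maximized, ties toward the larger $l$ — for a perfect step $1\ldots10\ldots0$
the argmax provably sits at the step. The refined tip minimizes the *signed*
forward difference of $\bar I_{BM}$ within $2d$ of the Doppler tip (ties
toward larger $l$), i.e. the strongest brightness drop; the tip is placed at
the last needle-like sample, without sub-pixel interpolation. A constant
$\bar I_{PD}$ (no termination evidence) or a drop-free search window falls
back gracefully and flags the result low-confidence.

## Phantom generator

The generator emulates, on a rectangular linear-array-like grid (no
curvilinear scan conversion — the localization math never uses fan geometry):

* **B-mode:** a reflectivity scene (tissue 1.0; a soft-edged needle capsule of
  width $d/s$ px whose amplitude `needle_brightness` is attenuated linearly
  by `visibility_falloff` per degree of insertion angle, floored at 15%;
  `n_distractors` linear reflectors at angles ≥ 10° away from the needle's)
  multiplied by Rayleigh speckle and log-compressed to $[0,1]$.
* **Doppler:** weak exponential background noise, `doppler_blob_count`
  elliptical Gaussian blobs along the shaft — axial positions stratified
  (gap-free coverage from entry to tip, so a termination point always
  exists) with extra mass concentrated near the tip, the tip itself always
  responding — plus `n_spurious_blobs` blobs kept at least 10 needle
  diameters off-axis. Blob centers are displaced toward the deep side of
  the shaft by `doppler_blob_offset` (default 1.0 mm) with random scatter
  inside the `doppler_blob_jitter` envelope (default 2.0 mm). The
  deep-side bias reproduces the blooming of Doppler responses below a
  vibrating needle and is the feature that makes the two-stage design
  meaningful: the Doppler axis inherits the bias as an offset error at an
  accurate angle, and the B-mode stage removes it. With a zero-mean lateral
  model the Doppler stage is either already sub-pixel (nothing to refine) or
  wrong in angle (unrecoverable at fixed $\theta$), neither of which matches
  the imaging situation the method addresses.

Defaults: 360×480 px at 0.25 mm/px (a 90 mm × 120 mm field), 18G needle
($d = 1.27$ mm), entry on the *left* image edge at row 40 — the studied range
includes $\alpha = 0^\circ$, where a top-edge entry would run the needle
along the image border and clip every profile window. All randomness flows
from the single integer seed; identical configurations are bit-identical.

What the phantom does **not** emulate: curvilinear geometry and
scan-conversion artifacts, depth-dependent attenuation and focusing,
reverberation/comet-tail artifacts under the shaft, wall-filter clutter
residue, tissue motion, or bent needles. Passing the synthetic batch
therefore demonstrates the pipeline's correctness under its stated
assumptions (straight needle, Doppler evidence concentrated near a partially
visible linear shaft), not clinical-grade performance on acquired images.

## Evaluation protocol

The batch protocol (`needleloc.phantom.batch_configs`) draws 30 trials with
insertion angles evenly spaced over $[0^\circ, 65^\circ]$ (covering the
shallow $[0,20]$, moderate $(20,40]$ and steep $(40,65]$ bins — bins closed
on the right, since the bin bounds are conventionally written overlapping)
and depths evenly covering 40–80 mm, pairing shuffled deterministically from
the batch seed. 30 trials at 360×480 px keep a full batch under a minute on
one CPU while exercising every angle bin; error statistics over successes
use the population standard deviation, and empty bins are omitted rather
than reported as zero.

## Known limitations

* The refined axis angle is quantized to the 1° Radon grid of stage 1; the
  residual axis error this leaves (up to ≈0.35 mm at 80 mm depth) is
  accepted, as offset refinement dominates the error budget.
* Radon offsets are integer pixels; no sub-pixel peak interpolation.
* The tip is reported at integer profile index (no sub-pixel refinement),
  and a single needle is assumed — multi-needle scenes, curved tips and
  temporal tracking are out of scope.
* `intermeans_threshold` is scale-aware but assumes a roughly bimodal
  Doppler histogram; images whose blob intensities grade continuously into
  noise may threshold low and admit spurious clusters (mitigated by the
  $M$ filter and ROI elimination).
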