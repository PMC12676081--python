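"""Calibrated 2D morphometry on labelled masks.

Measures the quantitative characters used to diagnose fossil fungal
structures in thin section: equivalent spore diameter from mask area, spore
wall thickness of closed annuli (mean via area over medial length,
variability via the distance transform along the medial axis), and
hyphal/tube widths along a skeleton with branch points excluded.

All measurements are planar (the section plane); no stereological
correction for oblique sectioning is applied.  Foreground is 8-connected,
background 4-connected.

The skeleton-based estimators compute the skeleton on the original mask
(upsampling introduces staircase spurs) but sample the Euclidean distance
transform of a 4x bilinearly upsampled, rethresholded copy: bilinear
upsampling irons staircase notches back onto the smooth boundary, and the
orientation-dependent overshoot of the nearest-background distance beyond
the true boundary (half a pixel for grid-aligned edges, near zero for
oblique or curved ones) shrinks to under an eighth of an original pixel,
which is then removed as a fixed correction.  Both estimators are
validated against analytic bar and annulus oracles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure, morphology, transform

__all__ = [
    "CalibratedMask",
    "MorphRecord",
    "equivalent_diameter",
    "wall_thickness",
    "tubular_width",
]

_BG_STRUCTURE = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)  # 4-conn
_FG_STRUCTURE = np.ones((3, 3), dtype=bool)                              # 8-conn


@dataclass
class CalibratedMask:
    """Binary mask plus its micron-per-pixel scale."""

    mask: np.ndarray
    pixel_size_um: float

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        self.mask = np.asarray(self.mask).astype(bool)


@dataclass
class MorphRecord:
    """Collected measurements of one structure (all lengths in um)."""

    equivalent_diameter_um: float | None = None
    major_axis_um: float | None = None
    minor_axis_um: float | None = None
    wall_thickness_mean_um: float | None = None
    wall_thickness_sd_um: float | None = None
    width_median_um: float | None = None
    width_min_um: float | None = None
    width_max_um: float | None = None

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}


def equivalent_diameter(calmask: CalibratedMask) -> float:
    """Diameter of the disc with the mask's area: 2*sqrt(area_px/pi)*scale."""
    area = int(calmask.mask.sum())
    if area == 0:
        raise ValueError("empty mask")
    return 2.0 * math.sqrt(area / math.pi) * calmask.pixel_size_um


def _holes(mask: np.ndarray) -> int:
    """Number of background components fully enclosed by foreground."""
    labels, n = ndimage.label(~mask, structure=_BG_STRUCTURE)
    border = np.unique(np.concatenate([
        labels[0], labels[-1], labels[:, 0], labels[:, -1]
    ]))
    border = set(border[border > 0].tolist())
    return n - len(border)


_UPSAMPLE = 4


def _subpixel_widths(mask: np.ndarray, skel: np.ndarray) -> np.ndarray:
    """Full widths (original-pixel units) at skeleton pixels, sub-pixel EDT.

    The EDT is taken on a 4x bilinearly upsampled mask and averaged over the
    central 2x2 upsampled block of each skeleton pixel; 0.125 px of residual
    boundary overshoot is subtracted (see module docstring).
    """
    f = _UPSAMPLE
    up = transform.resize(mask.astype(float), (mask.shape[0] * f, mask.shape[1] * f),
                          order=1, anti_aliasing=False) >= 0.5
    dist_up = ndimage.distance_transform_edt(up)
    ys, xs = np.nonzero(skel)
    block = (dist_up[f * ys + 1, f * xs + 1] + dist_up[f * ys + 1, f * xs + 2]
             + dist_up[f * ys + 2, f * xs + 1] + dist_up[f * ys + 2, f * xs + 2]) / 4.0
    return np.maximum(2.0 * block / f - 0.125, 1.0 / f)


def _boundary_length(mask: np.ndarray, sigma_px: float = 3.0) -> float:
    """Total boundary length from smoothed sub-pixel marching-squares contours.

    Smoothing the contour coordinates (circularly, for closed contours)
    removes the excess length of pixel staircases while barely perturbing
    smooth boundaries (curvature shrinkage ~ sigma^2 / 2R).
    """
    total = 0.0
    for contour in measure.find_contours(mask.astype(float), 0.5):
        closed = bool(np.allclose(contour[0], contour[-1]))
        pts = contour[:-1] if closed and len(contour) > 1 else contour
        if closed and len(pts) > 8:
            pts = np.column_stack([
                ndimage.gaussian_filter1d(pts[:, 0], sigma_px, mode="wrap"),
                ndimage.gaussian_filter1d(pts[:, 1], sigma_px, mode="wrap"),
            ])
        diffs = np.diff(pts, axis=0, append=pts[:1] if closed else None)
        if not closed:
            diffs = np.diff(pts, axis=0)
        total += float(np.sum(np.hypot(diffs[:, 0], diffs[:, 1])))
    return total


def _prune_endpoint_branches(skel: np.ndarray, max_iter: int | None = None) -> np.ndarray:
    """Iteratively strip endpoint pixels, leaving only closed skeleton loops."""
    out = skel.copy()
    kernel = _FG_STRUCTURE.astype(np.uint8)
    limit = max_iter if max_iter is not None else max(out.shape)
    for _ in range(limit):
        neighbors = ndimage.convolve(out.astype(np.uint8), kernel, mode="constant") - 1
        endpoints = out & (neighbors <= 1)
        if not endpoints.any():
            break
        out &= ~endpoints
    return out


def wall_thickness(calmask: CalibratedMask) -> tuple[float, float]:
    """Mean and SD wall thickness of a closed annulus (e.g. a spore wall).

    The mean is the ribbon identity area / medial length, with the medial
    length taken as the average of the inner and outer Crofton perimeters;
    this is sub-pixel accurate and insensitive to jagged boundaries.  The
    SD comes from sub-pixel distance-transform samples along the medial
    axis (spurious side branches removed by iterative endpoint pruning;
    the true axis of a closed wall is a loop).  A mask without an enclosed
    hole is not a wall and is rejected.
    """
    mask = calmask.mask
    if mask.sum() == 0:
        raise ValueError("empty mask")
    if _holes(mask) < 1:
        raise ValueError("mask encloses no hole: not a wall")

    # mean thickness of a closed ribbon = area / medial length, with the
    # medial length taken as the average of the inner and outer boundary
    # lengths measured on smoothed marching-squares contours (sub-pixel
    # accurate and insensitive to jagged or block-upsampled boundaries)
    filled = ndimage.binary_fill_holes(mask)
    hole = filled & ~mask
    p_outer = _boundary_length(filled)
    p_inner = _boundary_length(hole)
    medial_length = 0.5 * (p_outer + p_inner)
    if medial_length <= 0:
        raise ValueError("degenerate annulus: zero medial length")
    mean_px = mask.sum() / medial_length

    # thickness variability along the axis from the medial-axis EDT samples
    skel = morphology.medial_axis(mask)
    loop = _prune_endpoint_branches(skel)
    if not loop.any():
        loop = skel  # no closed loop survived; fall back to the raw axis
    samples_px = _subpixel_widths(mask, loop)
    sd_px = float(np.std(samples_px)) if len(samples_px) else 0.0
    return float(mean_px * calmask.pixel_size_um), sd_px * calmask.pixel_size_um


def _branch_points(skel: np.ndarray) -> np.ndarray:
    neighbors = ndimage.convolve(skel.astype(np.uint8), _FG_STRUCTURE.astype(np.uint8),
                                 mode="constant") - 1
    return skel & (neighbors > 2)


def tubular_width(calmask: CalibratedMask) -> tuple[float, float, float]:
    """(median, min, max) width in um of an elongated (tube-like) mask.

    The mask is skeletonized; width at each skeleton pixel is twice the
    (sub-pixel) distance-transform value.  Skeleton pixels within 2x the
    local width of a branch point are excluded, since the distance
    transform inflates at junctions.  Blob-like masks (skeleton shorter
    than 3x the median width) are rejected with an aspect diagnostic.
    """
    mask = calmask.mask
    if mask.sum() == 0:
        raise ValueError("empty mask")
    skel = morphology.skeletonize(mask)
    if not skel.any():
        raise ValueError("mask has no skeleton")
    widths_px = _subpixel_widths(mask, skel)
    median_w = float(np.median(widths_px))
    skel_len = int(skel.sum())
    if skel_len < 3 * median_w:
        raise ValueError(
            f"mask is blob-like: skeleton length {skel_len} px < 3 x median "
            f"width {median_w:.1f} px"
        )
    branch = _branch_points(skel)
    keep_far = np.ones(len(widths_px), dtype=bool)
    if branch.any():
        far = ndimage.distance_transform_edt(~branch) > 2.0 * median_w
        ys, xs = np.nonzero(skel)
        keep_far = far[ys, xs]
    if not keep_far.any():
        keep_far[:] = True
    samples = widths_px[keep_far] * calmask.pixel_size_um
    return float(np.median(samples)), float(np.min(samples)), float(np.max(samples))
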