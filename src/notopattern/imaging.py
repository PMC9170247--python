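"""Quantification pipeline for two-channel mosaic-overexpression images.

The pipeline reproduces a standard workflow for mosaics of labeled
notochord cells: each channel is min-max normalized, Gaussian-smoothed
(sigma 3 px), and the cell channel is thresholded with the conjunction of a
global cutoff (1.5x the image median) and a local-mean adaptive cutoff
(uniform disc of 120 px diameter).  Three nested segmentations follow:

* Segmentation 1 — the thresholded pixel mask;
* Segmentation 2 — cell objects: hole-filling by 5 binary dilations and 9
  binary erosions, 8-connected labeling, and an area filter at 3500 px^2
  (the extra erosions avoid counting pixels on cell-cell boundaries);
* Segmentation 3 — the neighborhood: pixels reached by a 25-px dilation of
  the mask but excluded from its 8-px dilation (the boundary zone).

Relative intensity compares the signal channel inside segmented cells with
the rest of a manually provided organ region.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np
import scipy.ndimage as ndi
from scipy.signal import fftconvolve
from skimage.morphology import disk

__all__ = [
    "Image2D",
    "SegmentationParams",
    "SegmentationBundle",
    "normalize_channel",
    "smooth",
    "threshold_seg1",
    "cells_seg2",
    "neighborhood_seg3",
    "relative_intensity",
    "segment_image",
]

logger = logging.getLogger(__name__)

PIXEL_SIZE_NM = 63.7  # physical step of the analyzed images


@dataclass(frozen=True)
class Image2D:
    """A single-channel 2-D intensity grid with pixel-size metadata."""

    pixels: np.ndarray
    pixel_size_nm: float = PIXEL_SIZE_NM

    def __post_init__(self):
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2 or px.size == 0:
            raise ValueError("pixels must be a nonempty 2-D array")
        if not np.all(np.isfinite(px)):
            raise ValueError("pixels contain non-finite values")
        object.__setattr__(self, "pixels", px)


@dataclass(frozen=True)
class SegmentationParams:
    sigma: float = 3.0                 # Gaussian width, px
    global_factor: float = 1.5         # multiplier of the median intensity
    local_kernel_diameter: int = 120   # uniform-disc local mean, px
    dilate_fill: int = 5               # hole-filling dilation iterations
    erode_fill: int = 9                # hole-filling erosion iterations
    min_area: int = 3500               # object area cutoff, px^2
    boundary_dilate: int = 8           # boundary-zone dilation radius, px
    neighborhood_dilate: int = 25      # neighborhood dilation radius, px

    def __post_init__(self):
        for name, v in asdict(self).items():
            if v <= 0:
                raise ValueError(f"SegmentationParams.{name} must be positive, got {v}")
        if self.erode_fill < self.dilate_fill:
            raise ValueError("erode_fill must be >= dilate_fill (boundary-trimming asymmetry)")


@dataclass(frozen=True)
class SegmentationBundle:
    """The three nested masks plus the parameters that produced them."""

    seg1: np.ndarray        # thresholded pixel mask
    seg2: np.ndarray        # labeled cell objects (0 = background)
    seg3: np.ndarray        # neighborhood mask
    params: SegmentationParams


def _as_pixels(image) -> np.ndarray:
    return image.pixels if isinstance(image, Image2D) else np.asarray(image, dtype=float)


def normalize_channel(image) -> Image2D:
    """Min-max normalize a channel to [0, 1].

    Constant images map to all zeros with a logged warning.
    """
    px = _as_pixels(image)
    if not np.all(np.isfinite(px)):
        raise ValueError("pixels contain non-finite values")
    lo, hi = px.min(), px.max()
    if hi == lo:
        logger.warning("constant image: normalization returns all zeros")
        out = np.zeros_like(px)
    else:
        out = (px - lo) / (hi - lo)
    meta = image.pixel_size_nm if isinstance(image, Image2D) else PIXEL_SIZE_NM
    return Image2D(out, meta)


def smooth(image, sigma: float = 3.0) -> Image2D:
    """Gaussian smoothing with reflective border handling."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    px = _as_pixels(image)
    meta = image.pixel_size_nm if isinstance(image, Image2D) else PIXEL_SIZE_NM
    return Image2D(ndi.gaussian_filter(px, sigma=sigma, mode="reflect"), meta)


def _local_mean_disc(px: np.ndarray, diameter: int) -> np.ndarray:
    """Mean over a uniform disc footprint, reflective padding, via FFT."""
    footprint = disk(diameter // 2).astype(float)
    r = footprint.shape[0] // 2
    if min(px.shape) < 2 * r + 1:
        raise ValueError(f"kernel diameter {diameter} exceeds image size {px.shape}")
    if r == 0:
        return px.copy()
    padded = np.pad(px, r, mode="reflect")
    conv = fftconvolve(padded, footprint / footprint.sum(), mode="same")
    return conv[r:-r, r:-r]


def threshold_seg1(image, params: SegmentationParams = SegmentationParams()) -> np.ndarray:
    """Dual-threshold pixel mask (Segmentation 1).

    A pixel is kept only if it exceeds both the global threshold
    (``global_factor`` times the image median) and the local mean over a
    uniform disc of ``local_kernel_diameter`` pixels — strict inequalities,
    so a constant image yields an empty mask.
    """
    px = _as_pixels(image)
    global_thr = params.global_factor * np.median(px)
    local_thr = _local_mean_disc(px, params.local_kernel_diameter)
    return (px > global_thr) & (px > local_thr)


def cells_seg2(seg1: np.ndarray, params: SegmentationParams = SegmentationParams()) -> np.ndarray:
    """Labeled cell objects (Segmentation 2).

    Holes are filled by ``dilate_fill`` binary dilations followed by
    ``erode_fill`` binary erosions (4-connected unit cross per iteration;
    the net erosion trims cell-boundary pixels), then 8-connected components
    with area >= ``min_area`` are kept and relabeled sequentially.
    """
    mask = np.asarray(seg1, dtype=bool)
    if mask.any():
        mask = ndi.binary_dilation(mask, iterations=params.dilate_fill)
        mask = ndi.binary_erosion(mask, iterations=params.erode_fill)
    labels, n = ndi.label(mask, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return labels
    areas = ndi.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    keep = np.flatnonzero(areas >= params.min_area) + 1
    out = np.zeros_like(labels)
    for new, old in enumerate(keep, start=1):
        out[labels == old] = new
    return out


def neighborhood_seg3(
    seg1: np.ndarray,
    params: SegmentationParams = SegmentationParams(),
    dilate_from_boundary: bool = False,
) -> np.ndarray:
    """Neighborhood mask (Segmentation 3).

    The 8-px dilation of the mask defines the boundary zone between cells;
    the 25-px dilation defines the extent of neighboring cells.  The
    neighborhood is the extended region minus the boundary zone, so it is
    disjoint from the 8-px-dilated mask by construction.  Dilations use a
    disc structuring element of the stated radius and start from the
    thresholded mask (set ``dilate_from_boundary`` to grow the 25-px
    dilation from the already-dilated boundary instead).
    """
    mask = np.asarray(seg1, dtype=bool)
    if not mask.any():
        return np.zeros_like(mask)
    boundary = ndi.binary_dilation(mask, structure=disk(params.boundary_dilate))
    base = boundary if dilate_from_boundary else mask
    extended = ndi.binary_dilation(base, structure=disk(params.neighborhood_dilate))
    return extended & ~boundary


def relative_intensity(signal, region_mask: np.ndarray, organ_mask: np.ndarray) -> float:
    """Mean signal inside ``region & organ`` over mean signal in the rest
    of the organ."""
    px = _as_pixels(signal)
    region = np.asarray(region_mask, dtype=bool)
    organ = np.asarray(organ_mask, dtype=bool)
    inside = region & organ
    outside = organ & ~region
    if not inside.any() or not outside.any():
        raise ValueError("region-inside-organ and organ-outside-region must both be nonempty")
    denom = px[outside].mean()
    if denom == 0:
        raise ValueError("zero mean intensity outside the region: ratio undefined")
    return float(px[inside].mean() / denom)


def segment_image(
    cell_channel,
    params: SegmentationParams = SegmentationParams(),
    dilate_from_boundary: bool = False,
) -> SegmentationBundle:
    """Normalize, smooth, threshold, and build the three segmentations."""
    norm = normalize_channel(cell_channel)
    sm = smooth(norm, sigma=params.sigma)
    seg1 = threshold_seg1(sm, params)
    seg2 = cells_seg2(seg1, params)
    seg3 = neighborhood_seg3(seg1, params, dilate_from_boundary=dilate_from_boundary)
    return SegmentationBundle(seg1=seg1, seg2=seg2, seg3=seg3, params=params)
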