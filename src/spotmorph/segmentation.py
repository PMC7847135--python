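"""Spot segmentation: automatic thresholding, despeckling and labeling.

The chain mirrors classic particle analysis of light pattern elements on a
dark cuticle: binarize with the Minimum histogram threshold, remove bright
and dark outlier pixels with a median ("remove outliers") filter of radius 6
and deviation threshold 50, fill enclosed gaps, and label the surviving
connected components as spots.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.measure import find_contours, regionprops

logger = logging.getLogger(__name__)


class SegmentationError(ValueError):
    """Raised when an image cannot be segmented into spots."""


@dataclass
class SegmentationParams:
    threshold_method: str = "minimum_auto"  # or "fixed"
    fixed_threshold: int | None = None
    outlier_radius: int = 6
    outlier_threshold: int = 50
    min_spot_area: int = 25
    connectivity: int = 8  # 4 or 8
    expected_spot_count: int | None = None  # QC flag only, never edits the mask

    def __post_init__(self) -> None:
        if self.outlier_radius < 1:
            raise ValueError("outlier_radius must be >= 1")
        if not 0 <= self.outlier_threshold <= 255:
            raise ValueError("outlier_threshold must be in [0, 255]")
        if self.min_spot_area < 1:
            raise ValueError("min_spot_area must be >= 1")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")


@dataclass
class BinaryMask:
    grid: np.ndarray  # bool, True = spot pixel
    roi_mask: np.ndarray  # bool, abdomen interior

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=bool)
        self.roi_mask = np.asarray(self.roi_mask, dtype=bool)
        if self.grid.shape != self.roi_mask.shape:
            raise ValueError("mask and ROI must share dimensions")


@dataclass
class SpotComponent:
    label: int
    pixel_count: int
    contour: np.ndarray  # (n, 2) ordered boundary points as (x, y)
    centroid: tuple[float, float]  # (x, y)


@dataclass
class LabeledSpots:
    labels: np.ndarray  # int grid, 0 = background
    components: list[SpotComponent] = field(default_factory=list)
    Ta: int = 0  # abdomen (ROI) area in pixels


def _smooth_hist(h: np.ndarray) -> np.ndarray:
    """3-bin running mean with replicated ends (the Minimum method's kernel)."""
    padded = np.concatenate([h[:1], h, h[-1:]])
    return (padded[:-2] + padded[1:-1] + padded[2:]) / 3.0


def _local_maxima(h: np.ndarray) -> np.ndarray:
    left = np.concatenate(([-np.inf], h[:-1]))
    right = np.concatenate((h[1:], [-np.inf]))
    return np.flatnonzero((h > left) & (h > right))


def minimum_auto_threshold(gray: np.ndarray, roi_mask: np.ndarray | None = None) -> int:
    """Minimum-method automatic threshold.

    The 256-bin histogram is repeatedly smoothed with a 3-bin mean filter
    until exactly two local maxima remain; the threshold is the bin of the
    minimum between them.  When the valley bottom is a tied plateau (well
    separated modes leave empty bins) the middle tied bin is returned, so
    the cut sits centrally between the modes and inverting the contrast
    mirrors the threshold.  Raises :class:`SegmentationError` if the
    histogram never becomes bimodal (e.g. a constant image).
    """
    gray = np.asarray(gray)
    values = gray[roi_mask] if roi_mask is not None else gray.ravel()
    if values.size == 0 or np.ptp(values) == 0:
        raise SegmentationError("unimodal histogram")
    hist = np.bincount(values.astype(np.uint8).ravel(), minlength=256).astype(float)
    for _ in range(10_000):
        maxima = _local_maxima(hist)
        if len(maxima) == 2:
            lo, hi = maxima
            valley = hist[lo : hi + 1]
            ties = np.flatnonzero(valley == valley.min())
            return int(lo + ties[(len(ties) - 1) // 2])
        if len(maxima) < 2:
            raise SegmentationError("unimodal histogram")
        hist = _smooth_hist(hist)
    raise SegmentationError("unimodal histogram")


def binarize_spots(gray: np.ndarray, threshold: int, roi_mask: np.ndarray) -> BinaryMask:
    """Threshold and pick the minority class inside the ROI as spots.

    Spots are the light minority elements on the dark cuticle, but the rule
    is polarity-free: whichever thresholded class covers the smaller ROI
    fraction becomes the spot class (ties go to the brighter class).
    """
    if not 0 <= threshold <= 255:
        raise ValueError("threshold must be in [0, 255]")
    gray = np.asarray(gray)
    roi_mask = np.asarray(roi_mask, dtype=bool)
    above = (gray > threshold) & roi_mask
    below = (gray <= threshold) & roi_mask
    n_above, n_below = int(above.sum()), int(below.sum())
    if n_above == 0 or n_below == 0:
        raise SegmentationError("degenerate threshold")
    if n_above <= n_below:
        logger.debug("binarize_spots: spot class = brighter (above threshold)")
        grid = above
    else:
        logger.debug("binarize_spots: spot class = darker (below threshold)")
        grid = below
    return BinaryMask(grid=grid, roi_mask=roi_mask)


def _disk_footprint(radius: int) -> np.ndarray:
    yy, xx = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    return (xx * xx + yy * yy) <= radius * radius


def remove_outliers(gray: np.ndarray, radius: int = 6, threshold: int = 50, bright: bool = True) -> np.ndarray:
    """Median replace-if-deviant filter (one polarity pass) on a grayscale image.

    A pixel deviating from the median of its radius-``radius`` circular
    neighborhood by more than ``threshold`` is replaced by that median;
    ``bright=True`` removes bright outliers, ``bright=False`` dark ones.
    """
    gray = np.asarray(gray)
    med = ndi.median_filter(gray, footprint=_disk_footprint(radius), mode="reflect")
    if bright:
        deviant = gray.astype(int) - med.astype(int) > threshold
    else:
        deviant = med.astype(int) - gray.astype(int) > threshold
    return np.where(deviant, med, gray)


def clean_mask(mask: BinaryMask, radius: int = 6, threshold: int = 50) -> BinaryMask:
    """Two-pass outlier removal on the 0/255 rendering of a binary mask.

    For a binary image the circular-median filter reduces to a majority
    vote over the neighborhood (the footprint has an odd pixel count), and a
    pixel "deviates by more than ``threshold``" exactly when it disagrees
    with that majority (deviation 255) and ``threshold`` < 255.  Pass 1
    removes bright (true) outliers, pass 2 dark (false) ones, recomputing
    the neighborhood majority in between.
    """
    if radius < 1:
        raise ValueError("radius must be >= 1")
    grid = mask.grid
    if threshold >= 255 or not grid.any():
        return BinaryMask(grid=grid.copy(), roi_mask=mask.roi_mask)
    fp = _disk_footprint(radius).astype(np.int32)
    half = fp.sum() // 2  # footprint count is odd, so no ties

    counts = ndi.convolve(grid.astype(np.int32), fp, mode="reflect")
    majority = counts > half
    out = np.where(grid & ~majority, False, grid)  # demote bright outliers

    counts = ndi.convolve(out.astype(np.int32), fp, mode="reflect")
    majority = counts > half
    out = np.where(~out & majority, True, out)  # promote dark outliers

    out &= mask.roi_mask
    return BinaryMask(grid=out, roi_mask=mask.roi_mask)


def fill_holes(mask: BinaryMask) -> BinaryMask:
    """Fill false regions not connected to the ROI border.

    Background regions that can reach the abdomen outline (and through it
    the frame border) are kept; fully enclosed gaps become spot pixels.
    """
    filled = ndi.binary_fill_holes(mask.grid)
    return BinaryMask(grid=filled & mask.roi_mask, roi_mask=mask.roi_mask)


def _component_contour(region_mask: np.ndarray, origin_rc: tuple[int, int]) -> np.ndarray:
    padded = np.pad(region_mask.astype(float), 1)
    contours = find_contours(padded, 0.5)
    contour = max(contours, key=len)
    ys = contour[:, 0] - 1 + origin_rc[0]
    xs = contour[:, 1] - 1 + origin_rc[1]
    return np.column_stack([xs, ys])


def label_spots(mask: BinaryMask, params: SegmentationParams | None = None) -> LabeledSpots:
    """Label connected components of a cleaned mask as spots.

    Components smaller than ``params.min_spot_area`` are discarded; the
    survivors are relabeled 1..n in scan order with ordered boundary
    contours (sub-pixel, via marching squares at level 0.5) and pixel-mean
    centroids.  Ta is the ROI pixel count.
    """
    params = params or SegmentationParams()
    structure = np.ones((3, 3), dtype=bool) if params.connectivity == 8 else ndi.generate_binary_structure(2, 1)
    raw_labels, _ = ndi.label(mask.grid, structure=structure)
    components: list[SpotComponent] = []
    labels = np.zeros_like(raw_labels)
    next_label = 1
    for region in regionprops(raw_labels):
        if region.area < params.min_spot_area:
            continue
        minr, minc, maxr, maxc = region.bbox
        sub = raw_labels[minr:maxr, minc:maxc] == region.label
        contour = _component_contour(sub, (minr, minc))
        cy, cx = region.centroid
        labels[raw_labels == region.label] = next_label
        components.append(
            SpotComponent(
                label=next_label,
                pixel_count=int(region.area),
                contour=contour,
                centroid=(float(cx), float(cy)),
            )
        )
        next_label += 1
    if not components:
        raise SegmentationError(
            "no spots detected (QC: check threshold polarity, min_spot_area and image contrast)"
        )
    return LabeledSpots(labels=labels, components=components, Ta=int(mask.roi_mask.sum()))


def segment_image(
    gray: np.ndarray, roi_mask: np.ndarray, params: SegmentationParams | None = None
) -> tuple[LabeledSpots, BinaryMask]:
    """Full segmentation chain: threshold -> binarize -> clean -> fill -> label."""
    params = params or SegmentationParams()
    if params.threshold_method == "fixed":
        if params.fixed_threshold is None:
            raise ValueError("fixed threshold_method requires fixed_threshold")
        thr = int(params.fixed_threshold)
    else:
        thr = minimum_auto_threshold(gray, roi_mask)
    mask = binarize_spots(gray, thr, roi_mask)
    mask = clean_mask(mask, radius=params.outlier_radius, threshold=params.outlier_threshold)
    mask = fill_holes(mask)
    spots = label_spots(mask, params)
    return spots, mask
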