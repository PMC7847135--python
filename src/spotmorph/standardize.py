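"""Image standardization: desaturation, level stretching and geometric alignment.

Every specimen is brought into a common canonical frame before any spot is
measured: the thorax–abdomen insertion segment is made horizontal with the
abdomen tip pointing down, the abdomen outline is isotropically rescaled to
a fixed reference width, and its bounding box is translated to the frame
origin.  Because all downstream variables are relativized (areas by the
abdomen area Ta, lengths by sqrt(Ta)), the choice of reference width does
not affect the features beyond rasterization error.

Coordinate conventions: origin top-left, x rightward, y downward, 0-based
pixel indices.  Angles elsewhere in the package are reported in the
mathematical convention (counterclockwise from +x with the y axis flipped),
so 0 deg is the left-right axis and 90 deg the anterior-posterior axis.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from skimage import transform as sktransform
from skimage.draw import polygon2mask

from .io import AbdomenROI

logger = logging.getLogger(__name__)

#: Default canonical abdomen width in pixels.  Any fixed value is equivalent
#: because every feature is relative; 1000 px keeps rasterization error low
#: for full-resolution photographs.
DEFAULT_REF_WIDTH = 1000

#: Canonical frame height as a multiple of the reference width.
FRAME_ASPECT = 1.5


@dataclass
class SimilarityTransformRecord:
    """The similarity transform applied during standardization.

    ``rotation_deg`` is the rotation applied to image coordinates
    (x, y with y down); ``scale`` the isotropic factor; ``translation`` the
    (dx, dy) shift applied after rotation and scaling.
    """

    rotation_deg: float
    scale: float
    translation: tuple[float, float]

    def to_dict(self) -> dict:
        return {
            "rotation_deg": float(self.rotation_deg),
            "scale": float(self.scale),
            "translation": [float(self.translation[0]), float(self.translation[1])],
        }

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map (n, 2) source (x, y) points into the canonical frame."""
        pts = np.asarray(points, dtype=float)
        phi = math.radians(self.rotation_deg)
        rot = np.array([[math.cos(phi), -math.sin(phi)], [math.sin(phi), math.cos(phi)]])
        return self.scale * pts @ rot.T + np.asarray(self.translation)


@dataclass
class StandardizedImage:
    """Aligned, rescaled grayscale abdomen image in the canonical frame."""

    pixels: np.ndarray  # (h, w) uint8, 0 outside the abdomen
    transform: SimilarityTransformRecord
    roi_mask: np.ndarray  # bool, abdomen interior
    ref_width: int
    source_id: str = ""
    roi: AbdomenROI | None = None  # landmarks mapped into the canonical frame


def desaturate(pixels: np.ndarray) -> np.ndarray:
    """Convert a 1- or 3-channel 8-bit image to grayscale.

    Channels are combined with the unweighted mean rounded half-up (the
    default 8-bit conversion of common particle-analysis software); an
    already-grayscale image is returned unchanged.
    """
    arr = np.asarray(pixels)
    if arr.ndim == 2:
        return arr
    if arr.ndim == 3 and arr.shape[2] == 1:
        return arr[:, :, 0]
    if arr.ndim == 3 and arr.shape[2] == 3:
        mean = arr.astype(np.float64).mean(axis=2)
        return np.floor(mean + 0.5).astype(np.uint8)
    raise ValueError(
        f"unsupported channel count {arr.shape[2] if arr.ndim == 3 else '?'}: "
        "expected 1 (grayscale) or 3 (RGB); flatten alpha before processing"
    )


def luma_desaturate(pixels: np.ndarray) -> np.ndarray:
    """Alternative desaturation using Rec. 601 luma weights."""
    arr = np.asarray(pixels)
    if arr.ndim == 2:
        return arr
    w = np.array([0.299, 0.587, 0.114])
    return np.floor(arr[..., :3].astype(np.float64) @ w + 0.5).astype(np.uint8)


def stretch_levels(
    gray: np.ndarray,
    low_q: float = 0.25,
    high_q: float = 0.75,
    roi_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Contrast-stretch to the central histogram band.

    Intensities at or below the ``low_q`` quantile map to 0, at or above the
    ``high_q`` quantile to 255, linearly in between (a monotone mapping).
    Quantiles are computed over ``roi_mask`` when given, otherwise over the
    whole frame.  A constant image is returned unchanged with a warning.
    """
    if not 0 <= low_q < high_q <= 1:
        raise ValueError("quantiles must satisfy 0 <= low_q < high_q <= 1")
    gray = np.asarray(gray)
    sample = gray[roi_mask] if roi_mask is not None else gray
    lo = float(np.quantile(sample, low_q))
    hi = float(np.quantile(sample, high_q))
    if hi <= lo:
        logger.warning("stretch_levels: constant histogram band (lo == hi); image unchanged")
        return gray.copy()
    out = (gray.astype(np.float64) - lo) * (255.0 / (hi - lo))
    return np.clip(np.floor(out + 0.5), 0, 255).astype(np.uint8)


def polygon_mask(shape: tuple[int, int], polygon_xy: np.ndarray) -> np.ndarray:
    # polygon2mask expects (row, col) vertices
    return polygon2mask(shape, np.asarray(polygon_xy, dtype=float)[:, ::-1])


def standardize_geometry(
    gray: np.ndarray,
    roi: AbdomenROI,
    ref_width: int = DEFAULT_REF_WIDTH,
    frame_aspect: float = FRAME_ASPECT,
) -> StandardizedImage:
    """Rotate, rescale and translate an abdomen into the canonical frame.

    The rotation makes the left->right insertion segment horizontal with the
    posterior tip below it (flipping 180 deg if needed); the isotropic scale
    makes the abdomen polygon's horizontal extent equal ``ref_width``; the
    translation puts the polygon bounding box's upper-left corner at the
    origin.  Grayscale pixels are interpolated bilinearly, the abdomen mask
    with nearest neighbors, and everything outside the polygon is set to 0.
    """
    if ref_width <= 0:
        raise ValueError("ref_width must be positive")
    gray = np.asarray(gray)
    left = np.asarray(roi.left_insertion, dtype=float)
    right = np.asarray(roi.right_insertion, dtype=float)
    post = np.asarray(roi.posterior, dtype=float)
    v = right - left
    if np.hypot(*v) < 1e-9:
        raise ValueError("degenerate ROI: insertion points coincide")

    # rotation that maps the insertion segment onto +x
    phi = -math.atan2(v[1], v[0])

    def _rot(points: np.ndarray, angle: float) -> np.ndarray:
        c, s = math.cos(angle), math.sin(angle)
        rotm = np.array([[c, -s], [s, c]])
        return np.asarray(points, dtype=float) @ rotm.T

    mid = 0.5 * (left + right)
    if _rot(post - mid, phi)[1] < 0:  # posterior above insertion line -> flip
        logger.info("standardize_geometry: posterior above insertion line; flipping 180 deg")
        phi += math.pi

    poly_rot = _rot(roi.polygon, phi)
    extent = float(poly_rot[:, 0].max() - poly_rot[:, 0].min())
    if extent <= 0:
        raise ValueError("degenerate ROI polygon: zero horizontal extent")
    scale = ref_width / extent
    bbox_ul = scale * poly_rot.min(axis=0)
    translation = (-bbox_ul[0], -bbox_ul[1])

    record = SimilarityTransformRecord(
        rotation_deg=math.degrees(phi), scale=scale, translation=tuple(translation)
    )

    out_h = int(round(frame_aspect * ref_width))
    out_w = int(ref_width)
    poly_canon = record.apply(roi.polygon)
    if poly_canon[:, 1].max() > out_h:
        logger.warning(
            "standardize_geometry: abdomen height %.0f px exceeds canonical frame height %d; clipped",
            poly_canon[:, 1].max(),
            out_h,
        )

    tform = sktransform.SimilarityTransform(
        scale=scale, rotation=phi, translation=translation
    )
    warped = sktransform.warp(
        gray.astype(np.float64),
        inverse_map=tform.inverse,
        output_shape=(out_h, out_w),
        order=1,
        cval=0.0,
        preserve_range=True,
    )
    mask = polygon_mask((out_h, out_w), poly_canon)
    pixels = np.floor(warped + 0.5).astype(np.uint8)
    pixels[~mask] = 0

    roi_canon = AbdomenROI(
        polygon=poly_canon,
        left_insertion=tuple(record.apply(left[None, :])[0]),
        right_insertion=tuple(record.apply(right[None, :])[0]),
        posterior=tuple(record.apply(post[None, :])[0]),
    )
    return StandardizedImage(
        pixels=pixels,
        transform=record,
        roi_mask=mask,
        ref_width=int(ref_width),
        roi=roi_canon,
    )


def auto_roi(gray: np.ndarray) -> AbdomenROI:
    """Low-fidelity automatic ROI: convex hull of the largest dark region.

    Provided as a fallback when no manual annotation exists.  Landmarks are
    placed heuristically (insertions at 20% depth of the hull, posterior at
    its lowest point); manual annotations should be preferred.
    """
    from scipy import ndimage as ndi
    from skimage.morphology import convex_hull_image

    gray = np.asarray(gray)
    dark = gray < np.quantile(gray, 0.5)
    labels, n = ndi.label(dark)
    if n == 0:
        raise ValueError("auto_roi: no dark region found")
    sizes = ndi.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    comp = labels == (1 + int(np.argmax(sizes)))
    hull = convex_hull_image(comp)
    from skimage.measure import find_contours

    contour = max(find_contours(hull.astype(float), 0.5), key=len)
    poly = contour[:: max(1, len(contour) // 64), ::-1]  # (x, y), subsampled
    ys = poly[:, 1]
    y_ins = ys.min() + 0.2 * (ys.max() - ys.min())
    band = poly[np.abs(ys - y_ins) < 0.05 * (ys.max() - ys.min() + 1)]
    if len(band) < 2:
        band = poly
    left = band[np.argmin(band[:, 0])]
    right = band[np.argmax(band[:, 0])]
    posterior = poly[np.argmax(ys)]
    return AbdomenROI(
        polygon=poly,
        left_insertion=tuple(left),
        right_insertion=tuple(right),
        posterior=tuple(posterior),
    )
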