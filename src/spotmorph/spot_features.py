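"""Spot numbering and the primary/derived pattern variables.

Primary variables per spot (all measured in the canonical frame):

- ``Ra``    — spot area as a percentage of the abdomen area Ta,
- ``MaxFd`` — maximum Feret diameter (largest pairwise contour distance),
  relative to sqrt(Ta),
- ``MinFd`` — minimum Feret diameter (smallest caliper width over
  orientations), relative to sqrt(Ta),
- ``Fa``    — orientation of the MaxFd segment in [0, 180), folded into
  [0, 90] so that left- and right-side inclinations are comparable,
- ``Ar``    — aspect ratio MinFd/MaxFd in (0, 1].

The two spots on the midline are numbered 1 and 2 (anterior first); spots
along the connexivum get consecutive odd numbers on the left and even
numbers on the right, each side anterior to posterior.  Per-specimen
derived variables average the primaries over the central and lateral spot
classes, add the total Ra, the central:lateral mean-Ra ratio, and the sum
of centroid distances between central and lateral spots measured after a
generalized Procrustes registration of the full centroid configurations.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError

from .segmentation import LabeledSpots

logger = logging.getLogger(__name__)


class QCError(ValueError):
    """Raised when a specimen fails a structural quality check."""


@dataclass
class SpotRecord:
    """One numbered spot with its primary metrics."""

    number: int
    cls: str  # "central" | "lateral"
    side: str  # "left" | "right" | "center"
    area_px: int
    centroid: tuple[float, float]
    contour: np.ndarray | None = None
    Ra: float | None = None  # percent of Ta
    MaxFd: float | None = None  # px / sqrt(Ta)
    MinFd: float | None = None  # px / sqrt(Ta)
    Fa: float | None = None  # degrees in [0, 180)
    Fa_folded: float | None = None  # degrees in [0, 90]
    Ar: float | None = None  # MinFd / MaxFd


@dataclass
class CentroidConfiguration:
    points: np.ndarray  # (k, 2), ordered by spot number
    specimen_id: str = ""

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)


@dataclass
class SpecimenSpots:
    """All numbered spots of one specimen, ready for feature derivation."""

    specimen_id: str
    group: str
    Ta: int
    records: list[SpotRecord] = field(default_factory=list)


#: Derived feature columns, in table order, with their units.
FEATURE_UNITS = {
    "total_Ra": "% of Ta",
    "mean_Ra_central": "% of Ta",
    "mean_Ra_lateral": "% of Ta",
    "central_lateral_ratio": "dimensionless",
    "mean_MaxFd_central": "px/sqrt(Ta)",
    "mean_MaxFd_lateral": "px/sqrt(Ta)",
    "mean_Ar_central": "dimensionless",
    "mean_Ar_lateral": "dimensionless",
    "mean_Fa_central": "degrees [0,90]",
    "mean_Fa_lateral": "degrees [0,90]",
    "sum_central_lateral_dist": "unit-centroid-size lengths",
}
FEATURE_COLUMNS = list(FEATURE_UNITS)


# ---------------------------------------------------------------------------
# numbering


def classify_and_number(
    spots: LabeledSpots,
    roi_mask: np.ndarray | None = None,
    central_band: float = 0.15,
    midline: float | None = None,
    body_width: float | None = None,
) -> list[SpotRecord]:
    """Assign the central-1/2, left-odd, right-even numbering.

    A spot whose centroid lies within ``central_band`` * body width of the
    vertical midline is central; the two central spots are numbered 1 and 2
    anterior-first.  Remaining spots are lateral; the left side receives
    3, 5, 7, ... and the right side 4, 6, 8, ..., each ordered by
    increasing y (ties broken by increasing x).
    """
    if not spots.components:
        raise QCError("no spots to number")
    if midline is None or body_width is None:
        if roi_mask is None:
            raise ValueError("either roi_mask or (midline, body_width) is required")
        cols = np.flatnonzero(np.asarray(roi_mask, dtype=bool).any(axis=0))
        body_width = float(cols.max() - cols.min() + 1)
        midline = float(0.5 * (cols.min() + cols.max()))

    centrals, laterals = [], []
    for comp in spots.components:
        x, y = comp.centroid
        if abs(x - midline) < central_band * body_width:
            centrals.append(comp)
        else:
            laterals.append(comp)
    if len(centrals) > 2:
        raise QCError(f"ambiguous central spots: {len(centrals)} candidates in the midline band")
    if len(centrals) == 0:
        logger.warning("no central spots found; central means will be missing")

    def _order(comps):
        return sorted(comps, key=lambda c: (c.centroid[1], c.centroid[0]))

    records: list[SpotRecord] = []
    for i, comp in enumerate(_order(centrals)):
        records.append(
            SpotRecord(
                number=i + 1,
                cls="central",
                side="center",
                area_px=comp.pixel_count,
                centroid=comp.centroid,
                contour=comp.contour,
            )
        )
    left = _order([c for c in laterals if c.centroid[0] < midline])
    right = _order([c for c in laterals if c.centroid[0] >= midline])
    for i, comp in enumerate(left):
        records.append(
            SpotRecord(
                number=3 + 2 * i,
                cls="lateral",
                side="left",
                area_px=comp.pixel_count,
                centroid=comp.centroid,
                contour=comp.contour,
            )
        )
    for i, comp in enumerate(right):
        records.append(
            SpotRecord(
                number=4 + 2 * i,
                cls="lateral",
                side="right",
                area_px=comp.pixel_count,
                centroid=comp.centroid,
                contour=comp.contour,
            )
        )
    return sorted(records, key=lambda r: r.number)


# ---------------------------------------------------------------------------
# Feret geometry


def _hull_points(points: np.ndarray) -> np.ndarray:
    pts = np.unique(np.asarray(points, dtype=float), axis=0)
    if len(pts) < 3:
        return pts
    try:
        hull = ConvexHull(pts)
    except QhullError:  # collinear input
        return pts
    return pts[hull.vertices]


def _segment_angle(dx: float, dy: float) -> float:
    """Orientation of a segment in degrees [0, 180), y-up convention."""
    ang = math.degrees(math.atan2(-dy, dx)) % 180.0
    return ang


def max_feret(contour: np.ndarray) -> tuple[float, float]:
    """Maximum Feret diameter and its angle.

    Returns the largest pairwise Euclidean distance between contour points
    (evaluated on the convex hull, which attains the maximum) and the
    orientation of the achieving segment in degrees [0, 180); among exactly
    tied pairs the smallest angle is reported.
    """
    pts = _hull_points(contour)
    if len(pts) < 2:
        raise ValueError("degenerate contour: fewer than 2 distinct points")
    diff = pts[:, None, :] - pts[None, :, :]
    d2 = np.einsum("ijk,ijk->ij", diff, diff)
    best = d2.max()
    ii, jj = np.nonzero(d2 == best)
    angles = [
        _segment_angle(pts[j, 0] - pts[i, 0], pts[j, 1] - pts[i, 1])
        for i, j in zip(ii, jj)
        if i < j
    ]
    return float(math.sqrt(best)), float(min(angles))


def min_feret(contour: np.ndarray) -> float:
    """Minimum Feret diameter (minimum caliper width).

    The minimum over convex-hull edge orientations of the hull's projection
    width perpendicular to that edge.  Collinear input returns 0 with a
    warning.
    """
    pts = _hull_points(contour)
    if len(pts) < 2:
        raise ValueError("degenerate contour: fewer than 2 distinct points")
    if len(pts) == 2 or _collinear(pts):
        logger.warning("min_feret: collinear contour, width 0")
        return 0.0
    best = math.inf
    n = len(pts)
    for i in range(n):
        edge = pts[(i + 1) % n] - pts[i]
        norm = math.hypot(*edge)
        if norm < 1e-12:
            continue
        normal = np.array([-edge[1], edge[0]]) / norm
        proj = pts @ normal
        best = min(best, float(proj.max() - proj.min()))
    return best


def _collinear(pts: np.ndarray, tol: float = 1e-9) -> bool:
    if len(pts) < 3:
        return True
    d = pts - pts[0]
    ref = d[np.argmax(np.einsum("ij,ij->i", d, d))]
    cross = d[:, 0] * ref[1] - d[:, 1] * ref[0]
    return bool(np.all(np.abs(cross) < tol * max(1.0, np.abs(ref).max())))


def fold_angle(theta: float) -> float:
    """Fold an orientation into [0, 90] degrees (mirror left/right quadrants)."""
    theta = theta % 180.0
    return theta if theta <= 90.0 else 180.0 - theta


def spot_metrics(record: SpotRecord, Ta: float) -> SpotRecord:
    """Fill in Ra, relative Feret diameters, angles and aspect ratio in place."""
    if Ta <= 0:
        raise ValueError("Ta must be positive")
    if record.contour is None:
        raise ValueError("spot record has no contour")
    length, angle = max_feret(record.contour)
    width = min_feret(record.contour)
    sqrt_ta = math.sqrt(Ta)
    record.Ra = 100.0 * record.area_px / Ta
    record.MaxFd = length / sqrt_ta
    record.MinFd = width / sqrt_ta
    record.Fa = angle
    record.Fa_folded = fold_angle(angle)
    record.Ar = width / length if length > 0 else float("nan")
    return record


# ---------------------------------------------------------------------------
# Procrustes registration of centroid configurations


@dataclass
class GPAResult:
    aligned: list[CentroidConfiguration]
    mean_shape: np.ndarray
    iterations: int


def _normalize(points: np.ndarray) -> np.ndarray:
    centered = points - points.mean(axis=0)
    size = np.linalg.norm(centered)
    if size < 1e-12:
        raise ValueError("degenerate configuration: zero centroid size")
    return centered / size


def _rotate_onto(x: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Optimal rotation (no reflection) of ``x`` onto ``ref``."""
    u, _, vt = np.linalg.svd(x.T @ ref)
    r = u @ vt
    if np.linalg.det(r) < 0:
        u[:, -1] *= -1
        r = u @ vt
    return x @ r


def gpa(configs: list[CentroidConfiguration], tol: float = 1e-8, max_iter: int = 1000) -> GPAResult:
    """Generalized Procrustes analysis of centroid configurations.

    Each configuration is translated to the origin and scaled to unit
    centroid size, then iteratively rotated to the evolving mean shape
    (rotation only, no reflection) until the mean changes by less than
    ``tol`` in Frobenius norm.
    """
    if len(configs) < 2:
        raise ValueError("gpa requires at least 2 configurations")
    counts = [len(c.points) for c in configs]
    if len(set(counts)) != 1:
        modal = max(set(counts), key=counts.count)
        offenders = [c.specimen_id for c in configs if len(c.points) != modal]
        raise ValueError(f"mismatched landmark counts across specimens: {offenders}")
    shapes = [_normalize(c.points) for c in configs]
    mean = shapes[0]
    iterations = 0
    for iterations in range(1, max_iter + 1):
        shapes = [_rotate_onto(s, mean) for s in shapes]
        new_mean = _normalize(np.mean(shapes, axis=0))
        if np.linalg.norm(new_mean - mean) < tol:
            mean = new_mean
            break
        mean = new_mean
    aligned = [
        CentroidConfiguration(points=s, specimen_id=c.specimen_id)
        for s, c in zip(shapes, configs)
    ]
    return GPAResult(aligned=aligned, mean_shape=mean, iterations=iterations)


def sum_central_lateral_distances(
    points: np.ndarray, classes: list[str]
) -> float:
    """Sum of Euclidean distances over all (central, lateral) centroid pairs."""
    pts = np.asarray(points, dtype=float)
    central = pts[[i for i, c in enumerate(classes) if c == "central"]]
    lateral = pts[[i for i, c in enumerate(classes) if c == "lateral"]]
    if len(central) == 0:
        raise ValueError("no central points")
    if len(lateral) == 0:
        raise ValueError("no lateral points")
    diff = central[:, None, :] - lateral[None, :, :]
    return float(np.sqrt(np.einsum("ijk,ijk->ij", diff, diff)).sum())


# ---------------------------------------------------------------------------
# feature table


def _mean_or_nan(values: list[float]) -> float:
    return float(np.mean(values)) if values else float("nan")


def build_feature_table(
    specimens: list[SpecimenSpots],
    run_gpa: bool = True,
) -> pd.DataFrame:
    """Derive the per-specimen feature vector table.

    One row per specimen: class means of the primary variables (angle means
    taken on folded angles), the total Ra, the central:lateral mean-Ra
    ratio, and the summed central-lateral centroid distances in the
    Procrustes-aligned frame.  Specimens whose spot count differs from the
    modal count are excluded from the Procrustes step only (distance
    recorded as missing); their remaining features are kept.
    """
    if not specimens:
        raise ValueError("empty specimen set")
    ids = [s.specimen_id for s in specimens]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicated specimen ids")

    rows = []
    for spec in specimens:
        cen = [r for r in spec.records if r.cls == "central"]
        lat = [r for r in spec.records if r.cls == "lateral"]
        mean_ra_c = _mean_or_nan([r.Ra for r in cen])
        mean_ra_l = _mean_or_nan([r.Ra for r in lat])
        rows.append(
            {
                "specimen_id": spec.specimen_id,
                "group": spec.group,
                "Ta": spec.Ta,
                "n_central": len(cen),
                "n_lateral": len(lat),
                "total_Ra": float(sum(r.Ra for r in spec.records)),
                "mean_Ra_central": mean_ra_c,
                "mean_Ra_lateral": mean_ra_l,
                "central_lateral_ratio": mean_ra_c / mean_ra_l if lat and cen else float("nan"),
                "mean_MaxFd_central": _mean_or_nan([r.MaxFd for r in cen]),
                "mean_MaxFd_lateral": _mean_or_nan([r.MaxFd for r in lat]),
                "mean_Ar_central": _mean_or_nan([r.Ar for r in cen]),
                "mean_Ar_lateral": _mean_or_nan([r.Ar for r in lat]),
                "mean_Fa_central": _mean_or_nan([r.Fa_folded for r in cen]),
                "mean_Fa_lateral": _mean_or_nan([r.Fa_folded for r in lat]),
                "sum_central_lateral_dist": float("nan"),
            }
        )
    table = pd.DataFrame(rows).set_index("specimen_id")

    if run_gpa:
        counts = pd.Series([len(s.records) for s in specimens], index=ids)
        modal = int(counts.mode().iloc[0])
        eligible = [s for s in specimens if len(s.records) == modal]
        if len(eligible) >= 2:
            configs = [
                CentroidConfiguration(
                    points=np.array([r.centroid for r in sorted(s.records, key=lambda r: r.number)]),
                    specimen_id=s.specimen_id,
                )
                for s in eligible
            ]
            result = gpa(configs)
            class_order = [
                r.cls for r in sorted(eligible[0].records, key=lambda r: r.number)
            ]
            for cfg in result.aligned:
                try:
                    d = sum_central_lateral_distances(cfg.points, class_order)
                except ValueError:
                    continue
                table.loc[cfg.specimen_id, "sum_central_lateral_dist"] = d
        excluded = sorted(set(ids) - {s.specimen_id for s in eligible})
        if excluded:
            logger.warning(
                "build_feature_table: %d specimen(s) excluded from Procrustes (spot count != %d): %s",
                len(excluded),
                modal,
                excluded,
            )
    return table
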