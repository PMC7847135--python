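"""Synthetic specimen generator with exact ground truth.

Renders archetypal dorsal spot patterns of the three *T. dimidiata*
haplogroups: a dark elliptical abdomen on a light background bearing two
central light spots on the midline and six pairs of lateral spots along the
connexivum, all drawn as ellipses.  The three default archetypes encode the
group contrasts reported for the real material:

* H1 — intermediate total relative spot area (~11% of the abdomen),
  lateral-dominant, with the three anterior lateral pairs tilted forward
  (low folded Feret angles);
* H2 — the largest total relative area (15.6%), with notably larger,
  rounder central spots contributing about as much area as all lateral
  spots together;
* H3 — the smallest total relative area (8.7%), lateral-dominant with
  elongated lateral spots (low aspect ratio).

Each specimen gets per-spot size/position/orientation jitter, a random
similarity pose (rotation/scale/translation), Gaussian intensity noise and
salt-and-pepper speckle; the exact pre-noise spot masks and per-spot truth
(area, centroid, orientation) are emitted alongside the image.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .io import AbdomenROI, RawImage, save_image, save_roi

DEG = math.pi / 180.0


@dataclass
class HaplogroupArchetype:
    """Generative parameters for one haplogroup's spot pattern.

    Lengths are fractions of the abdomen width unless stated; orientations
    are folded Feret angles in degrees (0 = transverse, 90 = longitudinal).
    """

    name: str
    target_total_Ra: float  # percent of abdomen area, specimen-level lognormal jitter
    central_axes: tuple[float, float]  # (major, minor) fractions of abdomen width
    lateral_axes_by_pair: list[tuple[float, float]]
    orientation_mean_by_pair: list[float]  # folded degrees, per lateral pair
    orientation_sd_by_pair: list[float]
    central_orientation_mean: float = 15.0
    central_orientation_sd: float = 8.0
    n_lateral_pairs: int = 6
    central_positions: list[tuple[float, float]] = field(
        default_factory=lambda: [(0.0, -0.20), (0.0, 0.02)]
    )  # (x, y) offsets from abdomen center in width/height fractions
    lateral_y_fracs: list[float] = field(
        default_factory=lambda: [-0.34, -0.21, -0.08, 0.05, 0.18, 0.31]
    )  # y offsets from center as fractions of abdomen height
    lateral_edge_frac: float = 0.78  # lateral x as a fraction of local half-width
    position_jitter: float = 0.012  # sd, fraction of abdomen width
    axis_jitter: float = 0.06  # lognormal sd per axis
    ra_jitter: float = 0.10  # lognormal sd of the specimen-level total Ra
    abdomen_axes: tuple[int, int] = (800, 1120)  # (width, height) px
    body_intensity: float = 60.0
    spot_intensity: float = 205.0
    background_intensity: float = 245.0
    intensity_sd: float = 7.0
    speckle_density: float = 0.005
    fusion_probability: float = 0.0
    rotation_sd_deg: float = 4.0
    scale_jitter: float = 0.06
    translation_jitter: float = 16.0  # px

    def __post_init__(self) -> None:
        if not 0 < self.target_total_Ra < 100:
            raise ValueError("target_total_Ra must be in (0, 100)")
        if self.n_lateral_pairs < 1:
            raise ValueError("n_lateral_pairs must be >= 1")
        for seq in (self.lateral_axes_by_pair, self.orientation_mean_by_pair, self.orientation_sd_by_pair, self.lateral_y_fracs):
            if len(seq) != self.n_lateral_pairs:
                raise ValueError("per-pair parameter lists must have n_lateral_pairs entries")


@dataclass
class TruthSpot:
    number: int
    cls: str
    side: str
    area_px: int
    centroid: tuple[float, float]
    orientation_folded: float  # degrees, canonical pose


@dataclass
class SyntheticSpecimen:
    image: RawImage
    roi: AbdomenROI
    truth_mask: np.ndarray  # bool, pre-noise spot pixels
    truth_spots: list[TruthSpot]
    group: str
    seed: int
    rotation_deg: float
    scale: float


def default_archetypes() -> tuple[HaplogroupArchetype, HaplogroupArchetype, HaplogroupArchetype]:
    """The three default haplogroup archetypes (H1, H2, H3)."""
    h1 = HaplogroupArchetype(
        name="H1",
        target_total_Ra=11.0,
        central_axes=(0.160, 0.112),
        lateral_axes_by_pair=[(0.133, 0.073)] * 6,
        orientation_mean_by_pair=[28.0, 30.0, 32.0, 62.0, 68.0, 72.0],
        orientation_sd_by_pair=[5.0, 5.0, 5.0, 11.0, 11.0, 11.0],
    )
    h2 = HaplogroupArchetype(
        name="H2",
        target_total_Ra=15.6,
        central_axes=(0.265, 0.218),
        lateral_axes_by_pair=[(0.119, 0.0774)] * 6,
        orientation_mean_by_pair=[60.0, 65.0, 70.0, 70.0, 72.0, 75.0],
        orientation_sd_by_pair=[13.0] * 6,
        central_orientation_mean=20.0,
        central_orientation_sd=10.0,
    )
    h3 = HaplogroupArchetype(
        name="H3",
        target_total_Ra=8.7,
        central_axes=(0.140, 0.100),
        lateral_axes_by_pair=[(0.161, 0.063)] * 6,
        orientation_mean_by_pair=[58.0, 64.0, 70.0, 72.0, 74.0, 76.0],
        orientation_sd_by_pair=[13.0] * 6,
    )
    return h1, h2, h3


def _rot_matrix(deg: float) -> np.ndarray:
    c, s = math.cos(deg * DEG), math.sin(deg * DEG)
    return np.array([[c, -s], [s, c]])


def _ellipse_mask(
    shape: tuple[int, int],
    center: np.ndarray,
    major_dir: np.ndarray,
    semi_major: float,
    semi_minor: float,
) -> np.ndarray:
    """Boolean mask of a rotated ellipse (pixel centers inside)."""
    h, w = shape
    cx, cy = center
    r = int(math.ceil(max(semi_major, semi_minor))) + 2
    x0, x1 = max(0, int(cx) - r), min(w, int(cx) + r + 1)
    y0, y1 = max(0, int(cy) - r), min(h, int(cy) + r + 1)
    out = np.zeros(shape, dtype=bool)
    if x0 >= x1 or y0 >= y1:
        return out
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dx = xx - cx
    dy = yy - cy
    u = major_dir
    v = np.array([-u[1], u[0]])
    pu = dx * u[0] + dy * u[1]
    pv = dx * v[0] + dy * v[1]
    out[y0:y1, x0:x1] = (pu / semi_major) ** 2 + (pv / semi_minor) ** 2 <= 1.0
    return out


def _fold(deg: float) -> float:
    deg = deg % 180.0
    return deg if deg <= 90.0 else 180.0 - deg


def generate_specimen(
    arch: HaplogroupArchetype,
    seed: int,
    rotation_deg: float | None = None,
    scale: float | None = None,
) -> SyntheticSpecimen:
    """Render one specimen; deterministic given (archetype, seed).

    ``rotation_deg``/``scale`` override the random pose (useful for
    geometric round-trip checks).  Rotation follows the image-coordinate
    convention used by the standardization step, so standardizing a
    specimen rendered with rotation r recovers a transform rotation of -r.
    """
    rng = np.random.default_rng(seed)
    w_abd, h_abd = arch.abdomen_axes
    if rotation_deg is None:
        rotation_deg = float(rng.normal(0.0, arch.rotation_sd_deg))
    if scale is None:
        scale = float(1.0 + rng.uniform(-arch.scale_jitter, arch.scale_jitter))
    rot = _rot_matrix(rotation_deg)

    side_px = int(math.ceil(max(w_abd, h_abd) * scale * 1.2)) + 40
    shape = (side_px, side_px)
    center = np.array([side_px / 2.0, side_px / 2.0]) + rng.uniform(
        -arch.translation_jitter, arch.translation_jitter, size=2
    )

    # --- spot geometry in the canonical (unrotated, unit-scale) pose -------
    target_ra = arch.target_total_Ra * float(np.exp(rng.normal(0.0, arch.ra_jitter)))
    target_ra = min(target_ra, 60.0)

    spots = []  # (number, cls, side, offset(x, y) px, axes(major, minor) px, folded deg)
    for i, (fx, fy) in enumerate(arch.central_positions[:2]):
        ang = _fold(float(rng.normal(arch.central_orientation_mean, arch.central_orientation_sd)))
        a = arch.central_axes[0] * w_abd * float(np.exp(rng.normal(0, arch.axis_jitter)))
        b = arch.central_axes[1] * w_abd * float(np.exp(rng.normal(0, arch.axis_jitter)))
        jx, jy = rng.normal(0.0, arch.position_jitter * w_abd, size=2)
        offset = np.array([fx * w_abd + jx, fy * h_abd + jy])
        spots.append([i + 1, "central", "center", offset, [a, b], ang, 0.0])
    for pair in range(arch.n_lateral_pairs):
        fy = arch.lateral_y_fracs[pair]
        for side, sign in (("left", -1.0), ("right", 1.0)):
            ang = _fold(float(rng.normal(arch.orientation_mean_by_pair[pair], arch.orientation_sd_by_pair[pair])))
            a0, b0 = arch.lateral_axes_by_pair[pair]
            a = a0 * w_abd * float(np.exp(rng.normal(0, arch.axis_jitter)))
            b = b0 * w_abd * float(np.exp(rng.normal(0, arch.axis_jitter)))
            jx, jy = rng.normal(0.0, arch.position_jitter * w_abd, size=2)
            # x offset is clamped after size rescaling; only the jitter so far
            offset = np.array([jx, fy * h_abd + jy])
            number = (3 if side == "left" else 4) + 2 * pair
            spots.append([number, "lateral", side, offset, [a, b], ang, sign])

    # rescale all spot axes so the expected total area hits the target Ra
    abdomen_area = math.pi / 4.0 * w_abd * h_abd
    nominal = sum(math.pi / 4.0 * s[4][0] * s[4][1] for s in spots)
    k = math.sqrt(target_ra / 100.0 * abdomen_area / nominal)
    for s in spots:
        s[4][0] *= k
        s[4][1] *= k

    # place lateral spots along the connexivum, pulled inward when needed so
    # the whole ellipse stays inside the abdomen (keeps orientation truth valid)
    for s in spots:
        if s[1] != "lateral":
            continue
        sign = s[6]
        y_off = s[3][1]
        u = y_off / (0.5 * h_abd)
        half_width = 0.5 * w_abd * math.sqrt(max(0.0, 1.0 - min(1.0, u * u)))
        semi_major = 0.5 * s[4][0]
        x_mag = min(arch.lateral_edge_frac * half_width, half_width - semi_major - 4.0)
        s[3][0] += sign * max(x_mag, 0.0)

    # --- rasterize ----------------------------------------------------------
    abdomen = _ellipse_mask(
        shape, center, rot @ np.array([1.0, 0.0]), 0.5 * w_abd * scale, 0.5 * h_abd * scale
    )

    truth_spots: list[TruthSpot] = []
    union = np.zeros(shape, dtype=bool)
    allow_fusion = rng.random() < arch.fusion_probability
    for attempt in range(100):
        union[:] = False
        masks = []
        overlap = False
        for number, cls, side, offset, (a, b), ang, _sign in spots:
            # folded angle -> actual major-axis direction: mirror on the left
            theta = ang if side != "left" else 180.0 - ang
            direction_canon = np.array([math.cos(theta * DEG), -math.sin(theta * DEG)])
            direction = rot @ direction_canon
            pos = center + rot @ (np.asarray(offset) * scale)
            m = _ellipse_mask(shape, pos, direction, 0.5 * a * scale, 0.5 * b * scale)
            m &= abdomen
            if (m & union).any():
                overlap = True
            union |= m
            masks.append((number, cls, side, ang, m))
        if not overlap or allow_fusion:
            break
        # re-jitter positions and retry
        for s in spots:
            s[3] = s[3] + rng.normal(0.0, 0.01 * w_abd, size=2)
    else:
        raise RuntimeError("could not place spots without overlap after 100 attempts")

    for number, cls, side, ang, m in masks:
        ys, xs = np.nonzero(m)
        if len(xs) == 0:
            raise RuntimeError(f"spot {number} fell entirely outside the abdomen")
        truth_spots.append(
            TruthSpot(
                number=number,
                cls=cls,
                side=side,
                area_px=int(m.sum()),
                centroid=(float(xs.mean()), float(ys.mean())),
                orientation_folded=float(ang),
            )
        )

    img = np.full(shape, arch.background_intensity, dtype=np.float64)
    img[abdomen] = arch.body_intensity
    img[union] = arch.spot_intensity
    if arch.intensity_sd > 0:
        img += rng.normal(0.0, arch.intensity_sd, size=shape)
    if arch.speckle_density > 0:
        speckle = (rng.random(shape) < arch.speckle_density) & abdomen
        salt = rng.random(shape) < 0.5
        img[speckle & salt] = 255.0
        img[speckle & ~salt] = 0.0
    pixels = np.clip(np.floor(img + 0.5), 0, 255).astype(np.uint8)

    # --- ROI annotation ------------------------------------------------------
    t = np.linspace(0.0, 2.0 * math.pi, 128, endpoint=False)
    ring = np.column_stack([0.5 * w_abd * np.cos(t), 0.5 * h_abd * np.sin(t)])
    polygon = (scale * ring) @ rot.T + center
    roi = AbdomenROI(
        polygon=polygon,
        left_insertion=tuple(center + rot @ (scale * np.array([-0.46 * w_abd, -0.32 * h_abd]))),
        right_insertion=tuple(center + rot @ (scale * np.array([0.46 * w_abd, -0.32 * h_abd]))),
        posterior=tuple(center + rot @ (scale * np.array([0.0, 0.5 * h_abd]))),
    )
    truth_spots.sort(key=lambda s: s.number)
    return SyntheticSpecimen(
        image=RawImage(pixels=pixels, source_id=f"{arch.name}_{seed:08d}"),
        roi=roi,
        truth_mask=union,
        truth_spots=truth_spots,
        group=arch.name,
        seed=seed,
        rotation_deg=float(rotation_deg),
        scale=float(scale),
    )


def generate_dataset(
    archetypes=None,
    n_per_group=(39, 23, 39),
    master_seed: int = 0,
    out_dir: str | Path | None = None,
    force: bool = False,
) -> list[SyntheticSpecimen]:
    """Generate a labeled dataset; per-specimen seeds derive from ``master_seed``.

    The default sample sizes (39/23/39) replicate the three-group design of
    the source material.  When ``out_dir`` is given, writes per-specimen
    PNG images and ROI JSONs plus ``labels.csv`` and ``truth.csv``.
    """
    archetypes = list(archetypes) if archetypes is not None else list(default_archetypes())
    if len(n_per_group) != len(archetypes):
        raise ValueError("n_per_group must match the number of archetypes")
    ss = np.random.SeedSequence(master_seed)
    specimens: list[SyntheticSpecimen] = []
    counter = 0
    children = ss.spawn(int(sum(n_per_group)))
    for arch, n in zip(archetypes, n_per_group):
        for i in range(n):
            seed = int(children[counter].generate_state(1)[0] % (2**31))
            spec = generate_specimen(arch, seed=seed)
            spec.image.source_id = f"{arch.name}_{i:04d}"
            specimens.append(spec)
            counter += 1
    if out_dir is not None:
        out = Path(out_dir)
        if out.exists() and any(out.iterdir()) and not force:
            raise FileExistsError(f"output directory {out} is not empty (use force=True)")
        (out / "images").mkdir(parents=True, exist_ok=True)
        (out / "rois").mkdir(parents=True, exist_ok=True)
        with open(out / "labels.csv", "w", newline="") as fh:
            lab = csv.writer(fh)
            lab.writerow(["specimen_id", "group"])
            for spec in specimens:
                lab.writerow([spec.image.source_id, spec.group])
        with open(out / "truth.csv", "w", newline="") as fh:
            tw = csv.writer(fh)
            tw.writerow(
                ["specimen_id", "group", "number", "cls", "side", "area_px", "centroid_x", "centroid_y", "orientation_folded"]
            )
            for spec in specimens:
                save_image(out / "images" / f"{spec.image.source_id}.png", spec.image.pixels)
                save_roi(out / "rois" / f"{spec.image.source_id}.json", spec.roi)
                for s in spec.truth_spots:
                    tw.writerow(
                        [
                            spec.image.source_id,
                            spec.group,
                            s.number,
                            s.cls,
                            s.side,
                            s.area_px,
                            f"{s.centroid[0]:.3f}",
                            f"{s.centroid[1]:.3f}",
                            f"{s.orientation_folded:.3f}",
                        ]
                    )
    return specimens


def identical_archetypes() -> tuple[HaplogroupArchetype, ...]:
    """Negative-control archetypes: three groups drawn from the same pattern."""
    h1, _, _ = default_archetypes()
    return tuple(replace(h1, name=name) for name in ("H1", "H2", "H3"))
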