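"""Reading and writing of images and region-of-interest annotations.

The ROI annotation replaces the manual abdomen clipping of the original
protocol: a JSON file per image with the abdomen outline polygon, the two
thorax–abdomen insertion points and the posterior tip of the abdomen, all
in source pixel coordinates (x rightward, y downward, origin top-left).

Schema::

    {
      "polygon": [[x, y], ...],          # >= 3 vertices, simple polygon
      "left_insertion": [x, y],
      "right_insertion": [x, y],
      "posterior": [x, y]
    }
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image


@dataclass
class AbdomenROI:
    """Abdomen outline plus alignment landmarks, in source pixel coordinates."""

    polygon: np.ndarray  # (n, 2) float array of (x, y) vertices
    left_insertion: tuple[float, float]
    right_insertion: tuple[float, float]
    posterior: tuple[float, float]

    def __post_init__(self) -> None:
        self.polygon = np.asarray(self.polygon, dtype=float)
        if self.polygon.ndim != 2 or self.polygon.shape[1] != 2 or len(self.polygon) < 3:
            raise ValueError("ROI polygon must be an (n, 2) array with n >= 3")

    def to_dict(self) -> dict:
        return {
            "polygon": np.asarray(self.polygon, dtype=float).tolist(),
            "left_insertion": list(map(float, self.left_insertion)),
            "right_insertion": list(map(float, self.right_insertion)),
            "posterior": list(map(float, self.posterior)),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AbdomenROI":
        return cls(
            polygon=np.asarray(d["polygon"], dtype=float),
            left_insertion=tuple(d["left_insertion"]),
            right_insertion=tuple(d["right_insertion"]),
            posterior=tuple(d["posterior"]),
        )


@dataclass
class RawImage:
    """A loaded source photograph (grayscale or RGB, 8-bit)."""

    pixels: np.ndarray  # (h, w) or (h, w, c) uint8
    source_id: str = ""

    height: int = field(init=False)
    width: int = field(init=False)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim not in (2, 3):
            raise ValueError("image must be 2-D (grayscale) or 3-D (multi-channel)")
        self.height, self.width = self.pixels.shape[:2]
        if self.height < 1 or self.width < 1:
            raise ValueError("image must have positive dimensions")


def load_image(path: str | Path) -> RawImage:
    """Load a PNG or TIFF image as :class:`RawImage` (alpha discarded if fully opaque)."""
    path = Path(path)
    with Image.open(path) as im:
        if im.mode in ("RGBA", "LA"):
            alpha = np.asarray(im)[..., -1]
            if not np.all(alpha == 255):
                raise ValueError(f"{path.name}: images with partial transparency are not supported")
            im = im.convert(im.mode[:-1])
        arr = np.asarray(im)
    return RawImage(pixels=arr, source_id=path.stem)


def save_image(path: str | Path, pixels: np.ndarray) -> None:
    Image.fromarray(np.asarray(pixels, dtype=np.uint8)).save(path)


def load_roi(path: str | Path) -> AbdomenROI:
    with open(path) as fh:
        return AbdomenROI.from_dict(json.load(fh))


def save_roi(path: str | Path, roi: AbdomenROI) -> None:
    with open(path, "w") as fh:
        json.dump(roi.to_dict(), fh, indent=1)


def save_json(path: str | Path, obj) -> None:
    """Write JSON with deterministic formatting (sorted keys, fixed separators)."""

    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True, default=_default)
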