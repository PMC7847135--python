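"""Per-group spot-frequency heat maps.

Superimposing the aligned binary spot masks of all specimens of one group
gives, per canonical-frame pixel, the fraction of specimens with a spot
there — high values mark the pattern shared across individuals, low values
idiosyncratic spots.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import matplotlib
import numpy as np

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .segmentation import BinaryMask  # noqa: E402


@dataclass
class HeatMap:
    grid: np.ndarray  # fractions in [0, 1]
    n: int
    group: str


def accumulate_heatmap(masks: list[BinaryMask | np.ndarray], group: str = "") -> HeatMap:
    """Per-pixel mean of boolean masks sharing the canonical frame."""
    if not masks:
        raise ValueError("no masks to accumulate")
    grids = [m.grid if isinstance(m, BinaryMask) else np.asarray(m, dtype=bool) for m in masks]
    shape = grids[0].shape
    for i, g in enumerate(grids):
        if g.shape != shape:
            raise ValueError(f"mask {i} has shape {g.shape}, expected {shape}")
    acc = np.zeros(shape, dtype=np.float64)
    for g in grids:
        acc += g
    return HeatMap(grid=acc / len(grids), n=len(grids), group=group)


def render_heatmap(
    hm: HeatMap, path: str | Path, palette: str = "viridis", dpi: int = 100
) -> None:
    """Write a false-color PNG with a colorbar; deterministic for fixed inputs."""
    h, w = hm.grid.shape
    fig, ax = plt.subplots(figsize=(w / dpi + 1.2, h / dpi), dpi=dpi)
    im = ax.imshow(hm.grid, cmap=palette, vmin=0.0, vmax=1.0, interpolation="nearest")
    ax.set_title(f"{hm.group} (n={hm.n})" if hm.group else f"n={hm.n}")
    ax.set_axis_off()
    cbar = fig.colorbar(im, ax=ax, fraction=0.046, pad=0.02)
    cbar.set_label("spot frequency")
    fig.savefig(path, metadata={"Software": "spotmorph"})
    plt.close(fig)


def save_heatmap_csv(hm: HeatMap, path: str | Path) -> None:
    np.savetxt(path, hm.grid, fmt="%.6g", delimiter=",")
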