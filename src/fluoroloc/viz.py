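"""Visual verification helpers: region overlays and pseudo-color export."""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .pipeline import GrayFrame
from .regions import ASSIGN_ORDER, RegionLayout

__all__ = ["layout_overlay", "colorize", "save_rgb"]

_REGION_COLORS = {
    "MC": (60, 180, 75),
    "TL": (230, 25, 75),
    "TR": (0, 130, 200),
    "BL": (245, 130, 48),
    "BR": (145, 30, 180),
    "BG": (64, 64, 64),
}


def layout_overlay(layout: RegionLayout, step: int = 1) -> np.ndarray:
    """Rasterize the region tiling as a labeled RGB image.

    ``step`` coarsens the rasterization (each output pixel covers a
    ``step x step`` block) to keep overlays cheap for large frames.
    """
    h = layout.height // step
    w = layout.width // step
    out = np.zeros((h, w, 3), dtype=np.uint8)
    for r in range(h):
        for c in range(w):
            region = layout.region_of(((c + 0.5) * step, (r + 0.5) * step))
            out[r, c] = _REGION_COLORS[region]
    for p0, p1 in layout.mirror_edges.values():
        _draw_segment(out, np.asarray(p0) / step, np.asarray(p1) / step)
    return out


def _draw_segment(img: np.ndarray, p0: np.ndarray, p1: np.ndarray) -> None:
    n = int(np.ceil(np.linalg.norm(p1 - p0))) * 2 + 1
    for t in np.linspace(0.0, 1.0, n):
        c, r = p0 + t * (p1 - p0)
        ri, ci = int(round(r)), int(round(c))
        if 0 <= ri < img.shape[0] and 0 <= ci < img.shape[1]:
            img[ri, ci] = (255, 255, 255)


def colorize(frame: GrayFrame, cmap: str = "viridis") -> np.ndarray:
    """Map an 8-bit frame through a linear colormap to RGB (visualization only)."""
    import matplotlib

    lut = (matplotlib.colormaps[cmap](np.linspace(0, 1, 256))[:, :3] * 255).astype(np.uint8)
    return lut[frame.pixels]


def save_rgb(img: np.ndarray, path: str | Path) -> None:
    iio.imwrite(Path(path), img)
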