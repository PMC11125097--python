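"""Frame pre-processing and fluorescence blob extraction.

The camera delivers 8-bit single-channel frames in which only the dye signal
is bright: a band-pass filter in front of the sensor suppresses everything
outside the emission band, so the background sits near zero intensity.  The
pipeline is deliberately simple — smooth, global-threshold, connected
components — mirroring the Fiji workflow used on the physical rig.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage
from skimage import measure

from .errors import EmptyMaskError, InputFormatError

__all__ = [
    "GrayFrame",
    "Blob",
    "ROIStats",
    "smooth_frame",
    "segment",
    "extract_blobs",
    "roi_intensity_stats",
    "blob_table",
    "write_mask",
]

_EIGHT_CONNECTED = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class GrayFrame:
    """An 8-bit single-channel frame; origin top-left, row-major."""

    pixels: np.ndarray
    frame_id: str = ""

    def __post_init__(self) -> None:
        px = self.pixels
        if px.ndim != 2 or px.size == 0:
            raise InputFormatError(f"frame must be a non-empty 2-D array, got shape {px.shape}")
        if px.dtype != np.uint8:
            raise InputFormatError(f"frame must be 8-bit (uint8), got {px.dtype}")

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @classmethod
    def from_file(cls, path: str | Path, frame_id: str | None = None) -> "GrayFrame":
        path = Path(path)
        arr = iio.imread(path)
        if arr.ndim == 3 and arr.shape[2] == 1:
            arr = arr[:, :, 0]
        if arr.ndim != 2:
            raise InputFormatError(
                f"{path.name}: expected single-channel grayscale, got shape {arr.shape}"
            )
        if arr.dtype != np.uint8:
            raise InputFormatError(f"{path.name}: expected 8-bit data, got {arr.dtype}")
        return cls(pixels=arr, frame_id=frame_id if frame_id is not None else path.stem)

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix.lower() in (".tif", ".tiff"):
            tifffile.imwrite(path, self.pixels)
        else:
            iio.imwrite(path, self.pixels)


@dataclass(frozen=True)
class Blob:
    """A segmented fluorescence component.

    ``centroid`` is the intensity-weighted sub-pixel position ``(col, row)``;
    ``bbox`` is ``(min_row, min_col, max_row, max_col)`` half-open as in
    scikit-image.
    """

    centroid: tuple[float, float]
    area: int
    mean_intensity: float
    max_intensity: int
    min_intensity: int
    bbox: tuple[int, int, int, int]


@dataclass(frozen=True)
class ROIStats:
    mean: float
    min: int
    max: int


def smooth_frame(f: GrayFrame, size: int = 3) -> GrayFrame:
    """Mean-filter a frame (edge replication), re-quantized round-half-up."""
    sm = ndimage.uniform_filter(f.pixels.astype(np.float64), size=size, mode="nearest")
    out = np.clip(np.floor(sm + 0.5), 0, 255).astype(np.uint8)
    return GrayFrame(pixels=out, frame_id=f.frame_id)


def segment(f: GrayFrame, threshold: int = 4) -> np.ndarray:
    """Boolean mask of pixels strictly above the global threshold.

    Strict comparison keeps the documented background ceiling (intensity 4
    for untreated plants) out of the foreground.
    """
    if not 0 <= threshold <= 255:
        raise ValueError(f"threshold must lie in [0, 255], got {threshold}")
    return f.pixels > threshold


def extract_blobs(mask: np.ndarray, f: GrayFrame, min_area: int = 12) -> list[Blob]:
    """8-connected components of ``mask`` with at least ``min_area`` pixels.

    Components are summarized with intensity-weighted centroids and sorted by
    descending area, ties broken by bounding-box top-left (row, col).
    """
    if mask.shape != f.pixels.shape:
        raise ValueError("mask and frame shapes differ")
    labels, n = ndimage.label(mask, structure=_EIGHT_CONNECTED)
    if n == 0:
        return []
    # drop sub-threshold components up front; noisy frames can have thousands
    areas = np.bincount(labels.ravel())
    small = np.where(areas < min_area)[0]
    if small.size:
        labels[np.isin(labels, small)] = 0
    blobs: list[Blob] = []
    for region in measure.regionprops(labels, intensity_image=f.pixels):
        if region.area < min_area:
            continue
        crow, ccol = region.centroid_weighted
        blobs.append(
            Blob(
                centroid=(float(ccol), float(crow)),
                area=int(region.area),
                mean_intensity=float(region.intensity_mean),
                max_intensity=int(region.intensity_max),
                min_intensity=int(region.intensity_min),
                bbox=tuple(int(v) for v in region.bbox),
            )
        )
    blobs.sort(key=lambda b: (-b.area, b.bbox[0], b.bbox[1]))
    return blobs


def roi_intensity_stats(f: GrayFrame, mask: np.ndarray) -> ROIStats:
    """Mean/min/max intensity over the masked pixels."""
    if mask.shape != f.pixels.shape:
        raise ValueError("mask and frame shapes differ")
    if not mask.any():
        raise EmptyMaskError("ROI mask is empty")
    vals = f.pixels[mask]
    return ROIStats(mean=float(vals.mean()), min=int(vals.min()), max=int(vals.max()))


def blob_table(blobs: list[Blob], frame_id: str = "", regions: list[str] | None = None) -> pd.DataFrame:
    """Tabulate blobs as one CSV-ready row each."""
    if regions is None:
        regions = [""] * len(blobs)
    rows = [
        {
            "frame_id": frame_id,
            "region": region,
            "centroid_col": b.centroid[0],
            "centroid_row": b.centroid[1],
            "area": b.area,
            "mean": b.mean_intensity,
            "min": b.min_intensity,
            "max": b.max_intensity,
        }
        for b, region in zip(blobs, regions)
    ]
    return pd.DataFrame(
        rows,
        columns=["frame_id", "region", "centroid_col", "centroid_row", "area", "mean", "min", "max"],
    )


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    """Write a binary mask as an 8-bit PNG (0/255)."""
    iio.imwrite(Path(path), (mask.astype(np.uint8) * 255))
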