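"""Droplet (condensate) quantification and two-channel colocalization.

The particle-analysis recipe follows common fluorescence practice: a
fixed intensity threshold (inclusive, default 100 — calibrated as the
maximum intensity of protein-alone control images on the same scale)
binarises the image, connected components (8-connected by default) become
particles, and components below an optional physical size cut (e.g.
2×2 μm² → 4 μm²) are discarded.  Touching droplets merge into one
particle: no watershed splitting is attempted.

Colocalization is the plain Pearson correlation of two channels over the
ROI pixels, with no thresholding.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from skimage import measure

__all__ = [
    "DropletStats",
    "ColocalizationResult",
    "quantify_droplets",
    "relative_total_area",
    "pearson_colocalization",
    "load_grayscale",
]


@dataclass
class DropletStats:
    """Per-particle and aggregate measurements from one thresholded image."""

    particles: pd.DataFrame  # area_px, area_um2, mean_intensity, equiv_diameter_px
    threshold: float
    min_area_um2: float
    pixel_size_um: float | None

    @property
    def count(self) -> int:
        return int(len(self.particles))

    @property
    def total_area_px(self) -> float:
        return float(self.particles["area_px"].sum())

    @property
    def total_area_um2(self) -> float:
        if self.pixel_size_um is None:
            raise ValueError("pixel size not provided: no physical areas")
        return float(self.particles["area_um2"].sum())

    @property
    def total_intensity(self) -> float:
        return float(
            (self.particles["mean_intensity"] * self.particles["area_px"]).sum()
        )

    def summary(self) -> dict:
        return {
            "count": self.count,
            "total_area_px": self.total_area_px,
            "total_intensity": self.total_intensity,
            "threshold": self.threshold,
            "min_area_um2": self.min_area_um2,
            "pixel_size_um": self.pixel_size_um,
        }


@dataclass(frozen=True)
class ColocalizationResult:
    pearson_r: float
    n_pixels: int
    roi: str = "full-frame"


def quantify_droplets(
    image: np.ndarray,
    threshold: float = 100.0,
    min_area_um2: float = 0.0,
    pixel_size_um: float | None = None,
    connectivity: int = 8,
) -> DropletStats:
    """Threshold an image and measure the resulting particles.

    Pixels with intensity >= ``threshold`` form the mask; particles are
    connected components (``connectivity`` 8 or 4); particles smaller than
    ``min_area_um2`` are dropped (requires ``pixel_size_um``).  An image
    with no above-threshold pixels yields count 0, which is a valid
    result, not an error.
    """
    img = np.asarray(image)
    if img.ndim != 2 or img.size == 0:
        raise ValueError("expected a non-empty 2-D grayscale image")
    if np.any(img < 0):
        raise ValueError("image intensities must be nonnegative")
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    if min_area_um2 > 0 and pixel_size_um is None:
        raise ValueError("a physical size cut requires pixel_size_um")
    if pixel_size_um is not None and pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be > 0")

    mask = img >= threshold
    labels = measure.label(mask, connectivity=2 if connectivity == 8 else 1)
    props = measure.regionprops(labels, intensity_image=img)

    px_area_um2 = pixel_size_um**2 if pixel_size_um is not None else np.nan
    rows = []
    for p in props:
        area_px = float(p.area)
        area_um2 = area_px * px_area_um2
        if min_area_um2 > 0 and area_um2 < min_area_um2:
            continue
        rows.append(
            {
                "label": int(p.label),
                "area_px": area_px,
                "area_um2": area_um2,
                "mean_intensity": float(p.intensity_mean),
                "equiv_diameter_px": float(p.equivalent_diameter_area),
                "centroid_row": float(p.centroid[0]),
                "centroid_col": float(p.centroid[1]),
            }
        )
    particles = pd.DataFrame(
        rows,
        columns=[
            "label", "area_px", "area_um2", "mean_intensity",
            "equiv_diameter_px", "centroid_row", "centroid_col",
        ],
    )
    return DropletStats(
        particles=particles,
        threshold=float(threshold),
        min_area_um2=float(min_area_um2),
        pixel_size_um=pixel_size_um,
    )


def relative_total_area(conditions: list[DropletStats] | list[float]) -> np.ndarray:
    """Total droplet area per condition, expressed as a fraction of the maximum."""
    if len(conditions) == 0:
        raise ValueError("need at least one condition")
    areas = np.array(
        [
            c.total_area_px if isinstance(c, DropletStats) else float(c)
            for c in conditions
        ],
        dtype=np.float64,
    )
    top = areas.max()
    if top <= 0:
        raise ValueError("all total areas are zero: relative areas undefined")
    return areas / top


def pearson_colocalization(
    channel_a: np.ndarray,
    channel_b: np.ndarray,
    roi_mask: np.ndarray | None = None,
) -> ColocalizationResult:
    """Pearson correlation of two channels over the ROI pixels (no threshold)."""
    a = np.asarray(channel_a, dtype=np.float64)
    b = np.asarray(channel_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("channels must share a shape")
    if roi_mask is not None:
        m = np.asarray(roi_mask, dtype=bool)
        if m.shape != a.shape:
            raise ValueError("ROI mask must share the channel shape")
        a, b = a[m], b[m]
        roi = f"mask({int(m.sum())} px)"
    else:
        a, b = a.ravel(), b.ravel()
        roi = "full-frame"
    if a.size < 2:
        raise ValueError("ROI must contain at least 2 pixels")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("undefined correlation: a channel is constant in the ROI")
    r = float(np.corrcoef(a, b)[0, 1])
    return ColocalizationResult(pearson_r=r, n_pixels=int(a.size), roi=roi)


def load_grayscale(path: str | Path, channel: int | None = None) -> np.ndarray:
    """Read a TIFF/PNG image as a 2-D array; pick ``channel`` if multi-channel."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        img = tifffile.imread(path)
    else:
        import imageio.v3 as iio

        img = iio.imread(path)
    img = np.asarray(img)
    if img.ndim == 3:
        if channel is None:
            raise ValueError(
                f"{path} has {img.shape} channels/planes; pass a channel index"
            )
        axis = int(np.argmin(img.shape))  # channel axis = smallest dimension
        img = np.take(img, channel, axis=axis)
    if img.ndim != 2:
        raise ValueError(f"{path}: could not reduce to a 2-D grayscale image")
    return img
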