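"""DAB-positive area quantification in RGB micrographs.

A pixel counts as DAB-positive when (R - G)/B >= threshold with channel
intensities normalized to [0, 1] and threshold 0.5 by default; the reported
statistic is positive pixels / total ROI pixels.  Pixels with B = 0 are
defined non-positive (division guard) and tallied separately.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["ROIQuantResult", "dab_positive_fraction", "load_image",
           "load_mask"]


@dataclass
class ROIQuantResult:
    """Per-ROI DAB quantification."""

    roi_name: str
    positive_pixels: int
    total_pixels: int
    fraction: float
    b_zero_pixels: int

    def __post_init__(self) -> None:
        assert 0.0 <= self.fraction <= 1.0
        assert self.positive_pixels <= self.total_pixels


def load_image(path: str | Path) -> np.ndarray:
    """Read an RGB image and normalize intensities to [0, 1] by the dtype max."""
    import imageio.v3 as iio
    from skimage.util import img_as_float

    img = iio.imread(Path(path))
    if img.ndim == 2:
        img = np.stack([img] * 3, axis=-1)
    return img_as_float(img[..., :3])


def load_mask(path: str | Path) -> np.ndarray:
    """Read an ROI mask image; any nonzero pixel belongs to the ROI."""
    import imageio.v3 as iio

    m = iio.imread(Path(path))
    if m.ndim == 3:
        m = m[..., 0]
    return m > 0


def dab_positive_fraction(image: np.ndarray, roi: np.ndarray | None = None,
                          threshold: float = 0.5,
                          roi_name: str = "roi") -> ROIQuantResult:
    """Fraction of ROI pixels with (R - G)/B at or above ``threshold``.

    ``image`` is HxWx3 with channels in [0, 1]; ``roi`` a boolean mask of the
    same spatial shape (``None`` = whole image).
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 3 or image.shape[2] < 3:
        raise ValueError("image must be HxWx3 RGB")
    if image.min() < 0 or image.max() > 1:
        raise ValueError("channel intensities must lie in [0, 1]")
    if roi is None:
        roi = np.ones(image.shape[:2], dtype=bool)
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != image.shape[:2]:
        raise ValueError(
            f"roi shape {roi.shape} != image shape {image.shape[:2]}")
    if not roi.any():
        raise ValueError("ROI selects no pixels")
    r = image[..., 0][roi]
    g = image[..., 1][roi]
    b = image[..., 2][roi]
    b_zero = b <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        positive = ~b_zero & ((r - g) / np.where(b_zero, 1.0, b) >= threshold)
    n_pos = int(positive.sum())
    n_tot = int(roi.sum())
    return ROIQuantResult(roi_name=roi_name, positive_pixels=n_pos,
                          total_pixels=n_tot, fraction=n_pos / n_tot,
                          b_zero_pixels=int(b_zero.sum()))
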