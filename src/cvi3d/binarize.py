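"""Luminal/stromal classification of choroid pixels by Niblack local thresholding.

The choroid ROI of a B-scan is the band between the RPE-Bruch's complex and
the choroid-scleral interface.  Within it, dark pixels correspond to vessel
lumina and bright pixels to stroma.  Classification uses Niblack's adaptive
threshold

    t(r, c) = mean_W(r, c) + k * std_W(r, c) - c0

over a square window W of side ``2 * window_radius + 1`` centred on each
pixel, with replicate padding at the image border and the population (divide
by n) standard deviation.  A pixel is luminal iff it lies inside the ROI and
its intensity is strictly below its local threshold; the luminal mask is the
pixelwise AND of the ROI mask and the dark-pixel mask.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import ValidationError


@dataclass(frozen=True)
class BinarisationParams:
    """Niblack parameters; recorded with every measurement for provenance.

    ``window_radius`` is the local-neighbourhood half-width in pixels, ``k``
    the dimensionless standard-deviation weight, and ``c`` an additive offset
    subtracted from the threshold (intensity units).  Defaults match the
    common ImageJ Auto Local Threshold settings (window radius 15, k = 0.2,
    c = 0).  Dark pixels are always the luminal class.  ``population_std``
    selects divide-by-n local standard deviation (the default); set False
    for the n-1 convention.
    """

    window_radius: int = 15
    k: float = 0.2
    c: float = 0.0
    population_std: bool = True

    def __post_init__(self) -> None:
        if self.window_radius < 1:
            raise ValidationError("window_radius must be >= 1")

    def as_dict(self) -> dict:
        return {
            "window_radius": self.window_radius,
            "k": self.k,
            "c": self.c,
            "population_std": self.population_std,
        }


def rasterize_roi(
    upper: np.ndarray, lower: np.ndarray, scan_shape: tuple[int, int]
) -> np.ndarray:
    """Rasterise one scan's boundary profiles into a boolean ROI mask.

    Pixel (r, c) is inside the ROI iff ``upper[c] <= r < lower[c]`` — the
    upper boundary row is included and the lower excluded, so the per-column
    true-pixel count is exactly ``lower[c] - upper[c]``.
    """
    upper = np.asarray(upper, dtype=int)
    lower = np.asarray(lower, dtype=int)
    rows, cols = scan_shape
    if upper.shape != (cols,) or lower.shape != (cols,):
        raise ValidationError(
            f"boundary profiles must have one entry per column ({cols})"
        )
    if np.any(upper > lower):
        raise ValidationError("upper boundary below lower boundary")
    if np.any(upper < 0) or np.any(lower > rows):
        raise ValidationError("boundaries extend outside the scan")
    r = np.arange(rows)[:, None]
    return (r >= upper[None, :]) & (r < lower[None, :])


def niblack_threshold(image: np.ndarray, params: BinarisationParams) -> np.ndarray:
    """Per-pixel Niblack threshold map of an 8-bit image.

    Local mean and standard deviation are computed over the square window of
    side ``2 * window_radius + 1`` with replicate (nearest) padding at the
    borders.  Raises if the window does not fit inside the image.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ValidationError("image must be 2D")
    side = 2 * params.window_radius + 1
    if side > min(image.shape):
        raise ValidationError(
            f"window side {side} exceeds image extent {min(image.shape)}"
        )
    mean = ndimage.uniform_filter(image, size=side, mode="nearest")
    mean_sq = ndimage.uniform_filter(image * image, size=side, mode="nearest")
    var = np.maximum(mean_sq - mean * mean, 0.0)
    if not params.population_std:
        n = side * side
        var = var * (n / (n - 1))
    return mean + params.k * np.sqrt(var) - params.c


def classify_luminal(
    image: np.ndarray, roi: np.ndarray, params: BinarisationParams
) -> np.ndarray:
    """Luminal mask: ROI pixels strictly darker than their local threshold.

    The threshold is computed on the full image (not restricted to the ROI)
    so window statistics match whole-scan behaviour.  Ties go to stroma.
    An empty ROI yields an empty mask with a warning.
    """
    image = np.asarray(image)
    roi = np.asarray(roi, dtype=bool)
    if image.shape != roi.shape:
        raise ValidationError("image and ROI must share shape")
    if not roi.any():
        warnings.warn("empty choroid ROI: no pixels to classify", stacklevel=2)
        return np.zeros_like(roi)
    threshold = niblack_threshold(image, params)
    return roi & (image.astype(np.float64) < threshold)
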