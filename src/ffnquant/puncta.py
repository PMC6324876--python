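"""Punctate-structure quantification via Canny edge filtering.

Baseline (pre-stimulus) images are reduced to a binary edge mask with a
Canny filter — a pixel is 1 where the image has high local contrast, i.e.
around fluorescent puncta and labelled neuropil — and the mask's pixel count
(the "Canny edge sum") serves as a proxy for punctate structure. Thresholds
follow MATLAB's convention: they apply to the gradient magnitude normalized
to a maximum of 1, with defaults low = 0.08 and high = 0.2 and a Gaussian
pre-smoothing width of ~1.4 px.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.ndimage as ndi
from scipy import stats as sps
from skimage import feature

from .protocols import StimulusProtocol

__all__ = [
    "BaselineImage",
    "EdgeMask",
    "baseline_image",
    "canny_mask",
    "canny_edge_sum",
    "pearson_r",
]


@dataclass
class BaselineImage:
    """Pixelwise mean of the pre-stimulus frames of one field of view."""

    pixels: np.ndarray
    pixel_size_um: float = 50.0 / 64.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2 or min(self.pixels.shape) < 1:
            raise ValueError("pixels must be a non-empty H x W array")
        if np.any(self.pixels < 0):
            raise ValueError("pixel intensities must be non-negative")


@dataclass
class EdgeMask:
    """Binary high-contrast mask with the thresholds that produced it."""

    pixels: np.ndarray
    low_threshold: float = 0.08
    high_threshold: float = 0.2
    smoothing_sigma_px: float = 1.4

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if not 0 <= self.low_threshold < self.high_threshold <= 1:
            raise ValueError("need 0 <= low < high <= 1")


def baseline_image(
    movie,
    protocol: StimulusProtocol | None = None,
    window_s: float | None = None,
) -> BaselineImage:
    """Pixelwise mean over the pre-stimulus frames.

    Frames with ``t < onset`` are used; ``window_s`` optionally restricts
    them to the window immediately before the stimulus.
    """
    protocol = protocol or movie.protocol
    if protocol is None:
        raise ValueError("no stimulus protocol available")
    times = np.arange(movie.frames.shape[0]) / movie.frame_rate_hz
    mask = times < protocol.onset_s - 1e-9
    if window_s is not None:
        mask &= times >= protocol.onset_s - window_s - 1e-9
    if not np.any(mask):
        raise ValueError("no pre-stimulus frames in the movie")
    return BaselineImage(movie.frames[mask].mean(axis=0), movie.pixel_size_um)


def _normalized_gradient_max(img: np.ndarray, sigma_px: float) -> float:
    """Max smoothed Sobel gradient magnitude, used to scale thresholds."""
    smoothed = ndi.gaussian_filter(img, sigma_px, mode="constant")
    gmag = np.hypot(ndi.sobel(smoothed, axis=0), ndi.sobel(smoothed, axis=1))
    return float(gmag.max())


def canny_mask(
    image: BaselineImage,
    low: float = 0.08,
    high: float = 0.2,
    sigma_px: float = 1.4,
) -> EdgeMask:
    """Canny edge mask with thresholds on the [0, 1]-normalized gradient.

    Gaussian smoothing, Sobel gradient, non-maximum suppression and
    hysteresis are delegated to scikit-image; the fractional thresholds are
    rescaled by the image's maximum gradient magnitude so they act on a
    gradient normalized to peak 1 (MATLAB-style semantics). A constant image
    yields an empty mask, not an error. The mask is invariant to adding or
    multiplying the image by a positive constant.
    """
    if not 0 <= low < high <= 1:
        raise ValueError("need 0 <= low < high <= 1")
    img = np.asarray(image.pixels, dtype=float)
    gmax = _normalized_gradient_max(img, sigma_px)
    if gmax == 0.0:
        mask = np.zeros(img.shape, dtype=bool)
    else:
        mask = feature.canny(
            img,
            sigma=sigma_px,
            low_threshold=low * gmax,
            high_threshold=high * gmax,
        )
    return EdgeMask(mask, low, high, sigma_px)


def canny_edge_sum(mask: EdgeMask) -> int:
    """Number of edge (1) pixels in the mask."""
    return int(np.count_nonzero(mask.pixels))


def pearson_r(x, y) -> float:
    """Sample Pearson correlation coefficient.

    Raises on length mismatch, fewer than 3 points, or zero variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("zero variance in x or y")
    return float(sps.pearsonr(x, y).statistic)
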