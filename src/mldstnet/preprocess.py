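"""Noise reduction, contrast enhancement and breast-region extraction.

The stage order mirrors a standard mammography front end: median filtering
against salt-and-pepper noise, global histogram equalization to spread a
typically dark, low-contrast exposure over the full dynamic range, and a
morphological cut that keeps only the largest tissue component.

Histogram equalization uses the textbook transfer function

    f(x) = x0 + (x_{L-1} - x0) * c(x),        c(x) = sum_{k<=x} h(k) / N,

with ``[x0, x_{L-1}] = [0, L-1]`` and round-half-up to the nearest integer.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.morphology import diamond

from .errors import EmptyROIError, ParameterError
from .image import GrayImage

__all__ = [
    "median_filter",
    "histogram",
    "equalize",
    "equalize_transfer_function",
    "extract_roi",
]


def median_filter(img: GrayImage, window: int = 3) -> GrayImage:
    """Median filter with a ``window x window`` neighborhood.

    Borders are handled by replication, so the filter neither shrinks the
    image nor darkens its rim.

    Parameters
    ----------
    img : GrayImage
    window : int
        Odd window size, at least 3.
    """
    if window < 3 or window % 2 == 0:
        raise ParameterError(f"window must be an odd integer >= 3, got {window}")
    out = ndimage.median_filter(img.pixels, size=window, mode="nearest")
    return GrayImage(out, levels=img.levels)


def histogram(img: GrayImage) -> np.ndarray:
    """Intensity histogram ``h(x)``: count of pixels at each level ``x`` in [0, L-1]."""
    return np.bincount(img.pixels.ravel(), minlength=img.levels).astype(np.int64)


def equalize_transfer_function(img: GrayImage) -> np.ndarray:
    """The (unrounded) equalization transfer function ``f(x)`` per level.

    Monotone nondecreasing; maps onto the full dynamic range ``[0, L-1]``.
    """
    h = histogram(img)
    p = h / img.n_pixels
    c = np.cumsum(p)
    x0, x_last = 0.0, float(img.levels - 1)
    return x0 + (x_last - x0) * c


def equalize(img: GrayImage) -> GrayImage:
    """Histogram-equalize an image over its full dynamic range.

    Output pixel = round-half-up of ``f(X(i,j))``, clipped to ``[0, L-1]``.
    """
    f = equalize_transfer_function(img)
    # round-half-up, then clip (f can only exceed L-1 by float fuzz)
    mapped = np.floor(f + 0.5).astype(np.int64)
    mapped = np.clip(mapped, 0, img.levels - 1)
    return GrayImage(mapped[img.pixels], levels=img.levels)


def extract_roi(
    img: GrayImage,
    threshold: float | None = None,
    erosion_radius: int = 3,
) -> tuple[GrayImage, np.ndarray]:
    """Isolate the dominant bright region (the breast tissue area).

    Binarize (Otsu's threshold unless one is given), erode with a flat
    diamond structuring element (city-block radius ``erosion_radius``),
    keep the largest 8-connected component, and zero the background.

    Returns
    -------
    (GrayImage, numpy.ndarray)
        The masked image and the boolean mask.

    Raises
    ------
    EmptyROIError
        If nothing survives binarization + erosion.
    """
    px = img.pixels
    if threshold is None:
        if px.min() == px.max():
            raise EmptyROIError("constant image has no separable foreground")
        threshold = threshold_otsu(px)
    binary = px > threshold
    eroded = ndimage.binary_erosion(binary, structure=diamond(erosion_radius))
    if not eroded.any():
        raise EmptyROIError("no foreground remains after erosion")
    labels = cc_label(eroded, connectivity=2)
    counts = np.bincount(labels.ravel())
    counts[0] = 0  # background
    mask = labels == np.argmax(counts)
    return GrayImage(np.where(mask, px, 0), levels=img.levels), mask
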