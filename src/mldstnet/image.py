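"""Grayscale image container and file I/O.

Images are plain 2-D integer arrays with an explicit number of gray levels
``L`` (256 for 8-bit mammograms).  File round-trips go through Pillow, which
covers binary (P5) and ASCII (P2) PGM as well as single-channel PNG and TIFF.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image as PILImage

from .errors import ParameterError

__all__ = ["GrayImage", "read_image", "write_image"]


@dataclass(frozen=True)
class GrayImage:
    """A 2-D grid of integer intensities in ``[0, levels-1]``.

    Parameters
    ----------
    pixels : numpy.ndarray
        2-D integer array of intensities.
    levels : int
        Number of gray levels ``L`` (intensities occupy ``[0, L-1]``).
    """

    pixels: np.ndarray
    levels: int = 256

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ParameterError(f"pixels must be 2-D, got shape {px.shape}")
        if self.levels < 2:
            raise ParameterError(f"levels must be >= 2, got {self.levels}")
        if not np.issubdtype(px.dtype, np.integer):
            if np.any(px != np.round(px)):
                raise ParameterError("pixels must be integer-valued")
            px = px.astype(np.int64)
        if px.size and (px.min() < 0 or px.max() > self.levels - 1):
            raise ParameterError(
                f"pixel values must lie in [0, {self.levels - 1}], "
                f"got range [{px.min()}, {px.max()}]"
            )
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def n_pixels(self) -> int:
        return self.pixels.size

    def astype_float(self) -> np.ndarray:
        """Pixels as float64, unscaled."""
        return self.pixels.astype(np.float64)

    def __eq__(self, other) -> bool:  # value semantics for tests
        if not isinstance(other, GrayImage):
            return NotImplemented
        return self.levels == other.levels and np.array_equal(self.pixels, other.pixels)

    def __hash__(self):
        return hash((self.levels, self.pixels.tobytes(), self.pixels.shape))


def read_image(path: str | Path, levels: int = 256) -> GrayImage:
    """Read a single-channel image (PGM/PNG/TIFF) as a :class:`GrayImage`."""
    with PILImage.open(path) as im:
        if im.mode not in ("L", "I", "I;16"):
            im = im.convert("L")
        arr = np.asarray(im)
    return GrayImage(arr.astype(np.int64), levels=levels)


def write_image(img: GrayImage, path: str | Path) -> None:
    """Write a :class:`GrayImage` to PGM/PNG/TIFF (format from the extension)."""
    if img.levels > 256:
        raise ParameterError("only images with <= 256 levels can be written")
    PILImage.fromarray(img.pixels.astype(np.uint8), mode="L").save(path)
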