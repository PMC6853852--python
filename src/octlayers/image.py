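"""B-scan image container, file I/O and the top-crop preprocessing step.

A B-scan is a single 2D cross-sectional OCT frame: rows index axial depth
(row 0 is the shallowest, vitreous side), columns index lateral position.
Intensities are kept as floating point internally so that enhancement and
gradient computation run at full precision; quantization to the native bit
depth happens only on export.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

from .errors import FormatError, ParameterError

__all__ = ["BScanImage", "load_image", "save_image", "crop_top"]


@dataclass
class BScanImage:
    """A single grayscale OCT B-scan.

    Parameters
    ----------
    pixels
        2D array of intensities, rows = depth, columns = lateral position.
        Stored as float64; values must lie in ``[0, max_grey - 1]``.
    max_grey
        Number of representable grey levels ``L`` (256 for 8-bit input,
        65536 for 16-bit).
    crop_offset
        Number of rows previously removed from the top of the frame.
        Carried along so boundary rows can be reported in the original
        (pre-crop) coordinate frame.
    """

    pixels: np.ndarray
    max_grey: int = 256
    crop_offset: int = 0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise FormatError(f"expected a 2D grayscale image, got ndim={self.pixels.ndim}")
        if self.pixels.shape[0] < 2 or self.pixels.shape[1] < 2:
            raise FormatError(f"image too small: {self.pixels.shape}")
        if self.max_grey < 2:
            raise ParameterError(f"max_grey must be >= 2, got {self.max_grey}")
        if not np.all(np.isfinite(self.pixels)):
            raise FormatError("image contains non-finite intensities")
        lo, hi = float(self.pixels.min()), float(self.pixels.max())
        if lo < 0 or hi > self.max_grey - 1:
            raise FormatError(
                f"intensities [{lo}, {hi}] outside [0, {self.max_grey - 1}]"
            )

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    def is_constant(self) -> bool:
        return bool(self.pixels.min() == self.pixels.max())


def load_image(path: str | Path, allow_rgb: bool = False) -> BScanImage:
    """Read a grayscale 8- or 16-bit TIFF/PNG into a :class:`BScanImage`.

    Intensities are preserved exactly. Multichannel input is rejected unless
    ``allow_rgb`` is set, in which case channels are averaged (and rounded)
    to produce a single luminance plane.
    """
    path = Path(path)
    try:
        arr = iio.imread(path)
    except Exception as exc:  # pragma: no cover - backend specific messages
        raise FormatError(f"cannot read image {path}: {exc}") from exc
    if arr.ndim == 3:
        if not allow_rgb:
            raise FormatError(
                f"{path} has {arr.shape[-1]} channels; pass allow_rgb=True to convert"
            )
        arr = np.round(arr.astype(np.float64).mean(axis=-1))
    if arr.dtype == np.uint16 or (arr.dtype.kind in "iu" and arr.max() > 255):
        max_grey = 65536
    else:
        max_grey = 256
    return BScanImage(arr.astype(np.float64), max_grey=max_grey)


def save_image(image: BScanImage, path: str | Path) -> None:
    """Write a B-scan as TIFF or PNG at its native bit depth.

    Continuous intensities are rounded and clipped to ``[0, L-1]`` here —
    this is the only place quantization happens.
    """
    path = Path(path)
    dtype = np.uint8 if image.max_grey <= 256 else np.uint16
    arr = np.clip(np.round(image.pixels), 0, image.max_grey - 1).astype(dtype)
    if path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(path, arr)
    else:
        iio.imwrite(path, arr)


def crop_top(image: BScanImage, fraction: float) -> BScanImage:
    """Remove ``floor(fraction * height)`` rows from the top of the scan.

    The shallow part of a B-scan above the retina carries little signal;
    removing it shrinks the graph and avoids spurious shortest paths. The
    number of removed rows is accumulated in ``crop_offset`` so results can
    be exported in original image coordinates.
    """
    if not (0 <= fraction < 0.5):
        raise ParameterError(f"crop fraction must be in [0, 0.5), got {fraction}")
    n = math.floor(fraction * image.height)
    if n == 0:
        return BScanImage(image.pixels.copy(), image.max_grey, image.crop_offset)
    return BScanImage(
        image.pixels[n:].copy(), image.max_grey, image.crop_offset + n
    )
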