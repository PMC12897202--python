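"""2D grayscale image container and TIFF I/O."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile


@dataclass
class Image2D:
    """A 2D grayscale raster with its bit depth and optional pixel size.

    Parameters
    ----------
    pixels : ndarray
        2D array of non-negative intensities.
    bit_depth : int
        8 or 16; intensities must lie in ``[0, 2**bit_depth - 1]``.
    pixel_size_um : float, optional
        Physical pixel edge length in micrometres (e.g. 0.035 for
        Airyscan confocal data).
    """

    pixels: np.ndarray
    bit_depth: int = 8
    pixel_size_um: float | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError(f"expected a 2D array, got shape {self.pixels.shape}")
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ValueError("image must have at least one row and one column")
        if self.bit_depth not in (8, 16):
            raise ValueError(f"unsupported bit depth {self.bit_depth}; use 8 or 16")
        if np.any(self.pixels < 0) or np.any(self.pixels > self.max_value):
            raise ValueError(
                f"intensities must lie in [0, {self.max_value}] for "
                f"{self.bit_depth}-bit data"
            )
        if self.pixel_size_um is not None and self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def max_value(self) -> int:
        """Full-scale intensity for this bit depth."""
        return 2**self.bit_depth - 1

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def astype_float(self) -> np.ndarray:
        return self.pixels.astype(np.float64)

    def with_pixels(self, pixels: np.ndarray) -> "Image2D":
        """Copy carrying new pixel data but the same metadata."""
        return Image2D(pixels, bit_depth=self.bit_depth, pixel_size_um=self.pixel_size_um)


def read_image(path: str | Path, channel: int | None = None) -> Image2D:
    """Read a single-channel 2D TIFF into an :class:`Image2D`.

    Multi-channel or stacked TIFFs are rejected unless ``channel`` selects
    one plane explicitly.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    arr = tifffile.imread(str(path))
    if arr.ndim == 3:
        if channel is None:
            raise ValueError(
                f"{path.name} has {arr.shape} planes/channels; pass an explicit "
                "channel index to select one"
            )
        # channel may sit on the first (stack) or last (RGB) axis
        if arr.shape[-1] <= 4 and arr.shape[0] > 4:
            arr = arr[..., channel]
        else:
            arr = arr[channel]
    elif arr.ndim != 2:
        raise ValueError(f"unsupported TIFF dimensionality {arr.ndim}")
    if arr.dtype == np.uint8:
        depth = 8
    elif arr.dtype == np.uint16:
        depth = 16
    else:
        raise ValueError(f"unsupported TIFF dtype {arr.dtype}; expected uint8 or uint16")
    return Image2D(arr, bit_depth=depth)


def write_image(img: Image2D, path: str | Path) -> None:
    """Write an :class:`Image2D` as an integer TIFF of its bit depth."""
    dtype = np.uint8 if img.bit_depth == 8 else np.uint16
    arr = np.clip(np.rint(np.asarray(img.pixels, dtype=np.float64)), 0, img.max_value)
    tifffile.imwrite(str(path), arr.astype(dtype))
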