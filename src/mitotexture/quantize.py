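"""Gray-level discretization shared by all texture-matrix computations."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .image import Image2D


@dataclass
class QuantizedROI:
    """Integer gray-level raster (levels 1..Ng) plus validity mask."""

    levels: np.ndarray          # int array, masked entries >= 1
    Ng: int                     # number of gray levels (max level)
    mask: np.ndarray            # boolean, same shape
    bin_width: float

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, dtype=np.intp)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.levels.shape != self.mask.shape:
            raise ValueError("levels and mask shapes differ")
        if self.mask.any() and self.levels[self.mask].min() < 1:
            raise ValueError("gray levels must start at 1")
        if self.Ng < 1:
            raise ValueError("Ng must be >= 1")

    @property
    def n_masked(self) -> int:
        return int(self.mask.sum())


def _as_array_and_mask(roi, mask):
    x = roi.astype_float() if isinstance(roi, Image2D) else np.asarray(roi, dtype=np.float64)
    if mask is None:
        mask = np.ones(x.shape, dtype=bool)
    else:
        mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    return x, mask


def quantize_fixed_bin_width(roi, bin_width: float = 25.0, mask=None) -> QuantizedROI:
    """Discretize with a fixed intensity bin width (default 25).

    ``level(x) = floor(x / w) - floor(min_masked / w) + 1``; the level origin
    is anchored at the masked minimum so shifting all intensities by a
    multiple of the bin width leaves the levels unchanged.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    x, m = _as_array_and_mask(roi, mask)
    base = np.floor(x[m].min() / bin_width)
    levels = np.zeros(x.shape, dtype=np.intp)
    levels[m] = (np.floor(x[m] / bin_width) - base + 1).astype(np.intp)
    return QuantizedROI(levels, int(levels[m].max()), m, float(bin_width))


def quantize_fixed_bin_count(roi, n_bins: int, mask=None) -> QuantizedROI:
    """Discretize into ``n_bins`` equal-width bins spanning the masked
    intensity range; the top edge is inclusive. A constant ROI collapses to
    a single level with a warning."""
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    x, m = _as_array_and_mask(roi, mask)
    lo, hi = float(x[m].min()), float(x[m].max())
    levels = np.zeros(x.shape, dtype=np.intp)
    if hi == lo:
        warnings.warn("constant ROI: all pixels assigned level 1")
        levels[m] = 1
        return QuantizedROI(levels, 1, m, 0.0)
    width = (hi - lo) / n_bins
    lv = np.floor((x[m] - lo) / width).astype(np.intp) + 1
    lv[lv > n_bins] = n_bins  # top edge inclusive
    levels[m] = lv
    return QuantizedROI(levels, int(lv.max()), m, width)
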