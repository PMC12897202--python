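"""Confocal image pre-processing chain and ROI extraction.

The chain is: percentile saturation rescale -> contrast-limited adaptive
histogram equalization (CLAHE) -> pixel-wise adaptive Wiener denoising ->
Gaussian smoothing. All stages run in floating point; the chain re-quantizes
to the input bit depth only at the end to avoid cumulative rounding error.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .image import Image2D

logger = logging.getLogger(__name__)


@dataclass
class PreprocessConfig:
    """Parameters of the pre-processing chain.

    Defaults saturate the bottom/top 1% of intensities, equalize with an
    8x8 tile CLAHE at clip fraction 0.01, denoise with a 3x3 adaptive
    Wiener filter and smooth with a sigma = 0.5 px Gaussian.
    """

    sat_low_frac: float = 0.01
    sat_high_frac: float = 0.01
    clahe_tiles: tuple[int, int] = (8, 8)
    clahe_clip: float = 0.01
    clahe_nbins: int = 256
    wiener_window: int = 3
    gauss_sigma: float = 0.5

    def __post_init__(self) -> None:
        if not (0 <= self.sat_low_frac < 0.5 and 0 <= self.sat_high_frac < 0.5):
            raise ValueError("saturation fractions must lie in [0, 0.5)")
        if self.wiener_window < 3 or self.wiener_window % 2 == 0:
            raise ValueError("wiener_window must be odd and >= 3")
        if self.gauss_sigma <= 0:
            raise ValueError("gauss_sigma must be positive")
        if self.clahe_clip <= 0 or self.clahe_clip > 1:
            raise ValueError("clahe_clip must lie in (0, 1]")


def saturate_rescale(img: Image2D, low_frac: float = 0.01, high_frac: float = 0.01) -> Image2D:
    """Linearly map the [low_frac, 1-high_frac] intensity quantiles onto the
    full dynamic range, clipping values outside.

    Quantiles use linear interpolation. A constant image (degenerate
    quantiles) is returned unchanged.
    """
    x = img.astype_float()
    q_low = float(np.quantile(x, low_frac))
    q_high = float(np.quantile(x, 1.0 - high_frac))
    if q_high <= q_low:
        logger.info("saturate_rescale: degenerate quantiles (q_low == q_high); image unchanged")
        return img.with_pixels(x)
    out = (x - q_low) / (q_high - q_low) * img.max_value
    return img.with_pixels(np.clip(out, 0.0, img.max_value))


def _clahe_tile_luts(x: np.ndarray, tile_shape: tuple[int, int], n_tiles: tuple[int, int],
                     clip: float, nbins: int, full_scale: float) -> np.ndarray:
    """Per-tile clipped-histogram equalization lookup tables.

    Counts above ``clip * tile_pixel_count`` are clipped and the excess is
    redistributed uniformly over all bins; the LUT maps a histogram bin to
    ``full_scale * cdf``.
    """
    th, tw = tile_shape
    tr, tc = n_tiles
    npix = th * tw
    clip_count = max(clip * npix, 1.0)
    bins = np.clip((x / full_scale * nbins).astype(np.intp), 0, nbins - 1)
    luts = np.empty((tr, tc, nbins), dtype=np.float64)
    for r in range(tr):
        for c in range(tc):
            tile = bins[r * th:(r + 1) * th, c * tw:(c + 1) * tw]
            hist = np.bincount(tile.ravel(), minlength=nbins).astype(np.float64)
            excess = np.sum(np.maximum(hist - clip_count, 0.0))
            hist = np.minimum(hist, clip_count) + excess / nbins
            cdf = np.cumsum(hist) / npix
            luts[r, c] = full_scale * cdf
    return luts


def clahe(img: Image2D, tiles: tuple[int, int] = (8, 8), clip: float = 0.01,
          nbins: int = 256) -> Image2D:
    """Contrast-limited adaptive histogram equalization.

    The image is divided into a ``tiles`` grid; each tile's histogram is
    clipped at ``clip`` times the tile pixel count with the excess spread
    uniformly, equalized to the full dynamic range, and the per-tile
    mappings are blended by bilinear interpolation between tile centers.
    ``clip=1.0`` reduces to plain (unclipped) adaptive equalization.
    """
    tr, tc = tiles
    h, w = img.shape
    if tr > h or tc > w:
        warnings.warn("CLAHE tiling larger than image; falling back to a single tile")
        tr, tc = 1, 1
    x = img.astype_float()
    full_scale = float(img.max_value)

    # pad symmetrically so the grid divides the image exactly
    th = -(-h // tr)
    tw = -(-w // tc)
    pad_h, pad_w = th * tr - h, tw * tc - w
    xp = np.pad(x, ((0, pad_h), (0, pad_w)), mode="symmetric")

    luts = _clahe_tile_luts(xp, (th, tw), (tr, tc), clip, nbins, full_scale)
    bins = np.clip((xp / full_scale * nbins).astype(np.intp), 0, nbins - 1)

    rows = np.arange(xp.shape[0], dtype=np.float64)
    cols = np.arange(xp.shape[1], dtype=np.float64)
    # fractional position of each pixel relative to the tile-center grid
    fr = np.clip((rows - (th - 1) / 2.0) / th, 0.0, tr - 1.0)
    fc = np.clip((cols - (tw - 1) / 2.0) / tw, 0.0, tc - 1.0)
    r0 = np.minimum(fr.astype(np.intp), tr - 1)
    c0 = np.minimum(fc.astype(np.intp), tc - 1)
    r1 = np.minimum(r0 + 1, tr - 1)
    c1 = np.minimum(c0 + 1, tc - 1)
    wr = (fr - r0)[:, None]
    wc = (fc - c0)[None, :]

    R0 = r0[:, None]
    R1 = r1[:, None]
    C0 = c0[None, :]
    C1 = c1[None, :]
    v00 = luts[np.broadcast_to(R0, bins.shape), np.broadcast_to(C0, bins.shape), bins]
    v01 = luts[np.broadcast_to(R0, bins.shape), np.broadcast_to(C1, bins.shape), bins]
    v10 = luts[np.broadcast_to(R1, bins.shape), np.broadcast_to(C0, bins.shape), bins]
    v11 = luts[np.broadcast_to(R1, bins.shape), np.broadcast_to(C1, bins.shape), bins]
    out = ((1 - wr) * ((1 - wc) * v00 + wc * v01) + wr * ((1 - wc) * v10 + wc * v11))
    return img.with_pixels(np.clip(out[:h, :w], 0.0, full_scale))


def wiener_adaptive(img: Image2D, window: int = 3) -> Image2D:
    """Pixel-wise adaptive low-pass Wiener filter.

    Uses local mean mu and variance s2 over a ``window`` x ``window``
    neighborhood (symmetric boundary padding) and the noise power nu2
    estimated as the mean of all local variances:

        out = mu + max(s2 - nu2, 0) / max(s2, nu2) * (x - mu)

    Where both s2 and nu2 vanish the output is the local mean.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be odd and >= 3")
    x = img.astype_float()
    mu = ndimage.uniform_filter(x, size=window, mode="reflect")
    m2 = ndimage.uniform_filter(x * x, size=window, mode="reflect")
    s2 = np.maximum(m2 - mu * mu, 0.0)
    nu2 = float(np.mean(s2))
    denom = np.maximum(s2, nu2)
    gain = np.divide(np.maximum(s2 - nu2, 0.0), denom,
                     out=np.zeros_like(s2), where=denom > 0)
    return img.with_pixels(np.clip(mu + gain * (x - mu), 0.0, img.max_value))


def gaussian_smooth(img: Image2D, sigma: float = 0.5) -> Image2D:
    """Gaussian smoothing with a normalized kernel truncated at 4 sigma,
    symmetric boundary handling; conserves mean intensity."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    out = ndimage.gaussian_filter(img.astype_float(), sigma=sigma,
                                  mode="reflect", truncate=4.0)
    return img.with_pixels(np.clip(out, 0.0, img.max_value))


def preprocess_image(img: Image2D, config: PreprocessConfig | None = None) -> Image2D:
    """Run the full chain and re-quantize to the input bit depth."""
    cfg = config or PreprocessConfig()
    out = saturate_rescale(img, cfg.sat_low_frac, cfg.sat_high_frac)
    out = clahe(out, cfg.clahe_tiles, cfg.clahe_clip, cfg.clahe_nbins)
    out = wiener_adaptive(out, cfg.wiener_window)
    out = gaussian_smooth(out, cfg.gauss_sigma)
    dtype = np.uint8 if img.bit_depth == 8 else np.uint16
    quantized = np.clip(np.rint(out.pixels), 0, img.max_value).astype(dtype)
    return img.with_pixels(quantized)


def extract_rois(img: Image2D, centers_or_grid, size: int = 69) -> list[Image2D]:
    """Extract ``size`` x ``size`` crops, never padding.

    ``centers_or_grid`` is either a list of (row, col) ROI centers or the
    string ``"grid"`` for all non-overlapping tiles that fit. Each requested
    ROI must lie fully inside the image.
    """
    h, w = img.shape
    if isinstance(centers_or_grid, str):
        if centers_or_grid != "grid":
            raise ValueError(f"unknown ROI layout {centers_or_grid!r}")
        half = size // 2
        centers = [(r + half, c + half)
                   for r in range(0, h - size + 1, size)
                   for c in range(0, w - size + 1, size)]
    else:
        centers = list(centers_or_grid)
    rois = []
    for (r, c) in centers:
        top, left = int(r) - size // 2, int(c) - size // 2
        if top < 0 or left < 0 or top + size > h or left + size > w:
            raise ValueError(f"ROI centered at ({r}, {c}) with size {size} "
                             f"exceeds image bounds {img.shape}")
        rois.append(img.with_pixels(img.pixels[top:top + size, left:left + size].copy()))
    return rois
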