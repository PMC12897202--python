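"""Gray-level size zone matrix and its 16 features.

Zones are 8-connected components of equal gray level; a single matrix is
built per ROI (no directionality).
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from ..quantize import QuantizedROI

EPS = 2.0**-52

_STRUCT8 = np.ones((3, 3), dtype=bool)


def glszm_matrix(q: QuantizedROI) -> np.ndarray:
    """Zone count matrix, shape (Ng, max_zone_size)."""
    n_pixels = q.n_masked
    P = np.zeros((q.Ng, n_pixels), dtype=np.float64)
    for level in np.unique(q.levels[q.mask]):
        lab, n = ndimage.label((q.levels == level) & q.mask, structure=_STRUCT8)
        if n == 0:
            continue
        sizes = np.bincount(lab.ravel())[1:]
        for s in sizes:
            P[level - 1, s - 1] += 1.0
    return P


def glszm_features(q: QuantizedROI) -> dict[str, float]:
    """16 size-zone features of the single zone matrix."""
    P = glszm_matrix(q)
    Nz = P.sum()
    if Nz == 0:
        raise ValueError("no zones found")
    Np = q.n_masked
    p = P / Nz
    Ng, Smax = P.shape
    i = np.arange(1, Ng + 1, dtype=np.float64)[:, None]
    j = np.arange(1, Smax + 1, dtype=np.float64)[None, :]

    pg = p.sum(axis=1)
    ps = p.sum(axis=0)
    mu_i = float(np.sum(i.ravel() * pg))
    mu_j = float(np.sum(j.ravel() * ps))

    return {
        "GrayLevelNonUniformity": float(np.sum(P.sum(axis=1) ** 2) / Nz),
        "GrayLevelNonUniformityNormalized": float(np.sum(pg**2)),
        "GrayLevelVariance": float(np.sum(pg * (i.ravel() - mu_i) ** 2)),
        "HighGrayLevelZoneEmphasis": float(np.sum(p * i**2)),
        "LargeAreaEmphasis": float(np.sum(p * j**2)),
        "LargeAreaHighGrayLevelEmphasis": float(np.sum(p * i**2 * j**2)),
        "LargeAreaLowGrayLevelEmphasis": float(np.sum(p * j**2 / i**2)),
        "LowGrayLevelZoneEmphasis": float(np.sum(p / i**2)),
        "SizeZoneNonUniformity": float(np.sum(P.sum(axis=0) ** 2) / Nz),
        "SizeZoneNonUniformityNormalized": float(np.sum(ps**2)),
        "SmallAreaEmphasis": float(np.sum(p / j**2)),
        "SmallAreaHighGrayLevelEmphasis": float(np.sum(p * i**2 / j**2)),
        "SmallAreaLowGrayLevelEmphasis": float(np.sum(p / (i**2 * j**2))),
        "ZoneEntropy": float(-np.sum(p * np.log2(p + EPS))),
        "ZonePercentage": float(Nz / Np),
        "ZoneVariance": float(np.sum(ps * (j.ravel() - mu_j) ** 2)),
    }
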