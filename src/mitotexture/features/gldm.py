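"""Gray-level dependence matrix and its 14 features.

A neighbor (8-connectivity, distance 1) is *dependent* on the center pixel
when the absolute gray-level difference is at most ``alpha``; the dependence
size of a pixel is 1 + the number of its dependent neighbors (the center
counts itself).
"""

from __future__ import annotations

import numpy as np

from ..quantize import QuantizedROI

EPS = 2.0**-52

_OFFSETS = ((-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1))


def gldm_matrix(q: QuantizedROI, alpha: float = 0.0) -> np.ndarray:
    """Dependence count matrix, shape (Ng, 9): level x dependence size."""
    lv = q.levels
    m = q.mask
    h, w = lv.shape
    dep = np.zeros((h, w), dtype=np.intp)
    for dr, dc in _OFFSETS:
        r0, r1 = max(0, -dr), min(h, h - dr)
        c0, c1 = max(0, -dc), min(w, w - dc)
        ok = (m[r0:r1, c0:c1] & m[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
              & (np.abs(lv[r0:r1, c0:c1] - lv[r0 + dr:r1 + dr, c0 + dc:c1 + dc]) <= alpha))
        dep[r0:r1, c0:c1] += ok
    jmax = len(_OFFSETS) + 1
    P = np.zeros((q.Ng, jmax), dtype=np.float64)
    np.add.at(P, (lv[m] - 1, dep[m]), 1.0)  # dependence size j = dep + 1 -> column dep
    return P


def gldm_features(q: QuantizedROI, alpha: float = 0.0) -> dict[str, float]:
    """14 dependence features of the single dependence matrix."""
    P = gldm_matrix(q, alpha)
    Nz = P.sum()
    if Nz == 0:
        raise ValueError("empty mask")
    p = P / Nz
    Ng, Dmax = P.shape
    i = np.arange(1, Ng + 1, dtype=np.float64)[:, None]
    j = np.arange(1, Dmax + 1, dtype=np.float64)[None, :]

    pg = p.sum(axis=1)
    pd = p.sum(axis=0)
    mu_i = float(np.sum(i.ravel() * pg))
    mu_j = float(np.sum(j.ravel() * pd))

    return {
        "DependenceEntropy": float(-np.sum(p * np.log2(p + EPS))),
        "DependenceNonUniformity": float(np.sum(P.sum(axis=0) ** 2) / Nz),
        "DependenceNonUniformityNormalized": float(np.sum(pd**2)),
        "DependenceVariance": float(np.sum(pd * (j.ravel() - mu_j) ** 2)),
        "GrayLevelNonUniformity": float(np.sum(P.sum(axis=1) ** 2) / Nz),
        "GrayLevelVariance": float(np.sum(pg * (i.ravel() - mu_i) ** 2)),
        "HighGrayLevelEmphasis": float(np.sum(p * i**2)),
        "LargeDependenceEmphasis": float(np.sum(p * j**2)),
        "LargeDependenceHighGrayLevelEmphasis": float(np.sum(p * i**2 * j**2)),
        "LargeDependenceLowGrayLevelEmphasis": float(np.sum(p * j**2 / i**2)),
        "LowGrayLevelEmphasis": float(np.sum(p / i**2)),
        "SmallDependenceEmphasis": float(np.sum(p / j**2)),
        "SmallDependenceHighGrayLevelEmphasis": float(np.sum(p * i**2 / j**2)),
        "SmallDependenceLowGrayLevelEmphasis": float(np.sum(p / (i**2 * j**2))),
    }
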