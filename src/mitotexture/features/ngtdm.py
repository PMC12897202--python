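"""Neighboring gray tone difference matrix and its 5 features.

For each gray level i the matrix stores the pixel count n_i, probability
p_i and the summed absolute difference s_i between the level and the mean
of its valid 8-neighbors. Degenerate denominators follow fixed conventions:
Coarseness is capped at 1e6 when sum(p_i s_i) = 0; Contrast, Busyness,
Complexity and Strength are 0 when their denominators vanish.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from ..quantize import QuantizedROI

COARSENESS_CAP = 1.0e6

_KERNEL = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]], dtype=np.float64)


def ngtdm_matrix(q: QuantizedROI) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(n_i, p_i, s_i) triplet over levels 1..Ng."""
    lv = q.levels.astype(np.float64)
    m = q.mask.astype(np.float64)
    neigh_sum = ndimage.convolve(lv * m, _KERNEL, mode="constant", cval=0.0)
    neigh_cnt = ndimage.convolve(m, _KERNEL, mode="constant", cval=0.0)
    has_neigh = q.mask & (neigh_cnt > 0)
    if not has_neigh.any():
        raise ValueError("no pixel has a valid neighbor")
    diff = np.zeros_like(lv)
    diff[has_neigh] = np.abs(lv[has_neigh] - neigh_sum[has_neigh] / neigh_cnt[has_neigh])

    n = np.zeros(q.Ng, dtype=np.float64)
    s = np.zeros(q.Ng, dtype=np.float64)
    idx = q.levels[has_neigh] - 1
    np.add.at(n, idx, 1.0)
    np.add.at(s, idx, diff[has_neigh])
    p = n / n.sum()
    return n, p, s


def ngtdm_features(q: QuantizedROI) -> dict[str, float]:
    """Coarseness, Contrast, Busyness, Complexity, Strength."""
    n, p, s = ngtdm_matrix(q)
    Np = n.sum()
    i = np.arange(1, q.Ng + 1, dtype=np.float64)
    present = p > 0
    Ngp = int(present.sum())

    ps = float(np.sum(p * s))
    coarseness = 1.0 / ps if ps > 0 else COARSENESS_CAP
    coarseness = min(coarseness, COARSENESS_CAP)

    if Ngp > 1:
        pi = p[present][:, None]
        pj = p[present][None, :]
        ii = i[present][:, None]
        jj = i[present][None, :]
        contrast = (float(np.sum(pi * pj * (ii - jj) ** 2)) / (Ngp * (Ngp - 1))
                    * float(np.sum(s)) / Np)
        busy_den = float(np.sum(np.abs(ii * pi - jj * pj)))
        busyness = ps / busy_den if busy_den > 0 else 0.0
        si = s[present][:, None]
        sj = s[present][None, :]
        complexity = float(np.sum(np.abs(ii - jj) * (pi * si + pj * sj) / (pi + pj))) / Np
        s_sum = float(np.sum(s))
        strength = float(np.sum((pi + pj) * (ii - jj) ** 2)) / s_sum if s_sum > 0 else 0.0
    else:
        contrast = 0.0
        busyness = 0.0
        complexity = 0.0
        strength = 0.0

    return {
        "Busyness": busyness,
        "Coarseness": coarseness,
        "Complexity": complexity,
        "Contrast": contrast,
        "Strength": strength,
    }
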