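"""Gray-level co-occurrence matrix and its 24 features.

Co-occurrences are counted for the four 2D offsets (0,1), (1,1), (1,0),
(1,-1) at a configurable distance, symmetrized (count + transpose) and
normalized per angle; features are computed per angle and averaged.
Entropies are base-2 with an epsilon guard inside logarithms.
"""

from __future__ import annotations

import numpy as np

from ..quantize import QuantizedROI

EPS = 2.0**-52

ANGLES = ((0, 1), (1, 1), (1, 0), (1, -1))


def glcm_matrix(q: QuantizedROI, distance: int = 1, symmetric: bool = True) -> np.ndarray:
    """Stack of per-angle co-occurrence count matrices, shape (4, Ng, Ng)."""
    return _cooccurrence_counts(q, distance, symmetric)


def _cooccurrence_counts(q: QuantizedROI, distance: int, symmetric: bool) -> np.ndarray:
    lv = q.levels
    m = q.mask
    h, w = lv.shape
    out = np.zeros((len(ANGLES), q.Ng, q.Ng), dtype=np.float64)
    for a, (dr, dc) in enumerate(ANGLES):
        dr_, dc_ = dr * distance, dc * distance
        r0, r1 = max(0, -dr_), min(h, h - dr_)
        c0, c1 = max(0, -dc_), min(w, w - dc_)
        src = lv[r0:r1, c0:c1]
        dst = lv[r0 + dr_:r1 + dr_, c0 + dc_:c1 + dc_]
        valid = m[r0:r1, c0:c1] & m[r0 + dr_:r1 + dr_, c0 + dc_:c1 + dc_]
        np.add.at(out[a], (src[valid] - 1, dst[valid] - 1), 1.0)
        if symmetric:
            out[a] = out[a] + out[a].T
    return out


def _features_one_angle(P: np.ndarray, Ng: int) -> dict[str, float]:
    i_idx = np.arange(1, Ng + 1, dtype=np.float64)
    I = i_idx[:, None] * np.ones((1, Ng))
    J = np.ones((Ng, 1)) * i_idx[None, :]

    px = P.sum(axis=1)
    py = P.sum(axis=0)
    ux = float(np.sum(i_idx * px))
    uy = float(np.sum(i_idx * py))
    sx = float(np.sqrt(np.sum(px * (i_idx - ux) ** 2)))
    sy = float(np.sqrt(np.sum(py * (i_idx - uy) ** 2)))

    # diagonal (difference) and cross-diagonal (sum) marginals
    k_diff = np.arange(Ng, dtype=np.float64)            # |i - j| = 0 .. Ng-1
    p_diff = np.zeros(Ng)
    k_sum = np.arange(2, 2 * Ng + 1, dtype=np.float64)  # i + j = 2 .. 2Ng
    p_sum = np.zeros(2 * Ng - 1)
    for d in range(Ng):
        p_diff[d] = np.sum(P[np.abs(I - J) == d])
    for s in range(2, 2 * Ng + 1):
        p_sum[s - 2] = np.sum(P[(I + J) == s])

    hxy = float(-np.sum(P * np.log2(P + EPS)))
    hx = float(-np.sum(px * np.log2(px + EPS)))
    hy = float(-np.sum(py * np.log2(py + EPS)))
    pxpy = np.outer(px, py)
    hxy1 = float(-np.sum(P * np.log2(pxpy + EPS)))
    hxy2 = float(-np.sum(pxpy * np.log2(pxpy + EPS)))

    if max(hx, hy) > 0:
        imc1 = (hxy - hxy1) / max(hx, hy)
    else:
        imc1 = 0.0
    imc2 = float(np.sqrt(max(1.0 - np.exp(-2.0 * (hxy2 - hxy)), 0.0)))

    da = float(np.sum(k_diff * p_diff))

    if sx > 0 and sy > 0:
        corr = (float(np.sum(I * J * P)) - ux * uy) / (sx * sy)
    else:
        corr = 1.0

    # MCC: sqrt of the second largest eigenvalue of
    # Q(i,j) = sum_k P(i,k) P(j,k) / (px(i) py(k))
    if Ng == 1:
        mcc = 1.0
    else:
        nz = py > 0
        px_safe = np.where(px > 0, px, 1.0)
        Q = (P[:, nz] / px_safe[:, None]) @ (P[:, nz] / py[nz][None, :]).T
        ev = np.sort(np.abs(np.linalg.eigvals(Q)))[::-1]
        mcc = float(np.sqrt(max(ev[1], 0.0))) if ev.size > 1 else 1.0

    return {
        "Autocorrelation": float(np.sum(I * J * P)),
        "ClusterProminence": float(np.sum((I + J - ux - uy) ** 4 * P)),
        "ClusterShade": float(np.sum((I + J - ux - uy) ** 3 * P)),
        "ClusterTendency": float(np.sum((I + J - ux - uy) ** 2 * P)),
        "Contrast": float(np.sum((I - J) ** 2 * P)),
        "Correlation": corr,
        "DifferenceAverage": da,
        "DifferenceEntropy": float(-np.sum(p_diff * np.log2(p_diff + EPS))),
        "DifferenceVariance": float(np.sum((k_diff - da) ** 2 * p_diff)),
        "Id": float(np.sum(p_diff / (1.0 + k_diff))),
        "Idm": float(np.sum(p_diff / (1.0 + k_diff**2))),
        "Idmn": float(np.sum(p_diff / (1.0 + (k_diff / Ng) ** 2))),
        "Idn": float(np.sum(p_diff / (1.0 + k_diff / Ng))),
        "Imc1": imc1,
        "Imc2": imc2,
        "InverseVariance": float(np.sum(p_diff[1:] / k_diff[1:] ** 2)) if Ng > 1 else 0.0,
        "JointAverage": ux,
        "JointEnergy": float(np.sum(P**2)),
        "JointEntropy": hxy,
        "MCC": mcc,
        "MaximumProbability": float(P.max()),
        "SumAverage": float(np.sum(k_sum * p_sum)),
        "SumEntropy": float(-np.sum(p_sum * np.log2(p_sum + EPS))),
        "SumSquares": float(np.sum((I - ux) ** 2 * P)),
    }


def glcm_features(q: QuantizedROI, distance: int = 1, symmetric: bool = True) -> dict[str, float]:
    """24 co-occurrence features averaged over the four angles."""
    counts = _cooccurrence_counts(q, distance, symmetric)
    per_angle: list[dict[str, float]] = []
    for a in range(counts.shape[0]):
        total = counts[a].sum()
        if total == 0:
            continue
        per_angle.append(_features_one_angle(counts[a] / total, q.Ng))
    if not per_angle:
        raise ValueError("no valid pixel pairs for GLCM")
    return {k: float(np.mean([f[k] for f in per_angle])) for k in per_angle[0]}
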