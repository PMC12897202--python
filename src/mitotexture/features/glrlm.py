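"""Gray-level run length matrix and its 16 features.

A run is a maximal collinear sequence of equal-level masked pixels. Matrices
are built over the four directions (0,1), (1,1), (1,0), (1,-1); features are
computed per direction and averaged.
"""

from __future__ import annotations

import numpy as np

from ..quantize import QuantizedROI

EPS = 2.0**-52

DIRECTIONS = ((0, 1), (1, 1), (1, 0), (1, -1))


def _lines(levels: np.ndarray, mask: np.ndarray, direction: tuple[int, int]):
    """Yield the 1D level sequences along ``direction`` (masked-out -> 0)."""
    lv = np.where(mask, levels, 0)
    dr, dc = direction
    if (dr, dc) == (0, 1):
        yield from lv
    elif (dr, dc) == (1, 0):
        yield from lv.T
    elif (dr, dc) == (1, 1):
        h, w = lv.shape
        for off in range(-(h - 1), w):
            yield np.diagonal(lv, offset=off)
    elif (dr, dc) == (1, -1):
        fl = lv[:, ::-1]
        h, w = fl.shape
        for off in range(-(h - 1), w):
            yield np.diagonal(fl, offset=off)
    else:
        raise ValueError(f"unsupported direction {direction}")


def _runs_in_line(line: np.ndarray):
    """(level, run_length) pairs of the maximal runs in one scan line."""
    line = np.asarray(line)
    if line.size == 0:
        return
    boundaries = np.flatnonzero(np.diff(line) != 0)
    starts = np.concatenate(([0], boundaries + 1))
    ends = np.concatenate((boundaries + 1, [line.size]))
    for s, e in zip(starts, ends):
        if line[s] > 0:
            yield int(line[s]), int(e - s)


def glrlm_matrix(q: QuantizedROI, direction: tuple[int, int]) -> np.ndarray:
    """Run-length count matrix (Ng x max_run) for one direction."""
    max_run = max(q.levels.shape)
    P = np.zeros((q.Ng, max_run), dtype=np.float64)
    for line in _lines(q.levels, q.mask, direction):
        for level, length in _runs_in_line(line):
            P[level - 1, length - 1] += 1.0
    return P


def _features_one_direction(P: np.ndarray, n_pixels: int) -> dict[str, float]:
    Nr = P.sum()
    if Nr == 0:
        raise ValueError("no runs found")
    p = P / Nr
    Ng, Lmax = P.shape
    i = np.arange(1, Ng + 1, dtype=np.float64)[:, None]
    j = np.arange(1, Lmax + 1, dtype=np.float64)[None, :]

    pg = p.sum(axis=1)   # marginal over run length
    pr = p.sum(axis=0)   # marginal over gray level
    mu_i = float(np.sum(i.ravel() * pg))
    mu_j = float(np.sum(j.ravel() * pr))

    return {
        "GrayLevelNonUniformity": float(np.sum(P.sum(axis=1) ** 2) / Nr),
        "GrayLevelNonUniformityNormalized": float(np.sum(pg**2)),
        "GrayLevelVariance": float(np.sum(pg * (i.ravel() - mu_i) ** 2)),
        "HighGrayLevelRunEmphasis": float(np.sum(p * i**2)),
        "LongRunEmphasis": float(np.sum(p * j**2)),
        "LongRunHighGrayLevelEmphasis": float(np.sum(p * i**2 * j**2)),
        "LongRunLowGrayLevelEmphasis": float(np.sum(p * j**2 / i**2)),
        "LowGrayLevelRunEmphasis": float(np.sum(p / i**2)),
        "RunEntropy": float(-np.sum(p * np.log2(p + EPS))),
        "RunLengthNonUniformity": float(np.sum(P.sum(axis=0) ** 2) / Nr),
        "RunLengthNonUniformityNormalized": float(np.sum(pr**2)),
        "RunPercentage": float(Nr / n_pixels),
        "RunVariance": float(np.sum(pr * (j.ravel() - mu_j) ** 2)),
        "ShortRunEmphasis": float(np.sum(p / j**2)),
        "ShortRunHighGrayLevelEmphasis": float(np.sum(p * i**2 / j**2)),
        "ShortRunLowGrayLevelEmphasis": float(np.sum(p / (i**2 * j**2))),
    }


def glrlm_features(q: QuantizedROI) -> dict[str, float]:
    """16 run-length features averaged over the four directions."""
    n_pixels = q.n_masked
    per_dir = [_features_one_direction(glrlm_matrix(q, d), n_pixels) for d in DIRECTIONS]
    return {k: float(np.mean([f[k] for f in per_dir])) for k in per_dir[0]}
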