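"""First-order (histogram) intensity statistics.

18 descriptors of the masked intensity distribution. Entropy and Uniformity
are computed on the discretized (gray-level) histogram; all moments are
population (biased) moments, kurtosis is non-excess (normal = 3), and
skewness/kurtosis are defined as 0 for a zero-variance ROI.
"""

from __future__ import annotations

import numpy as np

from ..quantize import QuantizedROI

EPS = 2.0**-52


def firstorder_features(x: np.ndarray, q: QuantizedROI,
                        pixel_area: float = 1.0) -> dict[str, float]:
    """Compute the 18 first-order features of the masked intensities ``x``.

    ``q`` supplies the discretized levels for the histogram-based Entropy
    and Uniformity; ``pixel_area`` scales Energy into TotalEnergy.
    """
    v = np.asarray(x, dtype=np.float64)[q.mask]
    if v.size == 0:
        raise ValueError("empty mask")
    n = v.size
    mean = float(v.mean())
    m2 = float(np.mean((v - mean) ** 2))
    if m2 > 0:
        m3 = float(np.mean((v - mean) ** 3))
        m4 = float(np.mean((v - mean) ** 4))
        skewness = m3 / m2**1.5
        kurtosis = m4 / m2**2
    else:
        skewness = 0.0
        kurtosis = 0.0

    p10, p25, p75, p90 = np.percentile(v, [10, 25, 75, 90])
    robust = v[(v >= p10) & (v <= p90)]
    rmad = float(np.mean(np.abs(robust - robust.mean()))) if robust.size else 0.0

    counts = np.bincount(q.levels[q.mask], minlength=q.Ng + 1)[1:]
    p = counts / n

    energy = float(np.sum(v**2))
    return {
        "10Percentile": float(p10),
        "90Percentile": float(p90),
        "Energy": energy,
        "Entropy": float(-np.sum(p * np.log2(p + EPS))),
        "InterquartileRange": float(p75 - p25),
        "Kurtosis": kurtosis,
        "Maximum": float(v.max()),
        "Mean": mean,
        "MeanAbsoluteDeviation": float(np.mean(np.abs(v - mean))),
        "Median": float(np.median(v)),
        "Minimum": float(v.min()),
        "Range": float(v.max() - v.min()),
        "RobustMeanAbsoluteDeviation": rmad,
        "RootMeanSquared": float(np.sqrt(np.mean(v**2))),
        "Skewness": skewness,
        "TotalEnergy": pixel_area * energy,
        "Uniformity": float(np.sum(p**2)),
        "Variance": m2,
    }
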