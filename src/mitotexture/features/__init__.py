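"""The 93-descriptor feature suite.

18 first-order + 24 GLCM + 14 GLDM + 16 GLRLM + 16 GLSZM + 5 NGTDM
features per ROI. Feature names are ``<family>_<feature>``; the canonical
column order is alphabetical within family with families ordered
firstorder, glcm, gldm, glrlm, glszm, ngtdm.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ..image import Image2D
from ..quantize import QuantizedROI, quantize_fixed_bin_width, quantize_fixed_bin_count
from .firstorder import firstorder_features
from .glcm import glcm_features, glcm_matrix
from .glrlm import glrlm_features, glrlm_matrix
from .glszm import glszm_features, glszm_matrix
from .ngtdm import ngtdm_features, ngtdm_matrix
from .gldm import gldm_features, gldm_matrix

_FIRSTORDER = ["10Percentile", "90Percentile", "Energy", "Entropy", "InterquartileRange",
               "Kurtosis", "Maximum", "Mean", "MeanAbsoluteDeviation", "Median", "Minimum",
               "Range", "RobustMeanAbsoluteDeviation", "RootMeanSquared", "Skewness",
               "TotalEnergy", "Uniformity", "Variance"]
_GLCM = ["Autocorrelation", "ClusterProminence", "ClusterShade", "ClusterTendency",
         "Contrast", "Correlation", "DifferenceAverage", "DifferenceEntropy",
         "DifferenceVariance", "Id", "Idm", "Idmn", "Idn", "Imc1", "Imc2",
         "InverseVariance", "JointAverage", "JointEnergy", "JointEntropy", "MCC",
         "MaximumProbability", "SumAverage", "SumEntropy", "SumSquares"]
_GLDM = ["DependenceEntropy", "DependenceNonUniformity", "DependenceNonUniformityNormalized",
         "DependenceVariance", "GrayLevelNonUniformity", "GrayLevelVariance",
         "HighGrayLevelEmphasis", "LargeDependenceEmphasis",
         "LargeDependenceHighGrayLevelEmphasis", "LargeDependenceLowGrayLevelEmphasis",
         "LowGrayLevelEmphasis", "SmallDependenceEmphasis",
         "SmallDependenceHighGrayLevelEmphasis", "SmallDependenceLowGrayLevelEmphasis"]
_GLRLM = ["GrayLevelNonUniformity", "GrayLevelNonUniformityNormalized", "GrayLevelVariance",
          "HighGrayLevelRunEmphasis", "LongRunEmphasis", "LongRunHighGrayLevelEmphasis",
          "LongRunLowGrayLevelEmphasis", "LowGrayLevelRunEmphasis", "RunEntropy",
          "RunLengthNonUniformity", "RunLengthNonUniformityNormalized", "RunPercentage",
          "RunVariance", "ShortRunEmphasis", "ShortRunHighGrayLevelEmphasis",
          "ShortRunLowGrayLevelEmphasis"]
_GLSZM = ["GrayLevelNonUniformity", "GrayLevelNonUniformityNormalized", "GrayLevelVariance",
          "HighGrayLevelZoneEmphasis", "LargeAreaEmphasis", "LargeAreaHighGrayLevelEmphasis",
          "LargeAreaLowGrayLevelEmphasis", "LowGrayLevelZoneEmphasis", "SizeZoneNonUniformity",
          "SizeZoneNonUniformityNormalized", "SmallAreaEmphasis",
          "SmallAreaHighGrayLevelEmphasis", "SmallAreaLowGrayLevelEmphasis", "ZoneEntropy",
          "ZonePercentage", "ZoneVariance"]
_NGTDM = ["Busyness", "Coarseness", "Complexity", "Contrast", "Strength"]

FAMILIES: dict[str, list[str]] = {
    "firstorder": _FIRSTORDER,
    "glcm": _GLCM,
    "gldm": _GLDM,
    "glrlm": _GLRLM,
    "glszm": _GLSZM,
    "ngtdm": _NGTDM,
}

FEATURE_NAMES: list[str] = [f"{fam}_{name}" for fam, names in FAMILIES.items()
                            for name in names]
assert len(FEATURE_NAMES) == 93


@dataclass
class FeatureConfig:
    """Settings shared by all texture-matrix computations."""

    quantization: str = "fixed_width"   # "fixed_width" | "fixed_count"
    bin_width: float = 25.0
    n_bins: int = 32
    glcm_distance: int = 1
    glcm_symmetric: bool = True
    gldm_alpha: float = 0.0

    def quantize(self, roi, mask=None) -> QuantizedROI:
        if self.quantization == "fixed_width":
            return quantize_fixed_bin_width(roi, self.bin_width, mask)
        if self.quantization == "fixed_count":
            return quantize_fixed_bin_count(roi, self.n_bins, mask)
        raise ValueError(f"unknown quantization dialect {self.quantization!r}")


@dataclass
class FeatureVector:
    """One ROI's 93 named feature values plus identifiers."""

    roi_id: str
    class_label: str
    values: dict[str, float]

    def __post_init__(self) -> None:
        missing = set(FEATURE_NAMES) - set(self.values)
        extra = set(self.values) - set(FEATURE_NAMES)
        if missing or extra:
            raise ValueError(f"feature roster mismatch: missing={sorted(missing)[:3]} "
                             f"extra={sorted(extra)[:3]}")

    def as_array(self) -> np.ndarray:
        return np.array([self.values[k] for k in FEATURE_NAMES])


@dataclass
class FeatureTable:
    """Feature vectors for a set of ROIs plus run metadata."""

    rows: list[FeatureVector]
    metadata: dict = field(default_factory=dict)

    def to_dataframe(self) -> pd.DataFrame:
        recs = [{"roi_id": r.roi_id, "class_label": r.class_label, **r.values}
                for r in self.rows]
        return pd.DataFrame(recs, columns=["roi_id", "class_label"] + FEATURE_NAMES)

    def to_csv(self, path: str | Path, sidecar: bool = True) -> None:
        path = Path(path)
        self.to_dataframe().to_csv(path, index=False)
        if sidecar:
            with open(path.with_suffix(".meta.json"), "w") as fh:
                json.dump(self.metadata, fh, indent=2, default=str)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, metadata: dict | None = None) -> "FeatureTable":
        rows = [FeatureVector(str(rec["roi_id"]), str(rec["class_label"]),
                              {k: float(rec[k]) for k in FEATURE_NAMES})
                for rec in df.to_dict("records")]
        return cls(rows, metadata or {})

    @classmethod
    def read_csv(cls, path: str | Path) -> "FeatureTable":
        return cls.from_dataframe(pd.read_csv(path))


def extract_all(roi: Image2D, config: FeatureConfig | None = None,
                roi_id: str = "", class_label: str = "", mask=None) -> FeatureVector:
    """Quantize once and run all six family extractors on one ROI."""
    cfg = config or FeatureConfig()
    try:
        q = cfg.quantize(roi, mask)
        pixel_area = (roi.pixel_size_um or 1.0) ** 2
        fam_values = {
            "firstorder": firstorder_features(roi.astype_float(), q, pixel_area),
            "glcm": glcm_features(q, cfg.glcm_distance, cfg.glcm_symmetric),
            "gldm": gldm_features(q, cfg.gldm_alpha),
            "glrlm": glrlm_features(q),
            "glszm": glszm_features(q),
            "ngtdm": ngtdm_features(q),
        }
    except Exception as exc:
        raise type(exc)(f"ROI {roi_id or '<unnamed>'}: {exc}") from exc
    values = {f"{fam}_{name}": fam_values[fam][name]
              for fam, names in FAMILIES.items() for name in names}
    return FeatureVector(roi_id, class_label, values)


__all__ = [
    "FAMILIES", "FEATURE_NAMES", "FeatureConfig", "FeatureVector", "FeatureTable",
    "extract_all", "firstorder_features",
    "glcm_features", "glcm_matrix", "glrlm_features", "glrlm_matrix",
    "glszm_features", "glszm_matrix", "ngtdm_features", "ngtdm_matrix",
    "gldm_features", "gldm_matrix",
]
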