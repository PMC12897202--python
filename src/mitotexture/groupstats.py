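"""Per-feature two-group statistics: MAD outlier replacement, Shapiro-Wilk
normality screening, and Welch / Mann-Whitney comparison.

The outlier rule flags values outside median +/- k * MAD with k = 2.1, where
MAD is the raw (unscaled) median absolute deviation; flagged values are
replaced with NaN so downstream sample sizes shrink accordingly. Each group
is screened for normality after outlier removal; the comparison uses Welch's
unequal-variance t-test when both groups look normal and the two-sided
Mann-Whitney U test otherwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class OutlierConfig:
    """MAD fence scaling factor; k = 2.1 keeps the rule sensitive but strict."""

    k: float = 2.1

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("k must be positive")


@dataclass
class FeatureComparison:
    """Outcome of one per-feature two-group comparison."""

    feature: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    normality_p_a: float | None
    normality_p_b: float | None
    test: str                  # "welch" | "mannwhitney" | "degenerate"
    statistic: float
    p_value: float
    significant: bool
    alpha: float = 0.05

    @property
    def stars(self) -> str:
        if self.p_value < 1e-4:
            return "****"
        if self.p_value < 1e-3:
            return "***"
        if self.p_value < 1e-2:
            return "**"
        if self.p_value < 0.05:
            return "*"
        return "ns"


def mad_outlier_replace(values, k: float = 2.1) -> np.ndarray:
    """Replace values outside median +/- k*MAD with NaN, preserving order.

    MAD is the raw median absolute deviation (no 1.4826 normal-consistency
    factor). A zero MAD keeps only exact-median values, with a warning.
    """
    x = np.asarray(values, dtype=np.float64).copy()
    finite = np.isfinite(x)
    if finite.sum() < 3:
        raise ValueError("need at least 3 finite values")
    med = float(np.median(x[finite]))
    mad = float(np.median(np.abs(x[finite] - med)))
    if mad == 0:
        if np.any(finite & (x != med)):
            warnings.warn("MAD is 0: only exact-median values retained")
        out = np.where(finite & (x != med), np.nan, x)
        return out
    lo, hi = med - k * mad, med + k * mad
    out = np.where(finite & ((x < lo) | (x > hi)), np.nan, x)
    return out


def normality_test(values) -> tuple[float, float]:
    """Shapiro-Wilk test; returns (W, p). Requires 3 <= n <= 5000 finite
    values and a non-constant sample."""
    x = np.asarray(values, dtype=np.float64)
    x = x[np.isfinite(x)]
    if not (3 <= x.size <= 5000):
        raise ValueError(f"Shapiro-Wilk needs 3..5000 values, got {x.size}")
    if np.ptp(x) == 0:
        raise ValueError("normality undefined for a constant sample")
    w, p = stats.shapiro(x)
    return float(w), float(p)


def compare_groups(a, b, alpha: float = 0.05, feature: str = "",
                   outliers: OutlierConfig | None = None,
                   force_test: str | None = None) -> FeatureComparison:
    """Two-group comparison of one feature.

    When ``outliers`` is given, MAD replacement is applied per group first.
    Both groups passing Shapiro-Wilk (p > alpha) selects Welch's t-test;
    otherwise the two-sided Mann-Whitney U (exact for combined n <= 20
    without ties, normal approximation with tie correction above).
    ``force_test`` ("welch" | "mannwhitney") overrides the automatic choice.
    """
    xa = np.asarray(a, dtype=np.float64)
    xb = np.asarray(b, dtype=np.float64)
    if outliers is not None:
        xa = mad_outlier_replace(xa, outliers.k)
        xb = mad_outlier_replace(xb, outliers.k)
    xa = xa[np.isfinite(xa)]
    xb = xb[np.isfinite(xb)]
    if xa.size < 3 or xb.size < 3:
        raise ValueError("each group needs >= 3 values after outlier removal")

    def _norm_p(x):
        try:
            return normality_test(x)[1]
        except ValueError:
            return None

    pa, pb = _norm_p(xa), _norm_p(xb)
    both_normal = pa is not None and pb is not None and pa > alpha and pb > alpha
    if force_test is not None:
        if force_test not in ("welch", "mannwhitney"):
            raise ValueError(f"unknown test {force_test!r}")
        both_normal = force_test == "welch"

    if force_test is None and np.ptp(xa) == 0 and np.ptp(xb) == 0 and xa[0] == xb[0]:
        test, stat, p = "degenerate", 0.0, 1.0
    elif both_normal:
        res = stats.ttest_ind(xa, xb, equal_var=False)
        test, stat, p = "welch", float(res.statistic), float(res.pvalue)
    else:
        n = xa.size + xb.size
        has_ties = np.unique(np.concatenate([xa, xb])).size < n
        method = "exact" if (n <= 20 and not has_ties) else "asymptotic"
        res = stats.mannwhitneyu(xa, xb, alternative="two-sided", method=method)
        test, stat, p = "mannwhitney", float(res.statistic), float(res.pvalue)

    return FeatureComparison(
        feature=feature, n_a=int(xa.size), n_b=int(xb.size),
        mean_a=float(xa.mean()), mean_b=float(xb.mean()),
        normality_p_a=pa, normality_p_b=pb,
        test=test, statistic=stat, p_value=p,
        significant=bool(p < alpha), alpha=alpha,
    )


def compare_feature_table(df: pd.DataFrame, group_column: str = "class_label",
                          groups: tuple[str, str] | None = None,
                          alpha: float = 0.05, k: float = 2.1,
                          bh_correction: bool = False) -> pd.DataFrame:
    """Run the full per-feature pipeline over a feature table.

    Compares two groups of ``group_column`` across every numeric feature
    column. No multiple-testing correction is applied by default; a
    Benjamini-Hochberg option exists but is off.
    """
    labels = df[group_column].unique()
    if groups is None:
        if len(labels) != 2:
            raise ValueError(f"need exactly 2 groups, found {sorted(map(str, labels))}")
        groups = tuple(sorted(labels))
    ga = df[df[group_column] == groups[0]]
    gb = df[df[group_column] == groups[1]]
    feat_cols = [c for c in df.columns
                 if c not in ("roi_id", group_column)
                 and pd.api.types.is_numeric_dtype(df[c])]
    cfg = OutlierConfig(k=k)
    rows = []
    for feat in feat_cols:
        cmpres = compare_groups(ga[feat].to_numpy(), gb[feat].to_numpy(),
                                alpha=alpha, feature=feat, outliers=cfg)
        rows.append({
            "feature": feat,
            f"mean_{groups[0]}": cmpres.mean_a, f"mean_{groups[1]}": cmpres.mean_b,
            "n_a": cmpres.n_a, "n_b": cmpres.n_b,
            "test": cmpres.test, "statistic": cmpres.statistic,
            "p": cmpres.p_value, "significant": cmpres.significant,
            "stars": cmpres.stars,
        })
    out = pd.DataFrame(rows)
    if bh_correction and len(out):
        order = np.argsort(out["p"].to_numpy())
        m = len(out)
        adj = np.empty(m)
        prev = 1.0
        for rank_from_end, i in enumerate(order[::-1]):
            rank = m - rank_from_end
            prev = min(prev, out["p"].iloc[i] * m / rank)
            adj[i] = prev
        out["p_adjusted"] = adj
        out["significant"] = out["p_adjusted"] < alpha
    return out
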