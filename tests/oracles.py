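"""Independent brute-force reference implementations of the 93 features.

Everything here is written as naive loops over pixels, pairs, runs, zones
and neighborhoods, deliberately sharing no code with the package. Used to
verify the vectorized implementations feature-by-feature.
"""

from __future__ import annotations

import math

import numpy as np

EPS = 2.0**-52


def log2e(v: float) -> float:
    return math.log2(v + EPS)


# ---------------------------------------------------------------- first order

def o_firstorder(x: np.ndarray, levels: np.ndarray, Ng: int, mask: np.ndarray,
                 pixel_area: float = 1.0) -> dict:
    v = sorted(float(x[r, c]) for r in range(x.shape[0]) for c in range(x.shape[1])
               if mask[r, c])
    n = len(v)
    mean = sum(v) / n
    m2 = sum((u - mean) ** 2 for u in v) / n
    m3 = sum((u - mean) ** 3 for u in v) / n
    m4 = sum((u - mean) ** 4 for u in v) / n
    skew = m3 / m2**1.5 if m2 > 0 else 0.0
    kurt = m4 / m2**2 if m2 > 0 else 0.0

    def pct(q):  # linear-interpolation percentile on the sorted copy
        h = (n - 1) * q / 100.0
        lo = int(math.floor(h))
        hi = min(lo + 1, n - 1)
        return v[lo] + (h - lo) * (v[hi] - v[lo])

    p10, p25, p75, p90 = pct(10), pct(25), pct(75), pct(90)
    robust = [u for u in v if p10 <= u <= p90]
    rmean = sum(robust) / len(robust)
    rmad = sum(abs(u - rmean) for u in robust) / len(robust)

    counts = [0] * Ng
    for r in range(x.shape[0]):
        for c in range(x.shape[1]):
            if mask[r, c]:
                counts[levels[r, c] - 1] += 1
    probs = [cnt / n for cnt in counts]
    energy = sum(u * u for u in v)
    med = (v[n // 2] if n % 2 else (v[n // 2 - 1] + v[n // 2]) / 2.0)
    return {
        "10Percentile": p10,
        "90Percentile": p90,
        "Energy": energy,
        "Entropy": -sum(p * log2e(p) for p in probs),
        "InterquartileRange": p75 - p25,
        "Kurtosis": kurt,
        "Maximum": v[-1],
        "Mean": mean,
        "MeanAbsoluteDeviation": sum(abs(u - mean) for u in v) / n,
        "Median": med,
        "Minimum": v[0],
        "Range": v[-1] - v[0],
        "RobustMeanAbsoluteDeviation": rmad,
        "RootMeanSquared": math.sqrt(energy / n),
        "Skewness": skew,
        "TotalEnergy": pixel_area * energy,
        "Uniformity": sum(p * p for p in probs),
    } | {"Variance": m2}


# ----------------------------------------------------------------------- GLCM

def o_glcm_counts(levels, mask, Ng, distance, angle):
    h, w = levels.shape
    dr, dc = angle[0] * distance, angle[1] * distance
    P = [[0.0] * Ng for _ in range(Ng)]
    for r in range(h):
        for c in range(w):
            rr, cc = r + dr, c + dc
            if 0 <= rr < h and 0 <= cc < w and mask[r, c] and mask[rr, cc]:
                i, j = levels[r, c] - 1, levels[rr, cc] - 1
                P[i][j] += 1.0
                P[j][i] += 1.0  # symmetric: count + transpose
    return P


def o_glcm(levels, mask, Ng, distance=1):
    feats = None
    n_angles = 0
    for angle in ((0, 1), (1, 1), (1, 0), (1, -1)):
        C = o_glcm_counts(levels, mask, Ng, distance, angle)
        total = sum(sum(row) for row in C)
        if total == 0:
            continue
        P = [[c / total for c in row] for row in C]
        f = _o_glcm_one(P, Ng)
        if feats is None:
            feats = {k: 0.0 for k in f}
        for k in f:
            feats[k] += f[k]
        n_angles += 1
    return {k: v / n_angles for k, v in feats.items()}


def _o_glcm_one(P, Ng):
    idx = list(range(1, Ng + 1))
    px = [sum(P[i - 1][j - 1] for j in idx) for i in idx]
    py = [sum(P[i - 1][j - 1] for i in idx) for j in idx]
    ux = sum(i * px[i - 1] for i in idx)
    uy = sum(j * py[j - 1] for j in idx)
    sx = math.sqrt(sum(px[i - 1] * (i - ux) ** 2 for i in idx))
    sy = math.sqrt(sum(py[j - 1] * (j - uy) ** 2 for j in idx))

    p_diff = [0.0] * Ng
    p_sum = [0.0] * (2 * Ng - 1)
    for i in idx:
        for j in idx:
            p_diff[abs(i - j)] += P[i - 1][j - 1]
            p_sum[i + j - 2] += P[i - 1][j - 1]

    hxy = -sum(P[i - 1][j - 1] * log2e(P[i - 1][j - 1]) for i in idx for j in idx)
    hx = -sum(p * log2e(p) for p in px)
    hy = -sum(p * log2e(p) for p in py)
    hxy1 = -sum(P[i - 1][j - 1] * log2e(px[i - 1] * py[j - 1]) for i in idx for j in idx)
    hxy2 = -sum(px[i - 1] * py[j - 1] * log2e(px[i - 1] * py[j - 1])
                for i in idx for j in idx)

    da = sum(k * p_diff[k] for k in range(Ng))
    corr = ((sum(i * j * P[i - 1][j - 1] for i in idx for j in idx) - ux * uy)
            / (sx * sy)) if sx > 0 and sy > 0 else 1.0

    if Ng == 1:
        mcc = 1.0
    else:
        Q = [[0.0] * Ng for _ in range(Ng)]
        for i in idx:
            for j in idx:
                acc = 0.0
                for k in idx:
                    if px[i - 1] > 0 and py[k - 1] > 0:
                        acc += P[i - 1][k - 1] * P[j - 1][k - 1] / (px[i - 1] * py[k - 1])
                Q[i - 1][j - 1] = acc
        ev = sorted(abs(e) for e in np.linalg.eigvals(np.array(Q)))[::-1]
        mcc = math.sqrt(max(ev[1], 0.0)) if len(ev) > 1 else 1.0

    return {
        "Autocorrelation": sum(i * j * P[i - 1][j - 1] for i in idx for j in idx),
        "ClusterProminence": sum((i + j - ux - uy) ** 4 * P[i - 1][j - 1]
                                 for i in idx for j in idx),
        "ClusterShade": sum((i + j - ux - uy) ** 3 * P[i - 1][j - 1]
                            for i in idx for j in idx),
        "ClusterTendency": sum((i + j - ux - uy) ** 2 * P[i - 1][j - 1]
                               for i in idx for j in idx),
        "Contrast": sum((i - j) ** 2 * P[i - 1][j - 1] for i in idx for j in idx),
        "Correlation": corr,
        "DifferenceAverage": da,
        "DifferenceEntropy": -sum(p * log2e(p) for p in p_diff),
        "DifferenceVariance": sum((k - da) ** 2 * p_diff[k] for k in range(Ng)),
        "Id": sum(p_diff[k] / (1.0 + k) for k in range(Ng)),
        "Idm": sum(p_diff[k] / (1.0 + k * k) for k in range(Ng)),
        "Idmn": sum(p_diff[k] / (1.0 + (k / Ng) ** 2) for k in range(Ng)),
        "Idn": sum(p_diff[k] / (1.0 + k / Ng) for k in range(Ng)),
        "Imc1": (hxy - hxy1) / max(hx, hy) if max(hx, hy) > 0 else 0.0,
        "Imc2": math.sqrt(max(1.0 - math.exp(-2.0 * (hxy2 - hxy)), 0.0)),
        "InverseVariance": sum(p_diff[k] / k**2 for k in range(1, Ng)),
        "JointAverage": ux,
        "JointEnergy": sum(P[i - 1][j - 1] ** 2 for i in idx for j in idx),
        "JointEntropy": hxy,
        "MCC": mcc,
        "MaximumProbability": max(max(row) for row in P),
        "SumAverage": sum(s * p_sum[s - 2] for s in range(2, 2 * Ng + 1)),
        "SumEntropy": -sum(p * log2e(p) for p in p_sum),
        "SumSquares": sum((i - ux) ** 2 * P[i - 1][j - 1] for i in idx for j in idx),
    }


# ---------------------------------------------------------------------- GLRLM

def o_runs(levels, mask, direction):
    """All (level, length) runs along one direction, by explicit walking."""
    h, w = levels.shape
    dr, dc = direction
    starts = []
    for r in range(h):
        for c in range(w):
            pr, pc = r - dr, c - dc
            if not (0 <= pr < h and 0 <= pc < w):
                starts.append((r, c))
    runs = []
    for r0, c0 in starts:
        seq = []
        r, c = r0, c0
        while 0 <= r < h and 0 <= c < w:
            seq.append(levels[r, c] if mask[r, c] else 0)
            r, c = r + dr, c + dc
        k = 0
        while k < len(seq):
            if seq[k] > 0:
                length = 1
                while k + length < len(seq) and seq[k + length] == seq[k]:
                    length += 1
                runs.append((seq[k], length))
                k += length
            else:
                k += 1
    return runs


def _o_rlm_features(runs, Ng, n_pixels):
    Nr = len(runs)
    Lmax = max(length for _, length in runs)
    P = [[0.0] * Lmax for _ in range(Ng)]
    for lvl, length in runs:
        P[lvl - 1][length - 1] += 1.0
    p = [[c / Nr for c in row] for row in P]
    pg = [sum(row) for row in p]
    pr = [sum(p[i][j] for i in range(Ng)) for j in range(Lmax)]
    mu_i = sum((i + 1) * pg[i] for i in range(Ng))
    mu_j = sum((j + 1) * pr[j] for j in range(Lmax))
    S = lambda f: sum(f(i + 1, j + 1) * p[i][j] for i in range(Ng) for j in range(Lmax))
    return {
        "GrayLevelNonUniformity": sum(sum(row) ** 2 for row in P) / Nr,
        "GrayLevelNonUniformityNormalized": sum(g * g for g in pg),
        "GrayLevelVariance": sum(pg[i] * (i + 1 - mu_i) ** 2 for i in range(Ng)),
        "HighGrayLevelRunEmphasis": S(lambda i, j: i * i),
        "LongRunEmphasis": S(lambda i, j: j * j),
        "LongRunHighGrayLevelEmphasis": S(lambda i, j: i * i * j * j),
        "LongRunLowGrayLevelEmphasis": S(lambda i, j: j * j / (i * i)),
        "LowGrayLevelRunEmphasis": S(lambda i, j: 1.0 / (i * i)),
        "RunEntropy": -sum(p[i][j] * log2e(p[i][j])
                           for i in range(Ng) for j in range(Lmax)),
        "RunLengthNonUniformity": sum(
            sum(P[i][j] for i in range(Ng)) ** 2 for j in range(Lmax)) / Nr,
        "RunLengthNonUniformityNormalized": sum(r * r for r in pr),
        "RunPercentage": Nr / n_pixels,
        "RunVariance": sum(pr[j] * (j + 1 - mu_j) ** 2 for j in range(Lmax)),
        "ShortRunEmphasis": S(lambda i, j: 1.0 / (j * j)),
        "ShortRunHighGrayLevelEmphasis": S(lambda i, j: i * i / (j * j)),
        "ShortRunLowGrayLevelEmphasis": S(lambda i, j: 1.0 / (i * i * j * j)),
    }


def o_glrlm(levels, mask, Ng):
    n_pixels = int(mask.sum())
    dirs = ((0, 1), (1, 1), (1, 0), (1, -1))
    per_dir = [_o_rlm_features(o_runs(levels, mask, d), Ng, n_pixels) for d in dirs]
    return {k: sum(f[k] for f in per_dir) / len(per_dir) for k in per_dir[0]}


# ---------------------------------------------------------------------- GLSZM

def o_zones(levels, mask):
    """(level, size) of every 8-connected equal-level zone, by flood fill."""
    h, w = levels.shape
    seen = [[False] * w for _ in range(h)]
    zones = []
    for r in range(h):
        for c in range(w):
            if mask[r, c] and not seen[r][c]:
                lvl = levels[r, c]
                stack = [(r, c)]
                seen[r][c] = True
                size = 0
                while stack:
                    y, x = stack.pop()
                    size += 1
                    for dy in (-1, 0, 1):
                        for dx in (-1, 0, 1):
                            ny, nx = y + dy, x + dx
                            if (0 <= ny < h and 0 <= nx < w and mask[ny, nx]
                                    and not seen[ny][nx] and levels[ny, nx] == lvl):
                                seen[ny][nx] = True
                                stack.append((ny, nx))
                zones.append((lvl, size))
    return zones


def o_glszm(levels, mask, Ng):
    zones = o_zones(levels, mask)
    Nz = len(zones)
    Np = int(mask.sum())
    Smax = max(s for _, s in zones)
    P = [[0.0] * Smax for _ in range(Ng)]
    for lvl, s in zones:
        P[lvl - 1][s - 1] += 1.0
    p = [[c / Nz for c in row] for row in P]
    pg = [sum(row) for row in p]
    ps = [sum(p[i][j] for i in range(Ng)) for j in range(Smax)]
    mu_i = sum((i + 1) * pg[i] for i in range(Ng))
    mu_j = sum((j + 1) * ps[j] for j in range(Smax))
    S = lambda f: sum(f(i + 1, j + 1) * p[i][j] for i in range(Ng) for j in range(Smax))
    return {
        "GrayLevelNonUniformity": sum(sum(row) ** 2 for row in P) / Nz,
        "GrayLevelNonUniformityNormalized": sum(g * g for g in pg),
        "GrayLevelVariance": sum(pg[i] * (i + 1 - mu_i) ** 2 for i in range(Ng)),
        "HighGrayLevelZoneEmphasis": S(lambda i, j: i * i),
        "LargeAreaEmphasis": S(lambda i, j: j * j),
        "LargeAreaHighGrayLevelEmphasis": S(lambda i, j: i * i * j * j),
        "LargeAreaLowGrayLevelEmphasis": S(lambda i, j: j * j / (i * i)),
        "LowGrayLevelZoneEmphasis": S(lambda i, j: 1.0 / (i * i)),
        "SizeZoneNonUniformity": sum(
            sum(P[i][j] for i in range(Ng)) ** 2 for j in range(Smax)) / Nz,
        "SizeZoneNonUniformityNormalized": sum(z * z for z in ps),
        "SmallAreaEmphasis": S(lambda i, j: 1.0 / (j * j)),
        "SmallAreaHighGrayLevelEmphasis": S(lambda i, j: i * i / (j * j)),
        "SmallAreaLowGrayLevelEmphasis": S(lambda i, j: 1.0 / (i * i * j * j)),
        "ZoneEntropy": -sum(p[i][j] * log2e(p[i][j])
                            for i in range(Ng) for j in range(Smax)),
        "ZonePercentage": Nz / Np,
        "ZoneVariance": sum(ps[j] * (j + 1 - mu_j) ** 2 for j in range(Smax)),
    }


# ---------------------------------------------------------------------- NGTDM

def o_ngtdm_triplet(levels, mask, Ng):
    h, w = levels.shape
    n = [0.0] * Ng
    s = [0.0] * Ng
    for r in range(h):
        for c in range(w):
            if not mask[r, c]:
                continue
            neigh = []
            for dy in (-1, 0, 1):
                for dx in (-1, 0, 1):
                    if dy == 0 and dx == 0:
                        continue
                    ny, nx = r + dy, c + dx
                    if 0 <= ny < h and 0 <= nx < w and mask[ny, nx]:
                        neigh.append(levels[ny, nx])
            if not neigh:
                continue
            i = levels[r, c]
            n[i - 1] += 1
            s[i - 1] += abs(i - sum(neigh) / len(neigh))
    Np = sum(n)
    p = [ni / Np for ni in n]
    return n, p, s


def o_ngtdm(levels, mask, Ng):
    n, p, s = o_ngtdm_triplet(levels, mask, Ng)
    Np = sum(n)
    present = [i for i in range(Ng) if p[i] > 0]
    Ngp = len(present)
    ps = sum(p[i] * s[i] for i in range(Ng))
    coarseness = min(1.0 / ps if ps > 0 else 1.0e6, 1.0e6)
    if Ngp > 1:
        contrast = (sum(p[i] * p[j] * (i - j) ** 2 for i in present for j in present)
                    / (Ngp * (Ngp - 1)) * sum(s) / Np)
        busy_den = sum(abs((i + 1) * p[i] - (j + 1) * p[j])
                       for i in present for j in present)
        busyness = ps / busy_den if busy_den > 0 else 0.0
        complexity = sum(abs(i - j) * (p[i] * s[i] + p[j] * s[j]) / (p[i] + p[j])
                         for i in present for j in present) / Np
        s_sum = sum(s)
        strength = (sum((p[i] + p[j]) * (i - j) ** 2 for i in present for j in present)
                    / s_sum) if s_sum > 0 else 0.0
    else:
        contrast = busyness = complexity = strength = 0.0
    return {"Busyness": busyness, "Coarseness": coarseness,
            "Complexity": complexity, "Contrast": contrast, "Strength": strength}


# ----------------------------------------------------------------------- GLDM

def o_gldm(levels, mask, Ng, alpha=0.0):
    h, w = levels.shape
    pairs = []
    for r in range(h):
        for c in range(w):
            if not mask[r, c]:
                continue
            d = 0
            for dy in (-1, 0, 1):
                for dx in (-1, 0, 1):
                    if dy == 0 and dx == 0:
                        continue
                    ny, nx = r + dy, c + dx
                    if (0 <= ny < h and 0 <= nx < w and mask[ny, nx]
                            and abs(int(levels[ny, nx]) - int(levels[r, c])) <= alpha):
                        d += 1
            pairs.append((levels[r, c], d + 1))
    Nz = len(pairs)
    Dmax = 9
    P = [[0.0] * Dmax for _ in range(Ng)]
    for lvl, j in pairs:
        P[lvl - 1][j - 1] += 1.0
    p = [[c / Nz for c in row] for row in P]
    pg = [sum(row) for row in p]
    pd = [sum(p[i][j] for i in range(Ng)) for j in range(Dmax)]
    mu_i = sum((i + 1) * pg[i] for i in range(Ng))
    mu_j = sum((j + 1) * pd[j] for j in range(Dmax))
    S = lambda f: sum(f(i + 1, j + 1) * p[i][j] for i in range(Ng) for j in range(Dmax))
    return {
        "DependenceEntropy": -sum(p[i][j] * log2e(p[i][j])
                                  for i in range(Ng) for j in range(Dmax)),
        "DependenceNonUniformity": sum(
            sum(P[i][j] for i in range(Ng)) ** 2 for j in range(Dmax)) / Nz,
        "DependenceNonUniformityNormalized": sum(d * d for d in pd),
        "DependenceVariance": sum(pd[j] * (j + 1 - mu_j) ** 2 for j in range(Dmax)),
        "GrayLevelNonUniformity": sum(sum(row) ** 2 for row in P) / Nz,
        "GrayLevelVariance": sum(pg[i] * (i + 1 - mu_i) ** 2 for i in range(Ng)),
        "HighGrayLevelEmphasis": S(lambda i, j: i * i),
        "LargeDependenceEmphasis": S(lambda i, j: j * j),
        "LargeDependenceHighGrayLevelEmphasis": S(lambda i, j: i * i * j * j),
        "LargeDependenceLowGrayLevelEmphasis": S(lambda i, j: j * j / (i * i)),
        "LowGrayLevelEmphasis": S(lambda i, j: 1.0 / (i * i)),
        "SmallDependenceEmphasis": S(lambda i, j: 1.0 / (j * j)),
        "SmallDependenceHighGrayLevelEmphasis": S(lambda i, j: i * i / (j * j)),
        "SmallDependenceLowGrayLevelEmphasis": S(lambda i, j: 1.0 / (i * i * j * j)),
    }


def o_all_features(x: np.ndarray, levels: np.ndarray, Ng: int, mask: np.ndarray,
                   pixel_area: float = 1.0, alpha: float = 0.0) -> dict:
    """All 93 features as a flat {family_Feature: value} dict."""
    out = {}
    for fam, d in (("firstorder", o_firstorder(x, levels, Ng, mask, pixel_area)),
                   ("glcm", o_glcm(levels, mask, Ng)),
                   ("gldm", o_gldm(levels, mask, Ng, alpha)),
                   ("glrlm", o_glrlm(levels, mask, Ng)),
                   ("glszm", o_glszm(levels, mask, Ng)),
                   ("ngtdm", o_ngtdm(levels, mask, Ng))):
        for k, v in d.items():
            out[f"{fam}_{k}"] = v
    return out


# ------------------------------------------------------- preprocessing oracles

def o_wiener(x: np.ndarray, window: int) -> np.ndarray:
    """Direct loop implementation of the adaptive Wiener formula with
    symmetric padding."""
    half = window // 2
    xp = np.pad(x.astype(float), half, mode="symmetric")
    h, w = x.shape
    mu = np.zeros((h, w))
    s2 = np.zeros((h, w))
    for r in range(h):
        for c in range(w):
            patch = xp[r:r + window, c:c + window]
            mu[r, c] = patch.mean()
            s2[r, c] = patch.var()
    nu2 = s2.mean()
    out = np.zeros((h, w))
    for r in range(h):
        for c in range(w):
            denom = max(s2[r, c], nu2)
            gain = max(s2[r, c] - nu2, 0.0) / denom if denom > 0 else 0.0
            out[r, c] = mu[r, c] + gain * (x[r, c] - mu[r, c])
    return out


def o_tile_equalize(x: np.ndarray, tiles: tuple[int, int], nbins: int,
                    full_scale: float) -> np.ndarray:
    """Plain per-tile histogram equalization (no clipping, no interpolation):
    returns the per-tile LUT stack used to cross-check the CLAHE mappings."""
    tr, tc = tiles
    th = -(-x.shape[0] // tr)
    tw = -(-x.shape[1] // tc)
    xp = np.pad(x.astype(float), ((0, th * tr - x.shape[0]), (0, tw * tc - x.shape[1])),
                mode="symmetric")
    luts = np.zeros((tr, tc, nbins))
    for r in range(tr):
        for c in range(tc):
            tile = xp[r * th:(r + 1) * th, c * tw:(c + 1) * tw]
            bins = np.clip((tile / full_scale * nbins).astype(int), 0, nbins - 1)
            hist = [0.0] * nbins
            for b in bins.ravel():
                hist[b] += 1
            cdf = 0.0
            for k in range(nbins):
                cdf += hist[k] / tile.size
                luts[r, c, k] = full_scale * cdf
    return luts
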