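"""Brute-force reference implementations used only as test oracles.

Everything here is written as plain enumeration (explicit loops over voxel
pairs, runs, zones, neighbourhoods and coalitions) so that it shares no code
path with the package's vectorised implementations.
"""

from __future__ import annotations

import math
from collections import defaultdict

import numpy as np

NEIGHBOURS_26 = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
]
DIRECTIONS_13 = [d for d in NEIGHBOURS_26 if d > (0, 0, 0)]


def quantise(values, mask, ng):
    x = values[mask]
    m, M = x.min(), x.max()
    levels = np.zeros(values.shape, dtype=int)
    if M == m:
        levels[mask] = 1
        return levels
    for idx in zip(*np.nonzero(mask)):
        lv = int(np.floor(ng * (values[idx] - m) / (M - m))) + 1
        levels[idx] = min(lv, ng)
    return levels


def _inside(shape, p):
    return all(0 <= c < s for c, s in zip(p, shape))


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------


def glcm_matrix_direction(levels, mask, ng, off):
    """Symmetrised co-occurrence counts for one direction (both orders)."""
    P = np.zeros((ng, ng))
    for p in zip(*np.nonzero(mask)):
        for o in (off, tuple(-c for c in off)):
            qx = tuple(c + d for c, d in zip(p, o))
            if _inside(mask.shape, qx) and mask[qx]:
                P[levels[p] - 1, levels[qx] - 1] += 1
    return P


def glcm_features_oracle(levels, mask, ng):
    per_dir = []
    for off in DIRECTIONS_13:
        P = glcm_matrix_direction(levels, mask, ng, off)
        if P.sum() == 0:
            continue
        P = P / P.sum()
        per_dir.append(_glcm_from_matrix(P, ng))
    keys = per_dir[0].keys()
    return {k: float(np.mean([d[k] for d in per_dir])) for k in keys}


def _glcm_from_matrix(P, ng):
    px = P.sum(axis=1)
    py = P.sum(axis=0)
    mux = sum((i + 1) * px[i] for i in range(ng))
    muy = sum((j + 1) * py[j] for j in range(ng))
    sigx = math.sqrt(sum((i + 1 - mux) ** 2 * px[i] for i in range(ng)))
    sigy = math.sqrt(sum((j + 1 - muy) ** 2 * py[j] for j in range(ng)))

    psum = defaultdict(float)
    pdiff = defaultdict(float)
    for i in range(ng):
        for j in range(ng):
            if P[i, j] > 0:
                psum[i + j + 2] += P[i, j]
                pdiff[abs(i - j)] += P[i, j]

    f = {}
    f["Autocorrelation"] = sum(
        (i + 1) * (j + 1) * P[i, j] for i in range(ng) for j in range(ng)
    )
    for power, name in ((2, "ClusterTendency"), (3, "ClusterShade"), (4, "ClusterProminence")):
        f[name] = sum(
            (i + 1 + j + 1 - mux - muy) ** power * P[i, j]
            for i in range(ng) for j in range(ng)
        )
    f["Contrast"] = sum((i - j) ** 2 * P[i, j] for i in range(ng) for j in range(ng))
    if sigx > 0 and sigy > 0:
        f["Correlation"] = (
            sum((i + 1) * (j + 1) * P[i, j] for i in range(ng) for j in range(ng))
            - mux * muy
        ) / (sigx * sigy)
    else:
        f["Correlation"] = 1.0
    da = sum(k * v for k, v in pdiff.items())
    f["DifferenceAverage"] = da
    f["DifferenceEntropy"] = -sum(v * math.log2(v) for v in pdiff.values() if v > 0)
    f["DifferenceVariance"] = sum((k - da) ** 2 * v for k, v in pdiff.items())
    f["Id"] = sum(P[i, j] / (1 + abs(i - j)) for i in range(ng) for j in range(ng))
    f["Idm"] = sum(P[i, j] / (1 + (i - j) ** 2) for i in range(ng) for j in range(ng))
    f["Idmn"] = sum(
        P[i, j] / (1 + ((i - j) / ng) ** 2) for i in range(ng) for j in range(ng)
    )
    f["Idn"] = sum(P[i, j] / (1 + abs(i - j) / ng) for i in range(ng) for j in range(ng))
    hxy = -sum(
        P[i, j] * math.log2(P[i, j])
        for i in range(ng) for j in range(ng) if P[i, j] > 0
    )
    hx = -sum(px[i] * math.log2(px[i]) for i in range(ng) if px[i] > 0)
    hy = -sum(py[j] * math.log2(py[j]) for j in range(ng) if py[j] > 0)
    hxy1 = -sum(
        P[i, j] * math.log2(px[i] * py[j])
        for i in range(ng) for j in range(ng) if P[i, j] > 0 and px[i] * py[j] > 0
    )
    hxy2 = -sum(
        px[i] * py[j] * math.log2(px[i] * py[j])
        for i in range(ng) for j in range(ng) if px[i] * py[j] > 0
    )
    f["Imc1"] = (hxy - hxy1) / max(hx, hy) if max(hx, hy) > 0 else 0.0
    f["Imc2"] = math.sqrt(max(0.0, 1.0 - math.exp(-2.0 * (hxy2 - hxy))))
    f["InverseVariance"] = sum(
        P[i, j] / (i - j) ** 2 for i in range(ng) for j in range(ng) if i != j
    )
    f["JointAverage"] = mux
    f["JointEnergy"] = sum(P[i, j] ** 2 for i in range(ng) for j in range(ng))
    f["JointEntropy"] = hxy
    f["MaximumProbability"] = P.max()

    present = [i for i in range(ng) if px[i] > 0]
    if len(present) > 1:
        Q = np.zeros((len(present), len(present)))
        for a, i in enumerate(present):
            for b, j in enumerate(present):
                Q[a, b] = sum(
                    P[i, k] * P[j, k] / (px[i] * py[k]) for k in present if py[k] > 0
                )
        # Q has a real spectrum (it is similar to the symmetric matrix
        # D^1/2 Q D^-1/2); apply that similarity before the eigensolve so
        # the oracle's eigenvalues carry symmetric-solver accuracy
        d = np.array([px[i] for i in present])
        M = np.sqrt(d)[:, None] * Q / np.sqrt(d)[None, :]
        ev = sorted(np.linalg.eigvalsh((M + M.T) / 2.0))
        f["MCC"] = math.sqrt(min(max(ev[-2], 0.0), 1.0))
    else:
        f["MCC"] = 1.0
    f["SumAverage"] = sum(k * v for k, v in psum.items())
    f["SumEntropy"] = -sum(v * math.log2(v) for v in psum.values() if v > 0)
    f["SumSquares"] = sum(
        (i + 1 - mux) ** 2 * P[i, j] for i in range(ng) for j in range(ng)
    )
    return f


# ---------------------------------------------------------------------------
# GLRLM
# ---------------------------------------------------------------------------


def runs_oracle(levels, mask, off):
    """All maximal runs (level, length) along one direction."""
    runs = []
    for p in zip(*np.nonzero(mask)):
        prev = tuple(c - d for c, d in zip(p, off))
        if _inside(mask.shape, prev) and mask[prev] and levels[prev] == levels[p]:
            continue  # not a run start
        length = 1
        cur = p
        while True:
            nxt = tuple(c + d for c, d in zip(cur, off))
            if _inside(mask.shape, nxt) and mask[nxt] and levels[nxt] == levels[cur]:
                length += 1
                cur = nxt
            else:
                break
        runs.append((levels[p], length))
    return runs


def glrlm_features_oracle(levels, mask, ng):
    n_vox = int(mask.sum())
    per_dir = []
    for off in DIRECTIONS_13:
        runs = runs_oracle(levels, mask, off)
        per_dir.append(_level_size_features(runs, n_vox, prefix="run"))
    keys = per_dir[0].keys()
    avg = {k: float(np.mean([d[k] for d in per_dir])) for k in keys}
    return {
        "GrayLevelNonUniformity": avg["gln"],
        "GrayLevelNonUniformityNormalized": avg["glnn"],
        "GrayLevelVariance": avg["glv"],
        "HighGrayLevelRunEmphasis": avg["high"],
        "LongRunEmphasis": avg["large"],
        "LongRunHighGrayLevelEmphasis": avg["largehigh"],
        "LongRunLowGrayLevelEmphasis": avg["largelow"],
        "LowGrayLevelRunEmphasis": avg["low"],
        "RunEntropy": avg["entropy"],
        "RunLengthNonUniformity": avg["sn"],
        "RunLengthNonUniformityNormalized": avg["snn"],
        "RunPercentage": avg["pct"],
        "RunVariance": avg["sv"],
        "ShortRunEmphasis": avg["small"],
        "ShortRunHighGrayLevelEmphasis": avg["smallhigh"],
        "ShortRunLowGrayLevelEmphasis": avg["smalllow"],
    }


def _level_size_features(pairs, n_vox, prefix):
    """Naive statistics over (level, size) multisets."""
    Ns = len(pairs)
    counts = defaultdict(float)
    for lv, sz in pairs:
        counts[(lv, sz)] += 1.0
    mu_i = sum(lv * c for (lv, _), c in counts.items()) / Ns
    mu_j = sum(sz * c for (_, sz), c in counts.items()) / Ns
    by_level = defaultdict(float)
    by_size = defaultdict(float)
    for (lv, sz), c in counts.items():
        by_level[lv] += c
        by_size[sz] += c
    return {
        "small": sum(c / sz**2 for (_, sz), c in counts.items()) / Ns,
        "large": sum(c * sz**2 for (_, sz), c in counts.items()) / Ns,
        "low": sum(c / lv**2 for (lv, _), c in counts.items()) / Ns,
        "high": sum(c * lv**2 for (lv, _), c in counts.items()) / Ns,
        "smalllow": sum(c / (lv**2 * sz**2) for (lv, sz), c in counts.items()) / Ns,
        "smallhigh": sum(c * lv**2 / sz**2 for (lv, sz), c in counts.items()) / Ns,
        "largelow": sum(c * sz**2 / lv**2 for (lv, sz), c in counts.items()) / Ns,
        "largehigh": sum(c * lv**2 * sz**2 for (lv, sz), c in counts.items()) / Ns,
        "gln": sum(v**2 for v in by_level.values()) / Ns,
        "glnn": sum(v**2 for v in by_level.values()) / Ns**2,
        "sn": sum(v**2 for v in by_size.values()) / Ns,
        "snn": sum(v**2 for v in by_size.values()) / Ns**2,
        "glv": sum(c / Ns * (lv - mu_i) ** 2 for (lv, _), c in counts.items()),
        "sv": sum(c / Ns * (sz - mu_j) ** 2 for (_, sz), c in counts.items()),
        "entropy": -sum(
            (c / Ns) * math.log2(c / Ns) for c in counts.values() if c > 0
        ),
        "pct": Ns / n_vox,
    }


# ---------------------------------------------------------------------------
# GLSZM (flood fill)
# ---------------------------------------------------------------------------


def zones_oracle(levels, mask):
    seen = set()
    zones = []
    for p in zip(*np.nonzero(mask)):
        if p in seen:
            continue
        lv = levels[p]
        stack = [p]
        seen.add(p)
        size = 0
        while stack:
            cur = stack.pop()
            size += 1
            for off in NEIGHBOURS_26:
                nb = tuple(c + d for c, d in zip(cur, off))
                if (
                    nb not in seen
                    and _inside(mask.shape, nb)
                    and mask[nb]
                    and levels[nb] == lv
                ):
                    seen.add(nb)
                    stack.append(nb)
        zones.append((lv, size))
    return zones


def glszm_features_oracle(levels, mask, ng):
    n_vox = int(mask.sum())
    g = _level_size_features(zones_oracle(levels, mask), n_vox, prefix="zone")
    return {
        "GrayLevelNonUniformity": g["gln"],
        "GrayLevelNonUniformityNormalized": g["glnn"],
        "GrayLevelVariance": g["glv"],
        "HighGrayLevelZoneEmphasis": g["high"],
        "LargeAreaEmphasis": g["large"],
        "LargeAreaHighGrayLevelEmphasis": g["largehigh"],
        "LargeAreaLowGrayLevelEmphasis": g["largelow"],
        "LowGrayLevelZoneEmphasis": g["low"],
        "SizeZoneNonUniformity": g["sn"],
        "SizeZoneNonUniformityNormalized": g["snn"],
        "SmallAreaEmphasis": g["small"],
        "SmallAreaHighGrayLevelEmphasis": g["smallhigh"],
        "SmallAreaLowGrayLevelEmphasis": g["smalllow"],
        "ZoneEntropy": g["entropy"],
        "ZonePercentage": g["pct"],
        "ZoneVariance": g["sv"],
    }


# ---------------------------------------------------------------------------
# GLDM (neighbour counting)
# ---------------------------------------------------------------------------


def dependences_oracle(levels, mask):
    out = []
    for p in zip(*np.nonzero(mask)):
        dep = 0
        for off in NEIGHBOURS_26:
            nb = tuple(c + d for c, d in zip(p, off))
            if _inside(mask.shape, nb) and mask[nb] and levels[nb] == levels[p]:
                dep += 1
        out.append((levels[p], dep + 1))  # column index = dependence + 1
    return out


def gldm_features_oracle(levels, mask, ng):
    n_vox = int(mask.sum())
    g = _level_size_features(dependences_oracle(levels, mask), n_vox, prefix="dep")
    return {
        "DependenceEntropy": g["entropy"],
        "DependenceNonUniformity": g["sn"],
        "DependenceNonUniformityNormalized": g["snn"],
        "DependenceVariance": g["sv"],
        "GrayLevelNonUniformity": g["gln"],
        "GrayLevelVariance": g["glv"],
        "HighGrayLevelEmphasis": g["high"],
        "LargeDependenceEmphasis": g["large"],
        "LargeDependenceHighGrayLevelEmphasis": g["largehigh"],
        "LargeDependenceLowGrayLevelEmphasis": g["largelow"],
        "LowGrayLevelEmphasis": g["low"],
        "SmallDependenceEmphasis": g["small"],
        "SmallDependenceHighGrayLevelEmphasis": g["smallhigh"],
        "SmallDependenceLowGrayLevelEmphasis": g["smalllow"],
    }


# ---------------------------------------------------------------------------
# NGTDM
# ---------------------------------------------------------------------------


def ngtdm_table_oracle(levels, mask, ng):
    n = np.zeros(ng)
    s = np.zeros(ng)
    for p in zip(*np.nonzero(mask)):
        lv = levels[p]
        n[lv - 1] += 1
        nb_levels = []
        for off in NEIGHBOURS_26:
            nb = tuple(c + d for c, d in zip(p, off))
            if _inside(mask.shape, nb) and mask[nb]:
                nb_levels.append(levels[nb])
        if nb_levels:
            s[lv - 1] += abs(lv - sum(nb_levels) / len(nb_levels))
    p_i = n / n.sum()
    return n, p_i, s


def ngtdm_features_oracle(levels, mask, ng):
    n, p, s = ngtdm_table_oracle(levels, mask, ng)
    N = n.sum()
    present = [i for i in range(ng) if p[i] > 0]
    ngp = len(present)
    ps = sum(p[i] * s[i] for i in present)
    coarseness = 1.0 / ps if ps > 0 else 1e6
    if ngp > 1:
        contrast = (
            sum(p[i] * p[j] * (i - j) ** 2 for i in present for j in present)
            / (ngp * (ngp - 1))
        ) * (s.sum() / N)
        denom = sum(
            abs((i + 1) * p[i] - (j + 1) * p[j]) for i in present for j in present
        )
        busyness = ps / denom if denom > 0 else 0.0
        complexity = sum(
            abs(i - j) * (p[i] * s[i] + p[j] * s[j]) / (p[i] + p[j])
            for i in present for j in present
        ) / N
        strength = (
            sum((p[i] + p[j]) * (i - j) ** 2 for i in present for j in present) / s.sum()
            if s.sum() > 0 else 0.0
        )
    else:
        contrast = busyness = complexity = strength = 0.0
    return {
        "Busyness": busyness,
        "Coarseness": coarseness,
        "Complexity": complexity,
        "Contrast": contrast,
        "Strength": strength,
    }


# ---------------------------------------------------------------------------
# Full 93-feature oracle
# ---------------------------------------------------------------------------


def all_texture_features_oracle(values, mask, ng):
    """All texture-family features (prefixed names) by brute force."""
    levels = quantise(np.asarray(values, float), np.asarray(mask, bool), ng)
    mask = np.asarray(mask, bool)
    out = {}
    for fam, fn in (
        ("glcm", glcm_features_oracle),
        ("gldm", gldm_features_oracle),
        ("glrlm", glrlm_features_oracle),
        ("glszm", glszm_features_oracle),
        ("ngtdm", ngtdm_features_oracle),
    ):
        for name, v in fn(levels, mask, ng).items():
            out[f"{fam}_{name}"] = v
    return out


# ---------------------------------------------------------------------------
# Statistics oracles
# ---------------------------------------------------------------------------


def eta_squared_oracle(df, factors, value_col="value"):
    """Group-mean sums of squares computed with explicit loops."""
    y = df[value_col].to_numpy(dtype=float)
    grand = y.mean()
    ss_total = float(((y - grand) ** 2).sum())
    shares = {}
    for f in factors:
        ss = 0.0
        for level in df[f].unique():
            sub = y[(df[f] == level).to_numpy()]
            ss += len(sub) * (sub.mean() - grand) ** 2
        shares[f] = ss / ss_total
    shares["error"] = 1.0 - sum(shares.values())
    return shares


def kruskal_oracle(values, groups):
    """Tie-corrected Kruskal-Wallis H from explicit mid-ranks."""
    values = list(map(float, values))
    N = len(values)
    order = sorted(range(N), key=lambda i: values[i])
    ranks = [0.0] * N
    i = 0
    while i < N:
        j = i
        while j + 1 < N and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    h = 0.0
    for g in set(groups):
        rsum = sum(r for r, gg in zip(ranks, groups) if gg == g)
        n = sum(1 for gg in groups if gg == g)
        h += rsum**2 / n
    h = 12.0 / (N * (N + 1)) * h - 3 * (N + 1)
    # tie correction
    tie = 0.0
    for v in set(values):
        t = values.count(v)
        tie += t**3 - t
    c = 1.0 - tie / (N**3 - N)
    return h / c if c > 0 else float("nan")


def rmcorr_oracle(x, y, subjects):
    """Subject-centred covariance correlation via explicit loops."""
    xs = defaultdict(list)
    ys = defaultdict(list)
    for xi, yi, s in zip(x, y, subjects):
        xs[s].append(xi)
        ys[s].append(yi)
    num = sxx = syy = 0.0
    for s in xs:
        mx = sum(xs[s]) / len(xs[s])
        my = sum(ys[s]) / len(ys[s])
        for xi, yi in zip(xs[s], ys[s]):
            num += (xi - mx) * (yi - my)
            sxx += (xi - mx) ** 2
            syy += (yi - my) ** 2
    return num / math.sqrt(sxx * syy)


def shapley_oracle(predict, x, background):
    """Exact Shapley values for one sample by full coalition enumeration."""
    k = len(x)
    idx = list(range(k))

    def value(S):
        total = 0.0
        for b in background:
            z = list(b)
            for i in S:
                z[i] = x[i]
            total += float(predict(np.asarray([z]))[0])
        return total / len(background)

    phi = [0.0] * k
    from itertools import combinations

    for i in idx:
        rest = [j for j in idx if j != i]
        for r in range(k):
            for S in combinations(rest, r):
                w = (
                    math.factorial(len(S))
                    * math.factorial(k - len(S) - 1)
                    / math.factorial(k)
                )
                phi[i] += w * (value(set(S) | {i}) - value(set(S)))
    return np.array(phi)


def first_order_oracle(values, mask, ng, voxel_volume):
    """The 18 first-order features by explicit summation."""
    x = sorted(float(v) for v in np.asarray(values)[np.asarray(mask, bool)])
    n = len(x)
    mean = sum(x) / n
    m2 = sum((v - mean) ** 2 for v in x) / n
    m3 = sum((v - mean) ** 3 for v in x) / n
    m4 = sum((v - mean) ** 4 for v in x) / n

    def pct(q):
        h = (n - 1) * q / 100.0
        lo = int(math.floor(h))
        if lo + 1 >= n:
            return x[-1]
        return x[lo] + (h - lo) * (x[lo + 1] - x[lo])

    p10, p25, p75, p90 = pct(10), pct(25), pct(75), pct(90)
    inner = [v for v in x if p10 <= v <= p90]
    imean = sum(inner) / len(inner)
    levels = quantise(np.asarray(values, float), np.asarray(mask, bool), ng)
    counts = defaultdict(int)
    for p in zip(*np.nonzero(np.asarray(mask, bool))):
        counts[levels[p]] += 1
    probs = [c / n for c in counts.values()]
    energy = sum(v * v for v in x)
    return {
        "Energy": energy,
        "TotalEnergy": energy * voxel_volume,
        "Entropy": -sum(p * math.log2(p) for p in probs if p > 0),
        "Minimum": x[0],
        "10Percentile": p10,
        "90Percentile": p90,
        "Maximum": x[-1],
        "Mean": mean,
        "Median": pct(50),
        "InterquartileRange": p75 - p25,
        "Range": x[-1] - x[0],
        "MeanAbsoluteDeviation": sum(abs(v - mean) for v in x) / n,
        "RobustMeanAbsoluteDeviation": sum(abs(v - imean) for v in inner) / len(inner),
        "RootMeanSquared": math.sqrt(energy / n),
        "Skewness": m3 / m2**1.5 if m2 > 0 else 0.0,
        "Kurtosis": m4 / m2**2 if m2 > 0 else 0.0,
        "Variance": m2,
        "Uniformity": sum(p * p for p in probs),
    }


def all_features_oracle(values, mask, ng, voxel_volume=1.0):
    """All 93 features (prefixed names) by brute force."""
    out = {
        f"firstorder_{k}": v
        for k, v in first_order_oracle(values, mask, ng, voxel_volume).items()
    }
    out.update(all_texture_features_oracle(values, mask, ng))
    return out
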