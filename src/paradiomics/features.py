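"""Native 3D radiomic feature extraction (93 features, six families).

Features are computed on the raw VOI intensities (first order) and on
grey-level texture matrices built from a fixed-bin-count quantisation of the
VOI (GLCM, GLDM, GLRLM, GLSZM, NGTDM). No image filtering and no resampling
are applied: texture neighbourhoods are unit steps in voxel-index space.

Conventions, chosen to match the standard definitions of these families:

* quantisation: ``level(x) = floor(Ng (x - min) / (max - min)) + 1`` with the
  maximum mapped to Ng (min-max fixed bin count);
* GLCM and GLRLM are computed per 3D direction (the 13 unique Chebyshev-1
  offsets) and the per-direction feature values averaged;
* GLCM matrices are symmetrised before normalisation;
* GLSZM zones and GLDM/NGTDM neighbourhoods use 26-connectivity;
* GLDM dependence uses alpha = 0 (neighbours of exactly equal level) and the
  matrix column index is dependence + 1;
* Kurtosis is non-excess (a Gaussian gives 3) and moments are population
  moments (divide by n);
* degenerate inputs (single grey level, single voxel) yield the features'
  defined limits, never NaN, and the affected names are flagged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .phantom import GREY_LEVELS, ImageVolume, VoiMask

# ---------------------------------------------------------------------------
# Feature registry
# ---------------------------------------------------------------------------

FIRSTORDER_NAMES = (
    "Energy", "TotalEnergy", "Entropy", "Minimum", "10Percentile", "90Percentile",
    "Maximum", "Mean", "Median", "InterquartileRange", "Range",
    "MeanAbsoluteDeviation", "RobustMeanAbsoluteDeviation", "RootMeanSquared",
    "Skewness", "Kurtosis", "Variance", "Uniformity",
)
GLCM_NAMES = (
    "Autocorrelation", "ClusterProminence", "ClusterShade", "ClusterTendency",
    "Contrast", "Correlation", "DifferenceAverage", "DifferenceEntropy",
    "DifferenceVariance", "Id", "Idm", "Idmn", "Idn", "Imc1", "Imc2",
    "InverseVariance", "JointAverage", "JointEnergy", "JointEntropy",
    "MaximumProbability", "MCC", "SumAverage", "SumEntropy", "SumSquares",
)
GLDM_NAMES = (
    "DependenceEntropy", "DependenceNonUniformity", "DependenceNonUniformityNormalized",
    "DependenceVariance", "GrayLevelNonUniformity", "GrayLevelVariance",
    "HighGrayLevelEmphasis", "LargeDependenceEmphasis",
    "LargeDependenceHighGrayLevelEmphasis", "LargeDependenceLowGrayLevelEmphasis",
    "LowGrayLevelEmphasis", "SmallDependenceEmphasis",
    "SmallDependenceHighGrayLevelEmphasis", "SmallDependenceLowGrayLevelEmphasis",
)
GLRLM_NAMES = (
    "GrayLevelNonUniformity", "GrayLevelNonUniformityNormalized", "GrayLevelVariance",
    "HighGrayLevelRunEmphasis", "LongRunEmphasis", "LongRunHighGrayLevelEmphasis",
    "LongRunLowGrayLevelEmphasis", "LowGrayLevelRunEmphasis", "RunEntropy",
    "RunLengthNonUniformity", "RunLengthNonUniformityNormalized", "RunPercentage",
    "RunVariance", "ShortRunEmphasis", "ShortRunHighGrayLevelEmphasis",
    "ShortRunLowGrayLevelEmphasis",
)
GLSZM_NAMES = (
    "GrayLevelNonUniformity", "GrayLevelNonUniformityNormalized", "GrayLevelVariance",
    "HighGrayLevelZoneEmphasis", "LargeAreaEmphasis", "LargeAreaHighGrayLevelEmphasis",
    "LargeAreaLowGrayLevelEmphasis", "LowGrayLevelZoneEmphasis",
    "SizeZoneNonUniformity", "SizeZoneNonUniformityNormalized", "SmallAreaEmphasis",
    "SmallAreaHighGrayLevelEmphasis", "SmallAreaLowGrayLevelEmphasis",
    "ZoneEntropy", "ZonePercentage", "ZoneVariance",
)
NGTDM_NAMES = ("Busyness", "Coarseness", "Complexity", "Contrast", "Strength")

FEATURE_REGISTRY: dict[str, tuple[str, ...]] = {
    "firstorder": FIRSTORDER_NAMES,
    "glcm": GLCM_NAMES,
    "gldm": GLDM_NAMES,
    "glrlm": GLRLM_NAMES,
    "glszm": GLSZM_NAMES,
    "ngtdm": NGTDM_NAMES,
}

FEATURE_NAMES: tuple[str, ...] = tuple(
    f"{family}_{name}" for family, names in FEATURE_REGISTRY.items() for name in names
)
assert len(FEATURE_NAMES) == 93 and len(set(FEATURE_NAMES)) == 93

# the 13 unique 3D offsets at Chebyshev distance 1 (one per +/- pair)
OFFSETS_13: tuple[tuple[int, int, int], ...] = tuple(
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0)
)
assert len(OFFSETS_13) == 13

_COARSENESS_CAP = 1e6
_LOG2 = np.log(2.0)


# ---------------------------------------------------------------------------
# Quantisation
# ---------------------------------------------------------------------------


@dataclass
class QuantisedVoi:
    """Grey-level map of a VOI: integer levels in 1..ng, 0 outside the mask."""

    levels: np.ndarray          # int array, full (cropped) grid, 0 = outside
    mask: np.ndarray            # bool array, same grid
    ng: int
    voxel_count: int
    voxel_volume_mm3: float
    degenerate: bool = False    # constant VOI collapsed to a single level


@dataclass
class FeatureVector:
    """The 93 named feature values plus the set of degenerate-valued names."""

    values: dict[str, float]
    degenerate: frozenset[str] = frozenset()

    def __getitem__(self, name: str) -> float:
        return self.values[name]


def quantise_fixed_bin_count(
    volume: ImageVolume | np.ndarray, mask: VoiMask | np.ndarray, ng: int
) -> QuantisedVoi:
    """Min-max fixed-bin-count quantisation of the VOI intensities."""
    arr = volume.values if isinstance(volume, ImageVolume) else np.asarray(volume, float)
    msk = (mask.mask if isinstance(mask, VoiMask) else np.asarray(mask)).astype(bool)
    if arr.shape != msk.shape:
        raise ValueError(f"volume {arr.shape} and mask {msk.shape} grids differ")
    if not msk.any():
        raise ValueError("empty VOI")
    if ng < 2:
        raise ValueError("ng must be >= 2")
    vv = volume.voxel_volume_mm3 if isinstance(volume, ImageVolume) else 1.0

    x = arr[msk]
    m, M = float(x.min()), float(x.max())
    levels = np.zeros(arr.shape, dtype=np.int64)
    if M == m:
        levels[msk] = 1
        return QuantisedVoi(levels, msk, ng, int(msk.sum()), vv, degenerate=True)
    lv = np.floor(ng * (x - m) / (M - m)).astype(np.int64) + 1
    lv[lv > ng] = ng  # x == max maps into the top level
    levels[msk] = lv
    return QuantisedVoi(levels, msk, ng, int(msk.sum()), vv)


def _crop_to_bbox(levels: np.ndarray, mask: np.ndarray, pad: int = 1):
    idx = np.argwhere(mask)
    lo = np.maximum(idx.min(axis=0) - pad, 0)
    hi = np.minimum(idx.max(axis=0) + pad + 1, mask.shape)
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    return levels[sl], mask[sl]


# ---------------------------------------------------------------------------
# First-order statistics
# ---------------------------------------------------------------------------


def first_order_features(
    voi_values: np.ndarray, ng: int, voxel_volume_mm3: float
) -> tuple[dict[str, float], set[str]]:
    """The 18 first-order features on raw intensities.

    Entropy and Uniformity use the Ng-level min-max histogram; everything
    else is quantisation-independent. Returns (values, degenerate names).
    """
    x = np.asarray(voi_values, dtype=np.float64).ravel()
    if x.size < 1:
        raise ValueError("empty VOI")
    degenerate: set[str] = set()
    n = x.size
    mean = float(x.mean())
    m2 = float(((x - mean) ** 2).mean())
    m3 = float(((x - mean) ** 3).mean())
    m4 = float(((x - mean) ** 4).mean())
    if n < 2 or m2 <= 0:
        skew, kurt = 0.0, 0.0
        degenerate.update({"Skewness", "Kurtosis"})
    else:
        skew = m3 / m2**1.5
        kurt = m4 / m2**2

    p10, p25, p50, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    inner = x[(x >= p10) & (x <= p90)]
    rmad = float(np.abs(inner - inner.mean()).mean()) if inner.size else 0.0

    # Ng-level histogram for Entropy / Uniformity
    m, M = float(x.min()), float(x.max())
    if M == m:
        p = np.array([1.0])
        degenerate.update({"Entropy", "Uniformity"})
    else:
        lv = np.floor(ng * (x - m) / (M - m)).astype(np.int64)
        lv[lv >= ng] = ng - 1
        counts = np.bincount(lv, minlength=ng)
        p = counts[counts > 0] / n
    entropy = float(-(p * np.log2(p)).sum())
    uniformity = float((p**2).sum())

    energy = float((x**2).sum())
    vals = {
        "Energy": energy,
        "TotalEnergy": energy * voxel_volume_mm3,
        "Entropy": entropy,
        "Minimum": m,
        "10Percentile": float(p10),
        "90Percentile": float(p90),
        "Maximum": M,
        "Mean": mean,
        "Median": float(p50),
        "InterquartileRange": float(p75 - p25),
        "Range": M - m,
        "MeanAbsoluteDeviation": float(np.abs(x - mean).mean()),
        "RobustMeanAbsoluteDeviation": rmad,
        "RootMeanSquared": float(np.sqrt((x**2).mean())),
        "Skewness": float(skew),
        "Kurtosis": float(kurt),
        "Variance": m2,
        "Uniformity": uniformity,
    }
    return vals, degenerate


# ---------------------------------------------------------------------------
# Texture matrix construction helpers
# ---------------------------------------------------------------------------


def _shifted_pairs(levels: np.ndarray, mask: np.ndarray, offset):
    """Level values of in-mask voxel pairs separated by ``offset``."""
    sl_src, sl_dst = [], []
    for d, size in zip(offset, levels.shape):
        if d >= 0:
            sl_src.append(slice(0, size - d))
            sl_dst.append(slice(d, size))
        else:
            sl_src.append(slice(-d, size))
            sl_dst.append(slice(0, size + d))
    a = levels[tuple(sl_src)]
    b = levels[tuple(sl_dst)]
    valid = mask[tuple(sl_src)] & mask[tuple(sl_dst)]
    return a[valid], b[valid]


def glcm_matrices(q: QuantisedVoi) -> list[np.ndarray]:
    """Symmetrised, normalised co-occurrence matrix per direction (with pairs)."""
    levels, mask = _crop_to_bbox(q.levels, q.mask)
    ng = q.ng
    mats = []
    for off in OFFSETS_13:
        a, b = _shifted_pairs(levels, mask, off)
        if a.size == 0:
            continue
        counts = np.bincount((a - 1) * ng + (b - 1), minlength=ng * ng).reshape(ng, ng)
        P = counts + counts.T
        mats.append(P / P.sum())
    return mats


def _glcm_features_one(P: np.ndarray, ng: int, degenerate: set[str]) -> dict[str, float]:
    # operate on the nonzero cells only: a VOI of n voxels yields at most
    # ~2n nonzero co-occurrence cells per direction regardless of ng
    ii, jj = np.nonzero(P)
    pv = P[ii, jj]
    iv = (ii + 1).astype(float)
    jv = (jj + 1).astype(float)
    dv = iv - jv
    sv = iv + jv

    px = np.bincount(ii, weights=pv, minlength=ng)  # == py by symmetry
    lv = np.arange(1, ng + 1, dtype=float)
    mu = float((lv * px).sum())
    sigma2 = float(((lv - mu) ** 2 * px).sum())

    psum = np.bincount(sv.astype(int), weights=pv, minlength=2 * ng + 1)
    k_sum = np.arange(2 * ng + 1)
    pdiff = np.bincount(np.abs(dv).astype(int), weights=pv, minlength=ng)
    k_diff = np.arange(ng)

    joint_entropy = float(-(pv * np.log2(pv)).sum())
    present = px > 0
    pxnz = px[present]
    HX = float(-(pxnz * np.log2(pxnz)).sum())
    HXY1 = float(-(pv * np.log2(px[ii] * px[jj])).sum())
    outer = pxnz[:, None] * pxnz[None, :]
    HXY2 = float(-(outer * np.log2(outer)).sum())

    if HX > 0:
        imc1 = (joint_entropy - HXY1) / HX
    else:
        imc1 = 0.0
        degenerate.add("Imc1")
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (HXY2 - joint_entropy)))))

    da = float((k_diff * pdiff).sum())
    if sigma2 > 0:
        corr = (float((iv * jv * pv).sum()) - mu * mu) / sigma2
    else:
        corr = 1.0
        degenerate.add("Correlation")

    # MCC = sqrt of the 2nd-largest eigenvalue of Q_ij = sum_k p(i,k)p(j,k)
    # / (px_i px_k).  Q = D^-1 P D^-1 P is similar to S^2 with the symmetric
    # S = D^-1/2 P D^-1/2 (restricted to present levels), so MCC equals the
    # second-largest |eigenvalue| of S.
    if present.sum() > 1:
        Pp = P[np.ix_(present, present)]
        S = Pp / np.sqrt(pxnz[:, None] * pxnz[None, :])
        ev = np.sort(np.abs(np.linalg.eigvalsh(S)))
        mcc = float(min(ev[-2], 1.0))
    else:
        mcc = 1.0
        degenerate.add("MCC")

    offdiag = dv != 0
    inv_var = float((pv[offdiag] / dv[offdiag] ** 2).sum())
    pdnz = pdiff > 0
    psnz = psum > 0

    return {
        "Autocorrelation": float((iv * jv * pv).sum()),
        "ClusterProminence": float(((sv - 2 * mu) ** 4 * pv).sum()),
        "ClusterShade": float(((sv - 2 * mu) ** 3 * pv).sum()),
        "ClusterTendency": float(((sv - 2 * mu) ** 2 * pv).sum()),
        "Contrast": float((dv**2 * pv).sum()),
        "Correlation": float(corr),
        "DifferenceAverage": da,
        "DifferenceEntropy": float(-(pdiff[pdnz] * np.log2(pdiff[pdnz])).sum()),
        "DifferenceVariance": float(((k_diff - da) ** 2 * pdiff).sum()),
        "Id": float((pv / (1.0 + np.abs(dv))).sum()),
        "Idm": float((pv / (1.0 + dv**2)).sum()),
        "Idmn": float((pv / (1.0 + (dv / ng) ** 2)).sum()),
        "Idn": float((pv / (1.0 + np.abs(dv) / ng)).sum()),
        "Imc1": float(imc1),
        "Imc2": imc2,
        "InverseVariance": inv_var,
        "JointAverage": mu,
        "JointEnergy": float((pv**2).sum()),
        "JointEntropy": joint_entropy,
        "MaximumProbability": float(pv.max()),
        "MCC": mcc,
        "SumAverage": float((k_sum * psum).sum()),
        "SumEntropy": float(-(psum[psnz] * np.log2(psum[psnz])).sum()),
        "SumSquares": float(((iv - mu) ** 2 * pv).sum()),
    }


def glcm_features(q: QuantisedVoi) -> tuple[dict[str, float], set[str]]:
    """24 co-occurrence features, averaged over directions with >= 1 pair."""
    mats = glcm_matrices(q)
    degenerate: set[str] = set()
    if not mats:
        # no voxel pairs at all (e.g. single-voxel VOI): defined limits
        vals = {n: 0.0 for n in GLCM_NAMES}
        vals.update({
            "Correlation": 1.0, "MCC": 1.0, "MaximumProbability": 1.0,
            "JointEnergy": 1.0, "Id": 1.0, "Idm": 1.0, "Idmn": 1.0, "Idn": 1.0,
            "JointAverage": 1.0, "SumAverage": 2.0, "Autocorrelation": 1.0,
        })
        return vals, set(GLCM_NAMES)
    acc = {n: 0.0 for n in GLCM_NAMES}
    for P in mats:
        one = _glcm_features_one(P, q.ng, degenerate)
        for n in GLCM_NAMES:
            acc[n] += one[n]
    return {n: v / len(mats) for n, v in acc.items()}, degenerate


# ---------------------------------------------------------------------------
# GLRLM
# ---------------------------------------------------------------------------


def _shift_bool(a: np.ndarray, offset, fill=False) -> np.ndarray:
    """a shifted by -offset: out[x] = a[x + offset] (fill outside)."""
    out = np.full(a.shape, fill, dtype=a.dtype)
    sl_src, sl_dst = [], []
    for d, size in zip(offset, a.shape):
        if d >= 0:
            sl_dst.append(slice(0, size - d))
            sl_src.append(slice(d, size))
        else:
            sl_dst.append(slice(-d, size))
            sl_src.append(slice(0, size + d))
    out[tuple(sl_dst)] = a[tuple(sl_src)]
    return out


def glrlm_matrices(q: QuantisedVoi) -> list[np.ndarray]:
    """Run-length matrix (ng x max_run) per direction."""
    levels, mask = _crop_to_bbox(q.levels, q.mask)
    max_len = int(np.ceil(np.sqrt(3) * max(levels.shape))) + 1
    mats = []
    for off in OFFSETS_13:
        nxt = _shift_bool(levels, off, 0)
        nxt_same = mask & (nxt == levels) & (nxt > 0) & _shift_bool(mask, off, False)
        prv = _shift_bool(levels, tuple(-d for d in off), 0)
        prv_same = mask & (prv == levels) & (prv > 0) & _shift_bool(
            mask, tuple(-d for d in off), False
        )
        # forward chain length: f(x) = 1 + f(x+off) if successor same-level
        f = np.ones(levels.shape, dtype=np.int64)
        f[~mask] = 0
        for _ in range(max(levels.shape) * 2):
            fn = np.where(nxt_same, 1 + _shift_bool(f, off, 0), 1)
            fn[~mask] = 0
            if np.array_equal(fn, f):
                break
            f = fn
        starts = mask & ~prv_same
        run_levels = levels[starts]
        run_lengths = f[starts]
        P = np.zeros((q.ng, run_lengths.max()), dtype=np.int64)
        np.add.at(P, (run_levels - 1, run_lengths - 1), 1)
        mats.append(P)
    return mats


def _sizezone_style_features(
    P: np.ndarray, n_voxels: int, names: dict[str, str]
) -> dict[str, float]:
    """Shared statistics for GLRLM / GLSZM / GLDM style (level x size) matrices.

    ``names`` maps the canonical keys to the family's feature names.
    """
    Ns = P.sum()
    i = np.arange(1, P.shape[0] + 1, dtype=float)[:, None]
    j = np.arange(1, P.shape[1] + 1, dtype=float)[None, :]
    p = P / Ns
    pi = p.sum(axis=1)
    pj = p.sum(axis=0)
    mu_i = float((i.ravel() * pi).sum())
    mu_j = float((j.ravel() * pj).sum())
    nzp = p > 0
    out = {
        "SmallEmphasis": float((P / j**2).sum() / Ns),
        "LargeEmphasis": float((P * j**2).sum() / Ns),
        "LowGrayEmphasis": float((P / i**2).sum() / Ns),
        "HighGrayEmphasis": float((P * i**2).sum() / Ns),
        "SmallLow": float((P / (i**2 * j**2)).sum() / Ns),
        "SmallHigh": float((P * i**2 / j**2).sum() / Ns),
        "LargeLow": float((P * j**2 / i**2).sum() / Ns),
        "LargeHigh": float((P * i**2 * j**2).sum() / Ns),
        "GrayLevelNonUniformity": float((P.sum(axis=1) ** 2).sum() / Ns),
        "GrayLevelNonUniformityNormalized": float((P.sum(axis=1) ** 2).sum() / Ns**2),
        "SizeNonUniformity": float((P.sum(axis=0) ** 2).sum() / Ns),
        "SizeNonUniformityNormalized": float((P.sum(axis=0) ** 2).sum() / Ns**2),
        "GrayLevelVariance": float((((i.ravel() - mu_i) ** 2) * pi).sum()),
        "SizeVariance": float((((j.ravel() - mu_j) ** 2) * pj).sum()),
        "Entropy": float(-(p[nzp] * np.log2(p[nzp])).sum()),
        "Percentage": float(Ns / n_voxels),
    }
    return {fam: out[key] for fam, key in names.items()}


_GLRLM_MAP = {
    "GrayLevelNonUniformity": "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized": "GrayLevelNonUniformityNormalized",
    "GrayLevelVariance": "GrayLevelVariance",
    "HighGrayLevelRunEmphasis": "HighGrayEmphasis",
    "LongRunEmphasis": "LargeEmphasis",
    "LongRunHighGrayLevelEmphasis": "LargeHigh",
    "LongRunLowGrayLevelEmphasis": "LargeLow",
    "LowGrayLevelRunEmphasis": "LowGrayEmphasis",
    "RunEntropy": "Entropy",
    "RunLengthNonUniformity": "SizeNonUniformity",
    "RunLengthNonUniformityNormalized": "SizeNonUniformityNormalized",
    "RunPercentage": "Percentage",
    "RunVariance": "SizeVariance",
    "ShortRunEmphasis": "SmallEmphasis",
    "ShortRunHighGrayLevelEmphasis": "SmallHigh",
    "ShortRunLowGrayLevelEmphasis": "SmallLow",
}

_GLSZM_MAP = {
    "GrayLevelNonUniformity": "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized": "GrayLevelNonUniformityNormalized",
    "GrayLevelVariance": "GrayLevelVariance",
    "HighGrayLevelZoneEmphasis": "HighGrayEmphasis",
    "LargeAreaEmphasis": "LargeEmphasis",
    "LargeAreaHighGrayLevelEmphasis": "LargeHigh",
    "LargeAreaLowGrayLevelEmphasis": "LargeLow",
    "LowGrayLevelZoneEmphasis": "LowGrayEmphasis",
    "SizeZoneNonUniformity": "SizeNonUniformity",
    "SizeZoneNonUniformityNormalized": "SizeNonUniformityNormalized",
    "SmallAreaEmphasis": "SmallEmphasis",
    "SmallAreaHighGrayLevelEmphasis": "SmallHigh",
    "SmallAreaLowGrayLevelEmphasis": "SmallLow",
    "ZoneEntropy": "Entropy",
    "ZonePercentage": "Percentage",
    "ZoneVariance": "SizeVariance",
}

_GLDM_MAP = {
    "DependenceEntropy": "Entropy",
    "DependenceNonUniformity": "SizeNonUniformity",
    "DependenceNonUniformityNormalized": "SizeNonUniformityNormalized",
    "DependenceVariance": "SizeVariance",
    "GrayLevelNonUniformity": "GrayLevelNonUniformity",
    "GrayLevelVariance": "GrayLevelVariance",
    "HighGrayLevelEmphasis": "HighGrayEmphasis",
    "LargeDependenceEmphasis": "LargeEmphasis",
    "LargeDependenceHighGrayLevelEmphasis": "LargeHigh",
    "LargeDependenceLowGrayLevelEmphasis": "LargeLow",
    "LowGrayLevelEmphasis": "LowGrayEmphasis",
    "SmallDependenceEmphasis": "SmallEmphasis",
    "SmallDependenceHighGrayLevelEmphasis": "SmallHigh",
    "SmallDependenceLowGrayLevelEmphasis": "SmallLow",
}


def glrlm_features(q: QuantisedVoi) -> tuple[dict[str, float], set[str]]:
    """16 run-length features averaged over the 13 directions."""
    acc = {n: 0.0 for n in GLRLM_NAMES}
    mats = glrlm_matrices(q)
    for P in mats:
        one = _sizezone_style_features(P, q.voxel_count, _GLRLM_MAP)
        for n in GLRLM_NAMES:
            acc[n] += one[n]
    return {n: v / len(mats) for n, v in acc.items()}, set()


# ---------------------------------------------------------------------------
# GLSZM
# ---------------------------------------------------------------------------

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


def glszm_matrix(q: QuantisedVoi) -> np.ndarray:
    """Size-zone matrix: 26-connected equal-level zones within the VOI."""
    levels, mask = _crop_to_bbox(q.levels, q.mask)
    zone_levels, zone_sizes = [], []
    for lvl in np.unique(levels[mask]):
        lab, nlab = ndimage.label(levels == lvl, structure=_STRUCT_26)
        if nlab:
            sizes = np.bincount(lab.ravel())[1:]
            zone_sizes.append(sizes)
            zone_levels.append(np.full(sizes.size, lvl))
    sizes = np.concatenate(zone_sizes)
    lvls = np.concatenate(zone_levels)
    P = np.zeros((q.ng, int(sizes.max())), dtype=np.int64)
    np.add.at(P, (lvls - 1, sizes - 1), 1)
    return P


def glszm_features(q: QuantisedVoi) -> tuple[dict[str, float], set[str]]:
    """16 size-zone features from the single (direction-free) matrix."""
    P = glszm_matrix(q)
    return _sizezone_style_features(P, q.voxel_count, _GLSZM_MAP), set()


# ---------------------------------------------------------------------------
# GLDM
# ---------------------------------------------------------------------------


def gldm_matrix(q: QuantisedVoi) -> np.ndarray:
    """Dependence matrix: per voxel, count of equal-level 26-neighbours."""
    levels, mask = _crop_to_bbox(q.levels, q.mask)
    dep = np.zeros(levels.shape, dtype=np.int64)
    for off in OFFSETS_13:
        for o in (off, tuple(-d for d in off)):
            nb = _shift_bool(levels, o, 0)
            dep += (mask & (nb == levels) & (nb > 0)).astype(np.int64)
    dep = dep[mask]
    lv = levels[mask]
    P = np.zeros((q.ng, int(dep.max()) + 1), dtype=np.int64)
    np.add.at(P, (lv - 1, dep), 1)  # column index = dependence + 1 via 0-base
    return P


def gldm_features(q: QuantisedVoi) -> tuple[dict[str, float], set[str]]:
    """14 dependence features (alpha = 0, dependence column j = d + 1)."""
    P = gldm_matrix(q)
    return _sizezone_style_features(P, q.voxel_count, _GLDM_MAP), set()


# ---------------------------------------------------------------------------
# NGTDM
# ---------------------------------------------------------------------------


def ngtdm_table(q: QuantisedVoi) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(n_i, p_i, s_i) per level: counts, probabilities, summed differences
    between each voxel's level and the mean level of its in-VOI 26-neighbours.
    Voxels with no in-VOI neighbour contribute zero to s."""
    levels, mask = _crop_to_bbox(q.levels, q.mask)
    nb_sum = np.zeros(levels.shape, dtype=np.float64)
    nb_cnt = np.zeros(levels.shape, dtype=np.int64)
    for off in OFFSETS_13:
        for o in (off, tuple(-d for d in off)):
            nb = _shift_bool(levels, o, 0)
            valid = nb > 0
            nb_sum += np.where(valid, nb, 0)
            nb_cnt += valid.astype(np.int64)
    lv = levels[mask]
    cnt = nb_cnt[mask]
    with np.errstate(invalid="ignore", divide="ignore"):
        diff = np.abs(lv - nb_sum[mask] / cnt)
    diff[cnt == 0] = 0.0
    n_i = np.bincount(lv - 1, minlength=q.ng).astype(float)
    s_i = np.zeros(q.ng)
    np.add.at(s_i, lv - 1, diff)
    p_i = n_i / n_i.sum()
    return n_i, p_i, s_i


def ngtdm_features(q: QuantisedVoi) -> tuple[dict[str, float], set[str]]:
    """Busyness, Coarseness, Complexity, Contrast, Strength."""
    n_i, p_i, s_i = ngtdm_table(q)
    degenerate: set[str] = set()
    N = n_i.sum()
    present = p_i > 0
    i = np.arange(1, q.ng + 1, dtype=float)
    ip, pp, sp = i[present], p_i[present], s_i[present]
    ngp = int(present.sum())
    ps = float((p_i * s_i).sum())

    coarseness = 1.0 / ps if ps > 0 else _COARSENESS_CAP
    if ps <= 0:
        degenerate.add("Coarseness")

    if ngp > 1:
        dij2 = (ip[:, None] - ip[None, :]) ** 2
        contrast = float(
            (pp[:, None] * pp[None, :] * dij2).sum() / (ngp * (ngp - 1)) * (s_i.sum() / N)
        )
        absdiff = np.abs(ip[:, None] * pp[:, None] - ip[None, :] * pp[None, :])
        denom = float(absdiff.sum())
        busyness = ps / denom if denom > 0 else 0.0
        if denom <= 0:
            degenerate.add("Busyness")
        pspj = pp[:, None] * sp[:, None] + pp[None, :] * sp[None, :]
        complexity = float(
            (np.abs(ip[:, None] - ip[None, :]) * pspj / (pp[:, None] + pp[None, :])).sum() / N
        )
        ssum = float(s_i.sum())
        strength = float(((pp[:, None] + pp[None, :]) * dij2).sum() / ssum) if ssum > 0 else 0.0
        if ssum <= 0:
            degenerate.add("Strength")
    else:
        contrast, busyness, complexity, strength = 0.0, 0.0, 0.0, 0.0
        degenerate.update({"Contrast", "Busyness", "Complexity", "Strength"})

    return {
        "Busyness": busyness,
        "Coarseness": coarseness,
        "Complexity": complexity,
        "Contrast": contrast,
        "Strength": strength,
    }, degenerate


# ---------------------------------------------------------------------------
# Full extraction
# ---------------------------------------------------------------------------


def extract_features(
    volume: ImageVolume | np.ndarray, mask: VoiMask | np.ndarray, ng: int
) -> FeatureVector:
    """Complete 93-entry feature vector at one grey-level quantisation."""
    arr = volume.values if isinstance(volume, ImageVolume) else np.asarray(volume, float)
    msk = (mask.mask if isinstance(mask, VoiMask) else np.asarray(mask)).astype(bool)
    if arr.shape != msk.shape:
        raise ValueError(f"volume grid {arr.shape} does not match mask grid {msk.shape}")
    if ng not in GREY_LEVELS:
        warnings.warn(f"grey-level count {ng} is outside the study set {GREY_LEVELS}")
    vv = volume.voxel_volume_mm3 if isinstance(volume, ImageVolume) else 1.0

    q = quantise_fixed_bin_count(arr, msk, ng)
    values: dict[str, float] = {}
    degenerate: set[str] = set()

    fo, fo_deg = first_order_features(arr[msk], ng, vv)
    family_results = {
        "firstorder": (fo, fo_deg),
        "glcm": glcm_features(q),
        "gldm": gldm_features(q),
        "glrlm": glrlm_features(q),
        "glszm": glszm_features(q),
        "ngtdm": ngtdm_features(q),
    }
    for family, (vals, deg) in family_results.items():
        for name, v in vals.items():
            values[f"{family}_{name}"] = float(v)
        degenerate.update(f"{family}_{n}" for n in deg)

    assert set(values) == set(FEATURE_NAMES)
    bad = [n for n, v in values.items() if not np.isfinite(v)]
    if bad:  # defensive: defined limits should prevent this
        raise FloatingPointError(f"non-finite feature values: {bad}")
    return FeatureVector({n: values[n] for n in FEATURE_NAMES}, frozenset(degenerate))
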