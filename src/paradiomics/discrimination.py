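"""Feature reduction and tumour-model discrimination ranking.

The stage chain:

1. volume correction — features with a significant Spearman dependence on
   VOI voxel count are residualised against a fitted power law a * V^b;
2. Kruskal–Wallis H per feature against the tumour-model label, with
   Benjamini–Hochberg step-up control of the false discovery rate (q = 0.25);
3. repeated-measures correlation between surviving features (subject =
   specimen, so the many conditions per tumour do not masquerade as
   independent observations), pruning each pair with |r| > 0.9 down to the
   member with the better single-feature classification score;
4. a seeded random forest on the selected features, ranked by mean absolute
   Shapley attribution of the luminal-class probability.

Shapley attributions use the interventional (marginal-expectation) value
function v(S) = E_b[f(x_S, b_~S)] over a background sample: exact coalition
enumeration when the feature count and evaluation budget allow, otherwise a
seeded permutation Monte-Carlo estimator.  Both satisfy local accuracy
(base value + sum of attributions = model output) to machine precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.model_selection import GroupKFold
from sklearn.svm import SVC

from .phantom import derive_seed

# ---------------------------------------------------------------------------
# Volume-dependency correction
# ---------------------------------------------------------------------------


def correct_volume_dependency(
    X: pd.DataFrame, volumes: np.ndarray, alpha: float = 0.05
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Residualise features with a significant power-law volume dependence.

    Per feature: Spearman correlation with the VOI voxel count V; if
    p < alpha, fit value = a * V^b by least squares on log-transformed
    (positive-shifted where needed) values and replace the values by the
    log-residuals recentred at the feature's grand mean.  Returns the
    corrected wide table and a report with (a, b, rho, p, corrected).
    """
    volumes = np.asarray(volumes, dtype=float)
    if np.any(volumes <= 0):
        raise ValueError("VOI voxel counts must be positive")
    logV = np.log(volumes)
    out = X.copy()
    report = []
    for name in X.columns:
        y = X[name].to_numpy(dtype=float)
        rho, p = stats.spearmanr(y, volumes)
        corrected = bool(np.isfinite(p) and p < alpha)
        a = b = np.nan
        if corrected:
            shift = 0.0
            if y.min() <= 0:
                rng_ = y.max() - y.min()
                shift = -y.min() + 0.01 * (rng_ if rng_ > 0 else 1.0)
            logy = np.log(y + shift)
            b, loga = np.polyfit(logV, logy, 1)
            a = float(np.exp(loga))
            resid = logy - (loga + b * logV)
            out[name] = resid - resid.mean() + y.mean()
        report.append(
            {"feature": name, "a": a, "b": b, "spearman_rho": rho, "p": p,
             "corrected": corrected}
        )
    return out, pd.DataFrame(report).set_index("feature")


# ---------------------------------------------------------------------------
# Kruskal-Wallis + Benjamini-Hochberg
# ---------------------------------------------------------------------------


def kruskal_wallis_h(values: np.ndarray, group_labels: np.ndarray):
    """Tie-corrected Kruskal–Wallis H with chi-square p-value.

    Returns (H, df, p, degenerate); all-identical values are flagged
    degenerate with H = 0 and p = 1 (the feature carries no group signal).
    """
    values = np.asarray(values, dtype=float)
    groups = pd.Series(group_labels)
    samples = [values[(groups == g).to_numpy()] for g in groups.unique()]
    if len(samples) < 2 or any(len(s) == 0 for s in samples):
        raise ValueError("need >= 2 groups each with >= 1 observation")
    df = len(samples) - 1
    if np.all(values == values[0]):
        return 0.0, df, 1.0, True
    h, p = stats.kruskal(*samples)
    return float(h), df, float(p), False


def kruskal_wallis_table(X: pd.DataFrame, labels: np.ndarray) -> pd.DataFrame:
    """KW H/df/p per feature column; constant features flagged degenerate."""
    rows = []
    for name in X.columns:
        h, df, p, deg = kruskal_wallis_h(X[name].to_numpy(), labels)
        rows.append({"feature": name, "H": h, "df": df, "p": p, "degenerate": deg})
    return pd.DataFrame(rows).set_index("feature")


def benjamini_hochberg(p_values: pd.Series, q: float = 0.25) -> pd.DataFrame:
    """Step-up BH decision at FDR level q with stable (p, name) ordering."""
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    p_values = pd.Series(p_values, dtype=float)
    if ((p_values < 0) | (p_values > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if p_values.empty:
        return pd.DataFrame(columns=["p", "rank", "critical", "reject"])
    order = sorted(p_values.index, key=lambda n: (p_values[n], str(n)))
    m = len(order)
    ranks = np.arange(1, m + 1)
    crit = ranks * q / m
    ps = p_values[order].to_numpy()
    below = np.nonzero(ps <= crit)[0]
    k_star = below[-1] + 1 if below.size else 0
    out = pd.DataFrame(
        {"p": ps, "rank": ranks, "critical": crit, "reject": ranks <= k_star},
        index=pd.Index(order, name="feature"),
    )
    return out


# ---------------------------------------------------------------------------
# Repeated-measures correlation
# ---------------------------------------------------------------------------


def repeated_measures_correlation(x, y, subject_ids):
    """Within-subject correlation after removing subject means.

    r_rm = sum (x - x̄_i)(y - ȳ_i) / sqrt(sum (x - x̄_i)^2 sum (y - ȳ_i)^2),
    df = N - k - 1, two-sided p via the t transform.  Returns
    (r, df, p, defined); zero within-subject variance gives defined=False.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    s = pd.Series(subject_ids)
    if s.nunique() < 2:
        raise ValueError("need >= 2 subjects")
    xc = x - pd.Series(x).groupby(s.values).transform("mean").to_numpy()
    yc = y - pd.Series(y).groupby(s.values).transform("mean").to_numpy()
    sxx, syy = (xc**2).sum(), (yc**2).sum()
    if sxx <= 0 or syy <= 0:
        return np.nan, len(x) - s.nunique() - 1, np.nan, False
    r = float((xc * yc).sum() / np.sqrt(sxx * syy))
    df = len(x) - s.nunique() - 1
    if df <= 0:
        return r, df, np.nan, False
    r_ = min(max(r, -1.0), 1.0)
    if abs(r_) == 1.0:
        p = 0.0
    else:
        t = r_ * np.sqrt(df / (1.0 - r_**2))
        p = float(2.0 * stats.t.sf(abs(t), df))
    return r, df, p, True


def rmcorr_matrix(X: pd.DataFrame, subject_ids) -> pd.DataFrame:
    """Symmetric feature x feature repeated-measures correlation matrix.

    Equivalent to the plain correlation of subject-centred columns (centred
    columns have zero mean, so no further centring occurs).
    """
    s = pd.Series(subject_ids).reset_index(drop=True)
    Xv = X.reset_index(drop=True)
    centred = Xv - Xv.groupby(s.values).transform("mean")
    C = centred.to_numpy(dtype=float)
    norms = np.sqrt((C**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        R = (C.T @ C) / np.outer(norms, norms)
    R[~np.isfinite(R)] = 0.0
    np.fill_diagonal(R, 1.0)
    return pd.DataFrame(R, index=X.columns, columns=X.columns)


# ---------------------------------------------------------------------------
# Single-feature classifier scores
# ---------------------------------------------------------------------------


def _default_classifiers(seed: int):
    return {
        "random_forest": RandomForestClassifier(n_estimators=100, random_state=seed),
        "gradient_boosting": GradientBoostingClassifier(
            max_depth=3, n_estimators=100, learning_rate=1.0, random_state=seed
        ),
        "svm_rbf": SVC(kernel="rbf", gamma=0.05, C=1.0, tol=0.001, random_state=seed),
    }


def single_feature_scores(
    X: pd.DataFrame,
    labels: np.ndarray,
    specimen_ids: np.ndarray,
    seed: int = 0,
    n_splits: int = 5,
) -> pd.Series:
    """Best specimen-grouped CV accuracy achievable with each feature alone.

    Three classifiers (random forest; gradient-boosted trees with depth 3,
    100 estimators, learning rate 1.0; RBF SVM with gamma 0.05, C 1.0,
    tol 0.001) are cross-validated with folds grouped by specimen so that
    the many conditions of one tumour never straddle a train/test split.
    The per-feature score is the maximum mean accuracy over classifiers.
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("labels must contain two classes")
    groups = np.asarray(specimen_ids)
    rng = np.random.default_rng(derive_seed(seed, "scores"))
    perm = rng.permutation(len(labels))
    Xp, yp, gp = X.iloc[perm], labels[perm], groups[perm]
    n_splits = min(n_splits, len(np.unique(groups)))
    splits = list(GroupKFold(n_splits=n_splits).split(Xp, yp, gp))

    scores = {}
    for name in X.columns:
        col = Xp[name].to_numpy(dtype=float).reshape(-1, 1)
        best = 0.0
        for clf_name, clf in _default_classifiers(seed).items():
            accs = []
            for tr, te in splits:
                if len(np.unique(yp[tr])) < 2:
                    continue
                clf.fit(col[tr], yp[tr])
                accs.append(float((clf.predict(col[te]) == yp[te]).mean()))
            if accs:
                best = max(best, float(np.mean(accs)))
        scores[name] = best
    return pd.Series(scores, name="score")


# ---------------------------------------------------------------------------
# Correlation pruning
# ---------------------------------------------------------------------------


@dataclass
class SelectionReport:
    """Outcome of the BH filter plus correlation pruning."""

    selected: list[str]
    discarded_by_bh: list[str]
    pruned_pairs: list[dict] = field(default_factory=list)


def prune_correlated(
    candidates: list[str],
    rmcorr: pd.DataFrame,
    scores: pd.Series,
    threshold: float = 0.9,
    discarded_by_bh: list[str] | None = None,
) -> SelectionReport:
    """Greedy pruning of feature pairs with |r| > threshold.

    Pairs are resolved in descending |r| order; the lower-scoring member is
    dropped, ties broken by the candidate (registry) order.  On exit no
    surviving pair exceeds the threshold.
    """
    order = {n: i for i, n in enumerate(candidates)}
    pairs = []
    for ia, a in enumerate(candidates):
        for b in candidates[ia + 1:]:
            r = abs(float(rmcorr.loc[a, b]))
            if r > threshold:
                pairs.append((r, a, b))
    pairs.sort(key=lambda t: (-t[0], order[t[1]], order[t[2]]))

    alive = set(candidates)
    pruned = []
    for r, a, b in pairs:
        if a not in alive or b not in alive:
            continue
        sa, sb = float(scores[a]), float(scores[b])
        if sa > sb or (sa == sb and order[a] < order[b]):
            keep, drop = a, b
        else:
            keep, drop = b, a
        alive.discard(drop)
        pruned.append(
            {"kept": keep, "dropped": drop, "abs_r": r,
             "kept_score": float(scores[keep]), "dropped_score": float(scores[drop])}
        )
    selected = [n for n in candidates if n in alive]
    return SelectionReport(
        selected=selected,
        discarded_by_bh=list(discarded_by_bh or []),
        pruned_pairs=pruned,
    )


# ---------------------------------------------------------------------------
# Shapley attribution of a fitted model
# ---------------------------------------------------------------------------


def _coalition_value(predict, X, background, mask_bits, k, chunk=262144):
    """v(S) per sample: mean prediction with features outside S drawn from
    the background rows (interventional marginal expectation)."""
    n, m = X.shape[0], background.shape[0]
    synth = np.tile(background, (n, 1))
    in_s = [i for i in range(k) if mask_bits >> i & 1]
    if in_s:
        rep = np.repeat(X[:, in_s], m, axis=0)
        synth[:, in_s] = rep
    preds = np.empty(synth.shape[0])
    for lo in range(0, synth.shape[0], chunk):
        preds[lo:lo + chunk] = predict(synth[lo:lo + chunk])
    return preds.reshape(n, m).mean(axis=1)


def shapley_attributions(
    predict,
    X: np.ndarray,
    background: np.ndarray,
    seed: int = 0,
    exact_max_features: int = 15,
    n_permutations: int = 32,
    eval_budget: float = 2e7,
) -> tuple[np.ndarray, float]:
    """Interventional Shapley attributions of ``predict`` for each row of X.

    Exact coalition enumeration is used when the feature count is at most
    ``exact_max_features`` and the implied prediction workload fits
    ``eval_budget`` rows; otherwise a seeded permutation Monte-Carlo
    estimator.  Either way the attributions of every sample telescope to
    f(x) - base exactly.  Returns (phi (n x k), base value).
    """
    X = np.asarray(X, dtype=float)
    background = np.asarray(background, dtype=float)
    n, k = X.shape
    cache: dict[int, np.ndarray] = {}

    def v(mask_bits: int) -> np.ndarray:
        if mask_bits not in cache:
            cache[mask_bits] = _coalition_value(predict, X, background, mask_bits, k)
        return cache[mask_bits]

    base = float(v(0).mean())
    phi = np.zeros((n, k))

    exact_rows = (2**k) * n * background.shape[0]
    if k <= exact_max_features and exact_rows <= eval_budget:
        from math import factorial

        w = [factorial(s) * factorial(k - 1 - s) / factorial(k) for s in range(k)]
        for mask_bits in range(2**k):
            s = bin(mask_bits).count("1")
            if s == k:
                continue
            vs = v(mask_bits)
            for i in range(k):
                if mask_bits >> i & 1:
                    continue
                phi[:, i] += w[s] * (v(mask_bits | (1 << i)) - vs)
    else:
        rng = np.random.default_rng(derive_seed(seed, "shapley"))
        for _ in range(n_permutations):
            perm = rng.permutation(k)
            mask_bits = 0
            prev = v(0)
            for i in perm:
                mask_bits |= 1 << int(i)
                cur = v(mask_bits)
                phi[:, i] += cur - prev
                prev = cur
        phi /= n_permutations
    return phi, base


@dataclass
class ShapleyRanking:
    """Global and per-sample Shapley importance of a fitted forest."""

    feature_names: list[str]
    attributions: np.ndarray        # (n_samples, n_features)
    base_value: float
    model_output: np.ndarray        # (n_samples,)
    mean_abs: pd.Series             # sorted descending
    degenerate: bool = False


def fit_forest_and_shapley(
    X: pd.DataFrame,
    labels: np.ndarray,
    seed: int = 0,
    positive_class: str = "luminal",
    background_size: int = 32,
    max_explained: int | None = None,
    exact_max_features: int = 15,
    n_permutations: int = 32,
    eval_budget: float = 5e6,
) -> ShapleyRanking:
    """Seeded random-forest fit plus Shapley ranking of its probability output.

    The explained quantity is the predicted probability of ``positive_class``
    (the luminal arm as signal).  ``max_explained`` caps the number of rows
    attributed (seeded subsample) to bound the coalition workload.
    """
    if X.shape[1] < 2:
        raise ValueError("need >= 2 selected features")
    labels = np.asarray(labels)
    forest = RandomForestClassifier(n_estimators=100, random_state=seed)
    forest.fit(X.to_numpy(dtype=float), labels)
    class_idx = int(np.nonzero(forest.classes_ == positive_class)[0][0])

    def predict(A: np.ndarray) -> np.ndarray:
        return forest.predict_proba(A)[:, class_idx]

    rng = np.random.default_rng(derive_seed(seed, "shap-rows"))
    Xv = X.to_numpy(dtype=float)
    rows = np.arange(len(X))
    if max_explained is not None and len(rows) > max_explained:
        rows = np.sort(rng.choice(rows, size=max_explained, replace=False))
    bg_rows = rows if len(rows) <= background_size else np.sort(
        rng.choice(rows, size=background_size, replace=False)
    )
    Xe, Xb = Xv[rows], Xv[bg_rows]

    phi, base = shapley_attributions(
        predict, Xe, Xb, seed=seed,
        exact_max_features=exact_max_features, n_permutations=n_permutations,
        eval_budget=eval_budget,
    )
    out = predict(Xe)
    degenerate = bool(np.allclose(out, out[0]))
    mean_abs = pd.Series(
        np.abs(phi).mean(axis=0), index=X.columns, name="mean_abs_shap"
    ).sort_values(ascending=False)
    return ShapleyRanking(
        feature_names=list(X.columns),
        attributions=phi,
        base_value=base,
        model_output=out,
        mean_abs=mean_abs,
        degenerate=degenerate,
    )
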