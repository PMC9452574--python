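"""Balanced full-factorial eta-squared sensitivity analysis.

For every radiomic feature the total sum of squares across the factorial
condition table is apportioned into main-effect shares

    eta2_f = SS_f / SS_total,     SS_f = sum_levels n_l (mean_l - grand)^2,

one per factor (tumour model, wavelength, grey levels, reconstruction), with
everything not explained by main effects — interactions plus residual —
lumped into a single *error* share so the shares sum to one exactly.  This
is a descriptive variance decomposition, not an inferential ANOVA: balance
is a precondition (with a balanced design every classical sum-of-squares
type coincides), and no p-values are attached.

Also provided: standardisation sweeps (fix one factor at a level and
re-decompose over the rest) and a k-fold specimen-removal scheme that
reports the mean, standard deviation and coefficient of variation of each
eta-squared share across folds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .phantom import derive_seed

DEFAULT_FACTORS = ["tumour_model", "wavelength_nm", "grey_levels", "reconstruction"]
FEATURE_COL = "feature"
VALUE_COL = "value"

# below this mean eta2 a CoV is reported as undefined rather than exploding
COV_MEAN_FLOOR = 1e-6
_DEGENERATE_SS_TOL = 1e-24


class UnbalancedDesignError(ValueError):
    """The factor-level cells of the table do not all have equal counts."""


def check_balance(table: pd.DataFrame, factors: list[str]) -> None:
    """Raise :class:`UnbalancedDesignError` naming offending cells."""
    conditions = table[factors + [FEATURE_COL]].groupby(factors, observed=True).size()
    if conditions.nunique() > 1:
        counts = conditions.value_counts()
        majority = counts.idxmax()
        offending = conditions[conditions != majority]
        raise UnbalancedDesignError(
            f"design is unbalanced over {factors}: cells with deviant counts: "
            f"{offending.head(10).to_dict()}"
        )


def eta_squared_main_effects(
    table: pd.DataFrame, factors: list[str] | None = None
) -> pd.DataFrame:
    """Per-feature main-effect eta-squared shares plus the lumped error term.

    Parameters
    ----------
    table
        Long-format feature table with one row per (condition, feature) and
        columns including ``feature``, ``value`` and every factor name.
    factors
        Factor columns to decompose over; defaults to the study's four.

    Returns
    -------
    DataFrame indexed by feature with one column per factor, an ``error``
    column and a boolean ``degenerate`` column (constant features decompose
    to all-zero shares).  Shares sum to one on non-degenerate features.
    """
    factors = list(DEFAULT_FACTORS if factors is None else factors)
    check_balance(table, factors)

    # (n_rows x n_features) matrix; replicate rows within a cell are kept
    # apart by an explicit replicate counter, not aggregated away
    keyed = table.copy()
    keyed["_rep"] = keyed.groupby(factors + [FEATURE_COL], observed=True).cumcount()
    Y = keyed.pivot_table(
        index=factors + ["_rep"], columns=FEATURE_COL, values=VALUE_COL,
        observed=True, sort=False,
    )
    features = list(Y.columns)
    vals = Y.to_numpy(dtype=float)
    grand = vals.mean(axis=0)
    ss_total = ((vals - grand) ** 2).sum(axis=0)

    shares = {}
    frame = Y.reset_index()
    for f in factors:
        grp = frame.groupby(f, observed=True)[features]
        means = grp.mean().to_numpy(dtype=float)
        counts = grp.size().to_numpy(dtype=float)[:, None]
        ss_f = (counts * (means - grand) ** 2).sum(axis=0)
        shares[f] = ss_f

    degenerate = ss_total <= _DEGENERATE_SS_TOL
    safe_total = np.where(degenerate, 1.0, ss_total)
    out = pd.DataFrame(index=pd.Index(features, name=FEATURE_COL))
    for f in factors:
        out[f] = np.where(degenerate, 0.0, shares[f] / safe_total)
    out["error"] = np.where(degenerate, 0.0, 1.0 - sum(out[f] for f in factors))
    out["degenerate"] = degenerate
    return out


def standardise_and_decompose(
    table: pd.DataFrame,
    fixed_factor: str,
    level,
    factors: list[str] | None = None,
) -> pd.DataFrame:
    """Fix one factor at a level and decompose over the remaining factors."""
    factors = list(DEFAULT_FACTORS if factors is None else factors)
    if fixed_factor not in factors:
        raise ValueError(f"{fixed_factor!r} is not among the factors {factors}")
    sub = table[table[fixed_factor] == level]
    if sub.empty:
        raise ValueError(f"level {level!r} not present in factor {fixed_factor!r}")
    remaining = [f for f in factors if f != fixed_factor]
    return eta_squared_main_effects(sub, remaining)


@dataclass
class FoldCov:
    """Across-fold stability of the eta-squared shares."""

    summary: pd.DataFrame       # feature x factor rows: mean, sd, cov, cov_defined
    per_fold: pd.DataFrame      # fold, feature, factor, eta2
    k: int
    removed: dict[int, list[str]] | None = None  # fold -> removed specimen ids


def kfold_cov(
    table: pd.DataFrame,
    k: int = 5,
    removal_rule: dict[str, int] | None = None,
    seed: int = 0,
    factors: list[str] | None = None,
    model_col: str = "tumour_model",
) -> FoldCov:
    """k seeded folds, each removing specimens per model, then re-decompose.

    ``removal_rule`` maps tumour model to the number of specimens removed in
    each fold (default: the counts that equalise the two arms at
    ``min(n) - max(0, ...)``, e.g. 2 basal and 3 luminal for a 10/11 cohort
    reduced to 8 + 8).  Each fold must remain balanced.
    """
    factors = list(DEFAULT_FACTORS if factors is None else factors)
    spec_models = (
        table[["specimen_id", model_col]].drop_duplicates().set_index("specimen_id")[model_col]
    )
    models = sorted(spec_models.unique())
    counts = spec_models.value_counts()
    if removal_rule is None:
        target = counts.min() - (2 if counts.min() >= 10 else 1)
        target = max(target, 2)
        removal_rule = {m: int(counts[m] - target) for m in models}
    kept_counts = {m: counts[m] - removal_rule.get(m, 0) for m in models}
    if any(v <= 0 for v in kept_counts.values()):
        raise ValueError(f"removal rule {removal_rule} removes too many specimens")
    if len(set(kept_counts.values())) > 1:
        raise UnbalancedDesignError(
            f"removal rule {removal_rule} yields unbalanced folds: {kept_counts}"
        )

    records = []
    removed_by_fold: dict[int, list[str]] = {}
    for fold in range(k):
        rng = np.random.default_rng(derive_seed(seed, "fold", fold))
        removed: list[str] = []
        for m in models:
            ids = sorted(spec_models[spec_models == m].index)
            removed.extend(rng.choice(ids, size=removal_rule.get(m, 0), replace=False))
        removed_by_fold[fold] = removed
        sub = table[~table["specimen_id"].isin(removed)]
        decomp = eta_squared_main_effects(sub, factors)
        for feat, row in decomp.iterrows():
            for f in factors + ["error"]:
                records.append(
                    {"fold": fold, FEATURE_COL: feat, "factor": f, "eta2": row[f]}
                )
    per_fold = pd.DataFrame(records)
    grp = per_fold.groupby([FEATURE_COL, "factor"], observed=True)["eta2"]
    summary = grp.agg(mean="mean", sd=lambda s: s.std(ddof=1)).reset_index()
    defined = summary["mean"].abs() >= COV_MEAN_FLOOR
    summary["cov"] = np.where(defined, summary["sd"] / summary["mean"].abs(), np.nan)
    summary["cov_defined"] = defined
    return FoldCov(summary=summary, per_fold=per_fold, k=k, removed=removed_by_fold)


def classify_robust_features(
    decomp: pd.DataFrame, threshold: float = 0.8, factor: str = "tumour_model"
) -> list[str]:
    """Features whose model eta-squared exceeds the threshold, sorted desc."""
    hits = decomp[decomp[factor] > threshold]
    return list(hits.sort_values(factor, ascending=False).index)
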