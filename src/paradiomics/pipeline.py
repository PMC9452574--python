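"""End-to-end orchestration and I/O: phantom -> features -> sensitivity ->
discrimination, with NIfTI volumes, CSV tables and JSON manifests."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from . import discrimination as disc
from . import features as feat
from . import phantom as ph
from . import sensitivity as sens

log = logging.getLogger("paradiomics")

LONG_COLUMNS = [
    "specimen_id", "tumour_model", "wavelength_nm", "grey_levels",
    "reconstruction", "voi_voxels", "feature", "value", "degenerate_flag",
]
SCHEMA_VERSION = "1"


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------


def _affine(spacing_mm) -> np.ndarray:
    aff = np.diag(list(spacing_mm) + [1.0])
    return aff


def write_volume(path: str | Path, volume: ph.ImageVolume) -> None:
    img = nib.Nifti1Image(volume.values.astype(np.float32), _affine(volume.spacing_mm))
    nib.save(img, str(path))


def write_mask(path: str | Path, mask: ph.VoiMask, spacing_mm=(0.075, 0.075, 1.0)) -> None:
    img = nib.Nifti1Image(mask.mask.astype(np.uint8), _affine(spacing_mm))
    nib.save(img, str(path))


def read_volume_and_mask(
    volume_path: str | Path, mask_path: str | Path
) -> tuple[ph.ImageVolume, ph.VoiMask]:
    """Load an aligned volume/mask pair, validating grids and mask coding."""
    vimg = nib.load(str(volume_path))
    mimg = nib.load(str(mask_path))
    vdata = np.asarray(vimg.dataobj, dtype=np.float64)
    mdata = np.asarray(mimg.dataobj)
    if vdata.shape != mdata.shape:
        raise ValueError(
            f"grid mismatch: volume {vdata.shape} vs mask {mdata.shape} "
            f"({volume_path} / {mask_path})"
        )
    if not np.allclose(vimg.affine, mimg.affine, atol=1e-6):
        raise ValueError(f"affine mismatch between {volume_path} and {mask_path}")
    offenders = sorted(set(np.unique(mdata).tolist()) - {0, 1})
    if offenders:
        raise ValueError(f"mask {mask_path} is not 0/1 coded; offending values: {offenders}")
    spacing = tuple(float(z) for z in vimg.header.get_zooms()[:3])
    return ph.ImageVolume(vdata, spacing_mm=spacing), ph.VoiMask(mdata.astype(bool))


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Everything a full pipeline run needs, serialisable to YAML."""

    seed: int = 0
    output_dir: str = "paradiomics_run"
    phantom: ph.PhantomConfig = field(default_factory=ph.PhantomConfig)
    n_basal: int = 10
    n_luminal: int = 11
    wavelengths: tuple[int, ...] = ph.WAVELENGTHS_NM
    grey_levels: tuple[int, ...] = ph.GREY_LEVELS
    reconstructions: tuple[str, ...] = ph.RECONSTRUCTIONS
    folds: int = 5
    fold_removal: dict | None = None        # tumour model -> n removed per fold
    q_fdr: float = 0.25
    corr_threshold: float = 0.9
    eta_threshold: float = 0.8
    standardise_factors: tuple[str, ...] = ("grey_levels", "reconstruction")
    score_max_rows: int = 600
    shap_max_samples: int = 128
    shap_background: int = 24
    shap_permutations: int = 32
    persist_volumes: bool = True
    render_plots: bool = False

    def __post_init__(self):
        # propagate the master seed into the phantom unless explicitly set
        if isinstance(self.phantom, dict):
            self.phantom = ph.PhantomConfig(**self.phantom)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return json.loads(json.dumps(d, default=list))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class RunManifest:
    """Counts and provenance of one pipeline run."""

    config_hash: str
    seed: int
    n_specimens: int
    n_design_rows_balanced: int
    n_design_rows_full: int
    n_features: int
    n_robust_features: int
    n_bh_survivors: int
    n_selected: int
    fold_k: int
    stage_seconds: dict = field(default_factory=dict)
    version: str = "0.1.0"

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# Feature-table construction
# ---------------------------------------------------------------------------


def extract_cohort_features(
    config: ph.PhantomConfig,
    specimens: Sequence[ph.SpecimenSpec],
    wavelengths: Sequence[int] = ph.WAVELENGTHS_NM,
    grey_levels: Sequence[int] = ph.GREY_LEVELS,
    reconstructions: Sequence[str] = ph.RECONSTRUCTIONS,
) -> pd.DataFrame:
    """Simulate every condition in memory and extract all 93 features.

    Returns the long-format feature table (one row per condition x feature).
    """
    records = []
    for spec in specimens:
        for w in wavelengths:
            for r in reconstructions:
                vol, mask = ph.simulate_condition(spec, config, int(w), str(r))
                for g in grey_levels:
                    fv = feat.extract_features(vol, mask, int(g))
                    for name, value in fv.values.items():
                        records.append(
                            (spec.specimen_id, spec.tumour_model, int(w), int(g),
                             str(r), mask.voxel_count, name, value,
                             name in fv.degenerate)
                        )
    return pd.DataFrame(records, columns=LONG_COLUMNS)


def extract_features_from_design(design: pd.DataFrame) -> pd.DataFrame:
    """Extract features for a persisted cohort (design rows carry file paths)."""
    records = []
    for (vp, mp), sub in design.groupby(["volume_path", "mask_path"], sort=False):
        vol, mask = read_volume_and_mask(vp, mp)
        for _, row in sub.iterrows():
            fv = feat.extract_features(vol, mask, int(row["grey_levels"]))
            for name, value in fv.values.items():
                records.append(
                    (row["specimen_id"], row["tumour_model"], int(row["wavelength_nm"]),
                     int(row["grey_levels"]), row["reconstruction"], mask.voxel_count,
                     name, value, name in fv.degenerate)
                )
    return pd.DataFrame(records, columns=LONG_COLUMNS)


def long_to_wide(table: pd.DataFrame) -> pd.DataFrame:
    """Pivot the long feature table to one row per condition."""
    keys = ["specimen_id", "tumour_model", "wavelength_nm", "grey_levels",
            "reconstruction", "voi_voxels"]
    wide = table.pivot_table(
        index=keys, columns="feature", values="value", observed=True, sort=False
    )
    return wide[list(feat.FEATURE_NAMES)].reset_index()


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute all stages, persisting every intermediate table.

    Deterministic (byte-identical manifests) under identical config + seed.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage_seconds: dict[str, float] = {}

    def _stage(name):
        log.info("stage %s", name)
        return time.perf_counter()

    # -- phantom cohort ----------------------------------------------------
    t0 = _stage("phantom")
    pconf = dataclasses.replace(config.phantom, seed=config.seed)
    specimens = ph.make_specimens(pconf, config.n_basal, config.n_luminal)
    if config.persist_volumes:
        ph.generate_cohort(
            pconf, specimens, out / "cohort", config.wavelengths,
            config.grey_levels, config.reconstructions,
        )
    design_full = ph.build_design_table(
        specimens, config.wavelengths, config.grey_levels, config.reconstructions
    )
    design_balanced = ph.build_design_table(
        specimens, config.wavelengths, config.grey_levels, config.reconstructions,
        balance=True, seed=config.seed,
    )
    design_full.to_csv(out / "design_full.csv", index=False)
    design_balanced.to_csv(out / "design_balanced.csv", index=False)
    stage_seconds["phantom"] = time.perf_counter() - t0

    # -- feature extraction ------------------------------------------------
    t0 = _stage("features")
    table = extract_cohort_features(
        pconf, specimens, config.wavelengths, config.grey_levels, config.reconstructions
    )
    table.to_csv(out / "features_long.csv", index=False)
    stage_seconds["features"] = time.perf_counter() - t0

    # -- sensitivity analysis (balanced subset) ----------------------------
    t0 = _stage("sensitivity")
    balanced_ids = set(design_balanced["specimen_id"])
    table_bal = table[table["specimen_id"].isin(balanced_ids)]
    decomp = sens.eta_squared_main_effects(table_bal)
    decomp.to_csv(out / "eta2.csv")
    robust = sens.classify_robust_features(decomp, threshold=config.eta_threshold)
    for factor in config.standardise_factors:
        for level in sorted(table_bal[factor].unique()):
            d = sens.standardise_and_decompose(table_bal, factor, level)
            d.to_csv(out / f"eta2_std_{factor}_{level}.csv")
    fold = sens.kfold_cov(
        table, k=config.folds, removal_rule=config.fold_removal, seed=config.seed
    )
    fold.summary.to_csv(out / "fold_cov.csv", index=False)
    stage_seconds["sensitivity"] = time.perf_counter() - t0

    # -- discrimination (all specimens) ------------------------------------
    t0 = _stage("discrimination")
    wide = long_to_wide(table)
    X = wide[list(feat.FEATURE_NAMES)]
    labels = wide["tumour_model"].to_numpy()
    specimen_ids = wide["specimen_id"].to_numpy()
    volumes = wide["voi_voxels"].to_numpy(dtype=float)

    Xc, vol_report = disc.correct_volume_dependency(X, volumes)
    vol_report.to_csv(out / "volume_correction.csv")

    constant = [c for c in Xc.columns if Xc[c].nunique() <= 1]
    if constant:
        log.info("excluding %d zero-variance features from KW: %s", len(constant), constant)
    kw = disc.kruskal_wallis_table(Xc.drop(columns=constant), labels)
    bh = disc.benjamini_hochberg(kw["p"], q=config.q_fdr)
    kw.join(bh[["rank", "critical", "reject"]]).to_csv(out / "kw_bh.csv")
    survivors = [n for n in feat.FEATURE_NAMES if n in bh.index and bh.loc[n, "reject"]]
    discarded = [n for n in feat.FEATURE_NAMES if n not in survivors]

    rng = np.random.default_rng(ph.derive_seed(config.seed, "score-rows"))
    if config.score_max_rows and len(wide) > config.score_max_rows:
        rows = np.sort(rng.choice(len(wide), size=config.score_max_rows, replace=False))
    else:
        rows = np.arange(len(wide))

    R = disc.rmcorr_matrix(Xc[survivors], specimen_ids)
    R.to_csv(out / "rmcorr.csv")
    scores = disc.single_feature_scores(
        Xc[survivors].iloc[rows], labels[rows], specimen_ids[rows], seed=config.seed
    )
    scores.to_csv(out / "single_feature_scores.csv")
    report = disc.prune_correlated(
        survivors, R, scores, threshold=config.corr_threshold, discarded_by_bh=discarded
    )
    (out / "selection_report.json").write_text(
        json.dumps(
            {"selected": report.selected, "discarded_by_bh": report.discarded_by_bh,
             "pruned_pairs": report.pruned_pairs},
            indent=2,
        )
    )
    ranking = disc.fit_forest_and_shapley(
        Xc[report.selected], labels, seed=config.seed,
        background_size=config.shap_background,
        max_explained=config.shap_max_samples,
        n_permutations=config.shap_permutations,
    )
    ranking.mean_abs.to_csv(out / "shapley_ranking.csv")
    stage_seconds["discrimination"] = time.perf_counter() - t0

    if config.render_plots:
        render_eta_chart(decomp, out / "eta2_stacked.png")
        render_shap_chart(ranking.mean_abs, out / "shap_ranking.png")

    manifest = RunManifest(
        config_hash=config.config_hash(),
        seed=config.seed,
        n_specimens=len(specimens),
        n_design_rows_balanced=len(design_balanced),
        n_design_rows_full=len(design_full),
        n_features=len(feat.FEATURE_NAMES),
        n_robust_features=len(robust),
        n_bh_survivors=len(survivors),
        n_selected=len(report.selected),
        fold_k=config.folds,
        stage_seconds={},  # excluded from the hashable payload for idempotence
    )
    (out / "manifest.json").write_text(manifest.to_json())
    (out / "timings.json").write_text(json.dumps(stage_seconds, indent=2))
    return manifest


# ---------------------------------------------------------------------------
# Optional rendering
# ---------------------------------------------------------------------------


def render_eta_chart(decomp: pd.DataFrame, path: str | Path) -> None:
    """Stacked-bar chart of the eta-squared shares per feature."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cols = [c for c in decomp.columns if c not in ("degenerate",)]
    ax = decomp[cols].plot.bar(stacked=True, figsize=(18, 5), width=1.0)
    ax.set_ylabel("eta-squared share")
    ax.set_xticks([])
    plt.tight_layout()
    plt.savefig(path, dpi=120)
    plt.close()


def render_shap_chart(mean_abs: pd.Series, path: str | Path) -> None:
    """Bar chart of mean absolute Shapley attributions (descending)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ax = mean_abs.iloc[::-1].plot.barh(figsize=(6, 0.3 * len(mean_abs) + 1))
    ax.set_xlabel("mean |Shapley attribution|")
    plt.tight_layout()
    plt.savefig(path, dpi=120)
    plt.close()
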