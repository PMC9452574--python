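"""Factorial study design and synthetic photoacoustic tumour phantoms.

The phantom cohort emulates the statistical structure of a two-arm
patient-derived-xenograft (PDX) photoacoustic imaging study:

* two tumour models whose voxel-intensity histograms differ in shape —
  *basal* tumours are right-tailed (positively skewed), *luminal* tumours
  near-Gaussian;
* wavelength-dependent image contrast built from a synthetic two-chromophore
  (oxy/deoxy-haemoglobin-like) mixing curve whose model-specific scale
  factors coincide at the 800 nm isobestic point;
* two reconstruction surrogates (backprojection-like additive noise vs.
  model-based-like smoothing plus affine intensity rescale) that shift
  first-order statistics while approximately preserving histogram skewness;
* basal tumour volumes larger on average and with a wider spread than
  luminal ones.

No physical photoacoustic forward model is involved: the generator only has
to realise the variance structure the downstream sensitivity and
discrimination analyses assume.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

# ---------------------------------------------------------------------------
# Study factor levels
# ---------------------------------------------------------------------------

WAVELENGTHS_NM: tuple[int, ...] = (700, 730, 750, 760, 770, 800, 820, 840, 850)
GREY_LEVELS: tuple[int, ...] = (8, 16, 32, 64, 128, 256)
RECONSTRUCTIONS: tuple[str, ...] = ("backprojection", "model_based")
TUMOUR_MODELS: tuple[str, ...] = ("basal", "luminal")
ISOBESTIC_NM = 800

DESIGN_COLUMNS = [
    "specimen_id",
    "tumour_model",
    "wavelength_nm",
    "grey_levels",
    "reconstruction",
]


def derive_seed(*parts) -> int:
    """Deterministic child seed from arbitrary string-able parts (< 2**31)."""
    token = ":".join(str(p) for p in parts)
    digest = hashlib.sha256(token.encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SpecimenSpec:
    """One tumour specimen: identity, model arm and target VOI size."""

    specimen_id: str
    tumour_model: str
    target_voi_voxels: int

    def __post_init__(self):
        if self.tumour_model not in TUMOUR_MODELS:
            raise ValueError(
                f"tumour_model must be one of {TUMOUR_MODELS}, got {self.tumour_model!r}"
            )
        if self.target_voi_voxels < 27:
            raise ValueError("target_voi_voxels must be >= 27 (a 3x3x3 core)")


@dataclass
class ImageVolume:
    """A 3D scalar image with anisotropic voxel spacing in mm."""

    values: np.ndarray
    spacing_mm: tuple[float, float, float] = (0.075, 0.075, 1.0)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError("values must be a 3D array")
        if min(self.values.shape) < 1:
            raise ValueError("all dimensions must be >= 1")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing must be strictly positive")

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))


@dataclass
class VoiMask:
    """Binary volume-of-interest mask aligned with an :class:`ImageVolume`."""

    mask: np.ndarray

    def __post_init__(self):
        self.mask = np.asarray(self.mask).astype(bool)
        if self.mask.ndim != 3:
            raise ValueError("mask must be a 3D array")
        if not self.mask.any():
            raise ValueError("mask must contain at least one foreground voxel")

    @property
    def voxel_count(self) -> int:
        return int(self.mask.sum())

    def is_single_component(self) -> bool:
        _, n = ndimage.label(self.mask, structure=np.ones((3, 3, 3)))
        return n == 1


@dataclass
class PhantomConfig:
    """Parameters of the synthetic cohort generator.

    Intensity units are arbitrary (photoacoustic amplitude); volumes are in
    voxels on the fixed (0.075, 0.075, 1.0) mm grid.
    """

    seed: int = 0
    grid_shape: tuple[int, int, int] = (32, 32, 10)
    spacing_mm: tuple[float, float, float] = (0.075, 0.075, 1.0)
    # intensity histograms inside the VOI
    basal_gamma_shape: float = 2.0      # skewness 2/sqrt(shape) ~ 1.41
    basal_gamma_scale: float = 1.5
    luminal_mean: float = 5.0
    luminal_sd: float = 1.0
    shape_jitter: float = 0.15          # specimen-level lognormal jitter
    # VOI volume distributions (voxels); basal larger and more spread
    basal_volume_mean: float = 550.0
    basal_volume_sd: float = 180.0
    luminal_volume_mean: float = 350.0
    luminal_volume_sd: float = 80.0
    min_volume: int = 64
    # wavelength contrast curve (two-chromophore mixing)
    contrast_amplitude: float = 0.25
    contrast_width_nm: float = 60.0
    basal_oxygenation: float = 0.30
    luminal_oxygenation: float = 0.70
    curve_domain_nm: tuple[float, float] = (650.0, 900.0)
    # reconstruction surrogates
    bp_noise_amplitude: float = 0.25
    mb_smoothing_sigma: float = 0.4
    mb_gain: float = 0.85
    mb_offset: float = 0.3
    # background
    background_scale: float = 0.3

    def __post_init__(self):
        for name in (
            "basal_gamma_shape", "basal_gamma_scale", "luminal_sd",
            "basal_volume_mean", "basal_volume_sd", "luminal_volume_mean",
            "luminal_volume_sd", "contrast_width_nm", "background_scale",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not self.basal_volume_mean > self.luminal_volume_mean:
            raise ValueError("basal mean volume must exceed luminal mean volume")


# ---------------------------------------------------------------------------
# Design table
# ---------------------------------------------------------------------------


def make_specimens(
    config: PhantomConfig, n_basal: int = 10, n_luminal: int = 11
) -> list[SpecimenSpec]:
    """Draw a cohort of specimens with model-specific volume distributions."""
    rng = np.random.default_rng(derive_seed(config.seed, "specimens"))
    specs: list[SpecimenSpec] = []
    for i in range(n_basal):
        v = rng.normal(config.basal_volume_mean, config.basal_volume_sd)
        v = int(max(config.min_volume, round(v)))
        specs.append(SpecimenSpec(f"B{i + 1:02d}", "basal", v))
    for i in range(n_luminal):
        v = rng.normal(config.luminal_volume_mean, config.luminal_volume_sd)
        v = int(max(config.min_volume, round(v)))
        specs.append(SpecimenSpec(f"L{i + 1:02d}", "luminal", v))
    return specs


def build_design_table(
    specimens: Sequence[SpecimenSpec],
    wavelengths: Sequence[int] = WAVELENGTHS_NM,
    grey_levels: Sequence[int] = GREY_LEVELS,
    reconstructions: Sequence[str] = RECONSTRUCTIONS,
    balance: bool = False,
    seed: int = 0,
) -> pd.DataFrame:
    """Full Cartesian product of specimens and acquisition factor levels.

    With ``balance=True`` the specimen counts per tumour model are equalised
    by removing seeded-random surplus specimens from the larger arm, so the
    resulting factorial design is balanced for the variance decomposition.
    """
    if len(specimens) == 0:
        raise ValueError("specimen list is empty")
    for name, levels in (
        ("wavelengths", wavelengths),
        ("grey_levels", grey_levels),
        ("reconstructions", reconstructions),
    ):
        if len(levels) == 0:
            raise ValueError(f"factor level list {name!r} is empty")

    specimens = list(specimens)
    if len({s.specimen_id for s in specimens}) != len(specimens):
        raise ValueError("specimen_id values must be unique within a cohort")

    if balance:
        by_model = {m: [s for s in specimens if s.tumour_model == m] for m in TUMOUR_MODELS}
        if all(len(v) == 0 for v in by_model.values()):
            raise ValueError("balance requested but both model groups are empty")
        n_keep = min(len(v) for v in by_model.values() if v)
        rng = np.random.default_rng(derive_seed(seed, "balance"))
        kept: list[SpecimenSpec] = []
        for model in TUMOUR_MODELS:
            group = by_model[model]
            surplus = len(group) - n_keep
            if surplus > 0:
                drop_idx = set(rng.choice(len(group), size=surplus, replace=False).tolist())
                group = [s for i, s in enumerate(group) if i not in drop_idx]
            kept.extend(group)
        specimens = kept

    rows = [
        {
            "specimen_id": s.specimen_id,
            "tumour_model": s.tumour_model,
            "wavelength_nm": int(w),
            "grey_levels": int(g),
            "reconstruction": str(r),
        }
        for s in specimens
        for w in wavelengths
        for g in grey_levels
        for r in reconstructions
    ]
    return pd.DataFrame(rows, columns=DESIGN_COLUMNS)


# ---------------------------------------------------------------------------
# Specimen simulation
# ---------------------------------------------------------------------------


def _ellipsoid_mask(grid_shape, target_voxels: int, rng: np.random.Generator) -> np.ndarray:
    gx, gy, gz = grid_shape
    c = min((gz - 1) / 2.0 - 0.5, 3.5)
    if c < 1.0:
        c = max((gz - 1) / 2.0, 0.5)
    a0 = np.sqrt(3.0 * target_voxels / (4.0 * np.pi * c))
    ratio = rng.uniform(0.85, 1.18)
    a, b = a0 * ratio, a0 / ratio
    if a > (gx - 1) / 2.0 - 0.5 or b > (gy - 1) / 2.0 - 0.5:
        raise ValueError(
            f"target VOI of {target_voxels} voxels exceeds grid capacity {grid_shape}"
        )
    cx, cy, cz = (gx - 1) / 2.0, (gy - 1) / 2.0, (gz - 1) / 2.0
    X, Y, Z = np.meshgrid(np.arange(gx), np.arange(gy), np.arange(gz), indexing="ij")
    mask = ((X - cx) / a) ** 2 + ((Y - cy) / b) ** 2 + ((Z - cz) / c) ** 2 <= 1.0
    return mask


def simulate_specimen(
    spec: SpecimenSpec, config: PhantomConfig, seed: int
) -> tuple[ImageVolume, VoiMask]:
    """Simulate the base (pre-contrast, pre-reconstruction) tumour image.

    VOI voxels follow a gamma distribution (right-skewed) for basal tumours
    and a zero-truncated Gaussian for luminal tumours; the background is a
    dim exponential field. Deterministic given (spec, config, seed).
    """
    rng = np.random.default_rng(seed)
    mask = _ellipsoid_mask(config.grid_shape, spec.target_voi_voxels, rng)
    n = int(mask.sum())

    values = rng.exponential(config.background_scale, size=config.grid_shape)
    jitter = float(np.exp(config.shape_jitter * rng.standard_normal()))
    if spec.tumour_model == "basal":
        voi = rng.gamma(config.basal_gamma_shape * jitter, config.basal_gamma_scale, size=n)
    else:
        voi = rng.normal(config.luminal_mean * jitter, config.luminal_sd, size=n)
        voi = np.maximum(voi, 1e-3)
    values[mask] = voi
    vol = ImageVolume(values, spacing_mm=config.spacing_mm)
    return vol, VoiMask(mask)


# ---------------------------------------------------------------------------
# Wavelength contrast
# ---------------------------------------------------------------------------


def wavelength_scale(tumour_model: str, wavelength_nm: float, config: PhantomConfig) -> float:
    """Closed-form contrast factor of the synthetic two-chromophore curve.

    The oxy- and deoxy-like extinction curves are ``1 ± A tanh((λ-800)/w)``;
    a tumour with oxygenation fraction f sees ``f ε_oxy + (1-f) ε_deoxy``.
    Both model curves equal 1 exactly at the 800 nm isobestic point.
    """
    lo, hi = config.curve_domain_nm
    if not (lo <= wavelength_nm <= hi):
        raise ValueError(
            f"wavelength {wavelength_nm} nm outside configured curve domain [{lo}, {hi}]"
        )
    if tumour_model not in TUMOUR_MODELS:
        raise ValueError(f"unknown tumour model {tumour_model!r}")
    f = config.basal_oxygenation if tumour_model == "basal" else config.luminal_oxygenation
    t = np.tanh((wavelength_nm - ISOBESTIC_NM) / config.contrast_width_nm)
    return float(1.0 + config.contrast_amplitude * (2.0 * f - 1.0) * t)


def apply_wavelength_contrast(
    volume: ImageVolume,
    mask: VoiMask,
    wavelength_nm: float,
    config: PhantomConfig,
    tumour_model: str,
) -> ImageVolume:
    """Rescale VOI intensities by the model's contrast factor at a wavelength.

    Multiplication by a positive scalar, hence rank-preserving within the VOI.
    """
    scale = wavelength_scale(tumour_model, wavelength_nm, config)
    out = volume.values.copy()
    out[mask.mask] *= scale
    return ImageVolume(out, spacing_mm=volume.spacing_mm)


# ---------------------------------------------------------------------------
# Reconstruction surrogates
# ---------------------------------------------------------------------------


def apply_reconstruction_surrogate(
    volume: ImageVolume, reconstruction: str, config: PhantomConfig, seed: int
) -> ImageVolume:
    """Emulate the first-order-statistics footprint of a reconstruction choice.

    ``backprojection``: identity plus seeded high-frequency (white) additive
    noise. ``model_based``: in-plane Gaussian smoothing followed by an affine
    intensity rescale. Both shift means/percentiles relative to each other
    while approximately preserving histogram skewness.
    """
    if reconstruction == "backprojection":
        rng = np.random.default_rng(seed)
        out = volume.values + config.bp_noise_amplitude * rng.standard_normal(volume.values.shape)
    elif reconstruction == "model_based":
        out = volume.values
        if config.mb_smoothing_sigma > 0:
            out = ndimage.gaussian_filter(
                out, sigma=(config.mb_smoothing_sigma, config.mb_smoothing_sigma, 0.0)
            )
        out = config.mb_gain * out + config.mb_offset
    else:
        raise ValueError(f"unknown reconstruction {reconstruction!r}")
    return ImageVolume(out, spacing_mm=volume.spacing_mm)


def simulate_condition(
    spec: SpecimenSpec,
    config: PhantomConfig,
    wavelength_nm: int,
    reconstruction: str,
) -> tuple[ImageVolume, VoiMask]:
    """Full in-memory chain: base image -> wavelength contrast -> surrogate.

    All seeds derive deterministically from ``config.seed`` and the condition
    identity, so repeated calls are bit-identical.
    """
    base, mask = simulate_specimen(spec, config, derive_seed(config.seed, spec.specimen_id))
    vol = apply_wavelength_contrast(base, mask, wavelength_nm, config, spec.tumour_model)
    vol = apply_reconstruction_surrogate(
        vol, reconstruction,
        config,
        derive_seed(config.seed, spec.specimen_id, wavelength_nm, reconstruction),
    )
    return vol, mask


# ---------------------------------------------------------------------------
# Cohort generation (persisted)
# ---------------------------------------------------------------------------


def generate_cohort(
    config: PhantomConfig,
    specimens: Sequence[SpecimenSpec],
    output_dir: str | Path,
    wavelengths: Sequence[int] = WAVELENGTHS_NM,
    grey_levels: Sequence[int] = GREY_LEVELS,
    reconstructions: Sequence[str] = RECONSTRUCTIONS,
) -> pd.DataFrame:
    """Persist one volume per (specimen, wavelength, reconstruction) plus masks.

    Grey-level quantisation happens at feature extraction, so the design
    table enumerates every grey-level setting per volume without separate
    image files. Returns the design table (also written to ``design.csv``
    together with a ``manifest.json`` recording all derived seeds).
    """
    from .pipeline import write_mask, write_volume  # local import avoids cycle

    out = Path(output_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:  # pragma: no cover - environment dependent
        raise OSError(f"cannot create output directory {out}: {exc}") from exc

    records = []
    seeds: dict[str, int] = {}
    for spec in specimens:
        _, mask = simulate_specimen(spec, config, derive_seed(config.seed, spec.specimen_id))
        mask_path = out / f"{spec.specimen_id}_mask.nii.gz"
        write_mask(mask_path, mask, spacing_mm=config.spacing_mm)
        seeds[spec.specimen_id] = derive_seed(config.seed, spec.specimen_id)
        for w in wavelengths:
            for r in reconstructions:
                vol, _ = simulate_condition(spec, config, int(w), str(r))
                vol_path = out / f"{spec.specimen_id}_{int(w)}nm_{r}.nii.gz"
                write_volume(vol_path, vol)
                seeds[f"{spec.specimen_id}:{int(w)}:{r}"] = derive_seed(
                    config.seed, spec.specimen_id, int(w), r
                )
                for g in grey_levels:
                    records.append(
                        {
                            "specimen_id": spec.specimen_id,
                            "tumour_model": spec.tumour_model,
                            "wavelength_nm": int(w),
                            "grey_levels": int(g),
                            "reconstruction": str(r),
                            "volume_path": str(vol_path),
                            "mask_path": str(mask_path),
                        }
                    )
    design = pd.DataFrame(records)
    design.to_csv(out / "design.csv", index=False)
    manifest = {
        "config": {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(config).items()},
        "n_specimens": len(specimens),
        "n_volume_files": len(specimens) * len(wavelengths) * len(reconstructions),
        "n_design_rows": len(design),
        "seeds": seeds,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return design
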