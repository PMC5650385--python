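"""Synthetic NPC-like cohort generator.

Emulates the structure of the study data end-to-end so the whole pipeline is
testable without any download: per patient, two co-registered 3-D MR-like
volumes (T2w-like and contrast-enhanced T1w-like) sharing one ellipsoidal
tumor mask, a clinical record with realistic marginals (age, sex, overall
stage III/IV, hemoglobin, platelets), right-censored progression-free
survival, and a 70/30 discovery/validation split.

Intratumoral texture is a Gaussian random field whose correlation length and
contrast are monotone in a scalar latent heterogeneity in [0, 1] (0 = smooth,
homogeneous tumor; 1 = rough, heterogeneous), plus a patient-specific coarse
component and white-noise floor so that texture features across filter
variants retain idiosyncratic variation.  Hazard follows a proportional-
hazards model whose linear predictor is a linear combination of z-scored
*planted* texture features realized from the generated images — by default
the five features of the published signature — while clinical covariates are
independent of hazard (the study found them non-prognostic).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

from . import features as feat
from .imaging import ImageVolume, ROIMask
from .survival import SurvivalRecord

__all__ = [
    "ClinicalRanges",
    "CohortConfig",
    "ClinicalRecord",
    "SyntheticPatient",
    "SyntheticCohort",
    "DEFAULT_PLANTED_KEYS",
    "generate_tumor_pair",
    "simulate_survival",
    "generate_cohort",
]

#: Default planted prognostic features: five texture features spread over
#: both sequences, four filter variants and three families, chosen for
#: bounded redundancy within the reference catalog (no near-duplicate twin
#: elsewhere in the 970) so that sparse support recovery is well-posed.
DEFAULT_PLANTED_KEYS: tuple[str, ...] = (
    "T2w_7_GLCM_correlation",
    "CET1w_12_GLCM_cluster_shade",
    "T2w_1_firstorder_kurtosis",
    "CET1w_11_GLRLM_gln",
    "CET1w_2_GLCM_inverse_variance",
)


@dataclass(frozen=True)
class ClinicalRanges:
    """Marginal distributions of the clinical covariates.

    Defaults reproduce the study cohort's marginals: median age ~43 years,
    ~75% male, ~35% stage IV, hemoglobin centred between the two sets'
    interquartile ranges, platelets likewise.
    """

    age_mean: float = 43.0
    age_sd: float = 9.5
    age_bounds: tuple[float, float] = (18.0, 75.0)
    p_male: float = 0.75
    p_stage_iv: float = 0.35
    hemoglobin_mean: float = 155.0
    hemoglobin_sd: float = 20.0
    hemoglobin_bounds: tuple[float, float] = (90.0, 260.0)
    platelet_mean: float = 170.0
    platelet_sd: float = 45.0
    platelet_bounds: tuple[float, float] = (60.0, 420.0)


@dataclass(frozen=True)
class CohortConfig:
    """Study-design parameters of the synthetic cohort."""

    n_patients: int = 100
    discovery_fraction: float = 0.7
    seed: int = 0
    grid_shape: tuple[int, int, int] = (32, 32, 16)
    voxel_spacing_mm: tuple[float, float, float] = (0.9, 0.9, 4.0)
    planted_feature_keys: tuple[str, ...] = DEFAULT_PLANTED_KEYS
    effect_sizes: tuple[float, ...] = (1.0, 1.0, 1.0, 1.0, -1.0)
    baseline_hazard: float = 0.015  # events / month at linear predictor 0
    censor_window_months: float = 89.0
    clinical_ranges: ClinicalRanges = field(default_factory=ClinicalRanges)
    n_bins: int = 32

    @property
    def n_planted_features(self) -> int:
        return len(self.planted_feature_keys)

    def validate(self) -> None:
        if self.n_patients < 4:
            raise ValueError("n_patients must be >= 4")
        if not 0.0 < self.discovery_fraction < 1.0:
            raise ValueError("discovery_fraction must be in (0, 1)")
        if len(self.grid_shape) != 3 or any(s < 4 for s in self.grid_shape):
            raise ValueError("grid_shape must be 3 voxel counts >= 4")
        if any(s <= 0 for s in self.voxel_spacing_mm):
            raise ValueError("voxel spacings must be positive")
        if len(self.effect_sizes) != self.n_planted_features:
            raise ValueError(
                "effect_sizes must have one entry per planted feature "
                f"({len(self.effect_sizes)} vs {self.n_planted_features})"
            )
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be > 0")
        if self.censor_window_months < 0:
            raise ValueError("censor_window_months must be >= 0")


@dataclass(frozen=True)
class ClinicalRecord:
    age_years: int
    sex: str  # male / female
    overall_stage: str  # III / IV
    hemoglobin_g_per_L: float
    platelet_1e9_per_L: float

    def __post_init__(self) -> None:
        if self.age_years <= 0:
            raise ValueError("age must be positive")
        if self.hemoglobin_g_per_L <= 0 or self.platelet_1e9_per_L <= 0:
            raise ValueError("hemoglobin and platelets must be positive")
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be male/female, got {self.sex!r}")
        if self.overall_stage not in ("III", "IV"):
            raise ValueError(f"overall_stage must be III/IV, got {self.overall_stage!r}")


@dataclass
class SyntheticPatient:
    patient_id: str
    volume_t2: ImageVolume
    volume_cet1: ImageVolume
    mask: ROIMask
    clinical: ClinicalRecord
    latent_heterogeneity: float
    survival: SurvivalRecord | None = None
    split_label: str = ""


def _ellipsoid_mask(config: CohortConfig, rng: np.random.Generator) -> np.ndarray:
    shape = np.asarray(config.grid_shape, dtype=float)
    center = (shape - 1) / 2.0
    radii = 0.30 * shape * rng.uniform(0.82, 1.12, size=3)
    if np.any(radii < 1.2):
        raise ValueError(
            f"grid {config.grid_shape} too small to contain an ellipsoid tumor mask"
        )
    radii = np.minimum(radii, shape / 2.0 - 1.0)
    grids = np.indices(config.grid_shape).astype(float)
    dist2 = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center, radii))
    mask = dist2 <= 1.0
    if not mask.any():
        raise ValueError("grid too small to contain the tumor mask")
    return mask


def _textured_field(
    shape: tuple[int, int, int], h: float, rng: np.random.Generator
) -> np.ndarray:
    """Unit-variance random field; rougher (shorter-range, noisier) as h -> 1."""
    corr_len = 2.2 - 1.8 * h  # voxels, in-plane
    aniso = rng.uniform(0.8, 1.25)
    base = ndimage.gaussian_filter(
        rng.standard_normal(shape), sigma=(corr_len, corr_len * aniso, corr_len)
    )
    base /= base.std()
    coarse = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=3.0)
    coarse /= coarse.std()
    w_coarse = rng.uniform(0.2, 0.5)
    w_white = 0.10 + 0.30 * h
    w_base = np.sqrt(max(1e-6, 1.0 - w_coarse**2 - w_white**2))
    field = w_base * base + w_coarse * coarse + w_white * rng.standard_normal(shape)
    return field / field.std()


def generate_tumor_pair(
    config: CohortConfig, latent_heterogeneity: float, rng: np.random.Generator
) -> tuple[ImageVolume, ImageVolume, ROIMask]:
    """One patient's aligned (T2w-like, CET1w-like) volumes and tumor mask.

    Both sequences share the mask and the latent heterogeneity but have
    independent field realizations.  Intratumoral contrast grows and the
    correlation length shrinks monotonically with ``latent_heterogeneity``.
    """
    if not 0.0 <= latent_heterogeneity <= 1.0:
        raise ValueError("latent_heterogeneity must be in [0, 1]")
    h = float(latent_heterogeneity)
    mask = _ellipsoid_mask(config, rng)
    spacing = config.voxel_spacing_mm
    volumes = []
    for base_level in (120.0, 160.0):  # T2w-like, CET1w-like
        contrast = 12.0 * (0.5 + 1.0 * h)
        field = _textured_field(config.grid_shape, h, rng)
        img = np.full(config.grid_shape, 30.0)
        img += 3.0 * ndimage.gaussian_filter(rng.standard_normal(config.grid_shape), 1.5)
        img[mask] = base_level + contrast * field[mask]
        volumes.append(img)
    t2 = ImageVolume(volumes[0], spacing, "T2w")
    cet1 = ImageVolume(volumes[1], spacing, "CET1w")
    return t2, cet1, ROIMask(mask, spacing)


def simulate_survival(
    linear_predictor: float, config: CohortConfig, rng: np.random.Generator
) -> SurvivalRecord:
    """Event time from hazard h0 * exp(lp), censored by dropout and window.

    Event times are exponential (inverse-transform of a constant baseline
    hazard); dropout is uniform on [0.1, 1] x the censoring window, so the
    observed time is min(event, dropout) and the event flag marks whether
    progression occurred first.
    """
    if not np.isfinite(linear_predictor):
        raise ValueError(f"linear predictor must be finite, got {linear_predictor}")
    lp = float(np.clip(linear_predictor, -30.0, 30.0))
    rate = config.baseline_hazard * np.exp(lp)
    t_event = rng.exponential(1.0 / rate)
    window = config.censor_window_months
    t_censor = rng.uniform(0.1 * window, window) if window > 0 else 0.0
    event = int(t_event <= t_censor)
    time = max(min(t_event, t_censor), 1e-9)
    return SurvivalRecord(time_months=time, event=event)


def _draw_clinical(ranges: ClinicalRanges, rng: np.random.Generator) -> ClinicalRecord:
    age = int(np.clip(round(rng.normal(ranges.age_mean, ranges.age_sd)), *ranges.age_bounds))
    sex = "male" if rng.random() < ranges.p_male else "female"
    stage = "IV" if rng.random() < ranges.p_stage_iv else "III"
    hgb = float(np.clip(rng.normal(ranges.hemoglobin_mean, ranges.hemoglobin_sd), *ranges.hemoglobin_bounds))
    plt = float(np.clip(rng.normal(ranges.platelet_mean, ranges.platelet_sd), *ranges.platelet_bounds))
    return ClinicalRecord(age, sex, stage, round(hgb, 1), round(plt, 1))


@dataclass
class SyntheticCohort:
    """A generated cohort plus its planted-feature table and linear predictors."""

    config: CohortConfig
    patients: list[SyntheticPatient]
    planted_features: pd.DataFrame  # raw (un-normalized) planted feature values
    linear_predictors: pd.Series

    def clinical_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.patients:
            rows.append(
                {
                    "patient_id": p.patient_id,
                    "age": p.clinical.age_years,
                    "sex": p.clinical.sex,
                    "stage": p.clinical.overall_stage,
                    "hemoglobin": p.clinical.hemoglobin_g_per_L,
                    "platelets": p.clinical.platelet_1e9_per_L,
                    "pfs_months": p.survival.time_months,
                    "event": p.survival.event,
                    "split": p.split_label,
                }
            )
        return pd.DataFrame(rows)

    def split(self, label: str) -> list[SyntheticPatient]:
        return [p for p in self.patients if p.split_label == label]

    def write(self, out_dir: str | Path) -> Path:
        """Write NIfTI volume/mask pairs, the clinical CSV and a manifest."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        affine = np.diag([*self.config.voxel_spacing_mm, 1.0])
        entries = []
        for p in self.patients:
            files = {}
            for tag, arr in (
                ("t2", p.volume_t2.values.astype(np.float32)),
                ("cet1", p.volume_cet1.values.astype(np.float32)),
                ("mask", p.mask.values.astype(np.uint8)),
            ):
                fname = f"{p.patient_id}_{tag}.nii.gz"
                nib.save(nib.Nifti1Image(arr, affine), out / fname)
                files[tag] = fname
            entries.append(
                {
                    "patient_id": p.patient_id,
                    "files": files,
                    "latent_heterogeneity": p.latent_heterogeneity,
                    "split": p.split_label,
                }
            )
        self.clinical_frame().to_csv(out / "clinical.csv", index=False)
        manifest = {
            "n_patients": self.config.n_patients,
            "seed": self.config.seed,
            "grid_shape": list(self.config.grid_shape),
            "voxel_spacing_mm": list(self.config.voxel_spacing_mm),
            "clinical_csv": "clinical.csv",
            "patients": entries,
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
        return out


def generate_cohort(config: CohortConfig | None = None) -> SyntheticCohort:
    """Generate the full synthetic cohort.

    Deterministic in ``config`` (every random draw descends from the config
    seed).  Hazard is tied to tumor texture by extracting the planted catalog
    features from the generated images, z-scoring them across the cohort
    (population convention), and forming the linear predictor with the
    configured per-SD effect sizes.  The discovery/validation split is a
    seeded permutation with the discovery count rounded half-up.
    """
    config = config or CohortConfig()
    config.validate()
    n = config.n_patients
    ss = np.random.SeedSequence(config.seed)
    latent_ss, clin_ss, split_ss, surv_ss, *patient_ss = ss.spawn(4 + n)
    latent_rng = np.random.default_rng(latent_ss)
    clin_rng = np.random.default_rng(clin_ss)
    surv_rng = np.random.default_rng(surv_ss)
    hs = latent_rng.uniform(0.0, 1.0, size=n)

    catalog = feat.FeatureCatalog()
    patients: list[SyntheticPatient] = []
    planted_rows = []
    ids = [f"P{i + 1:04d}" for i in range(n)]
    for i in range(n):
        rng_i = np.random.default_rng(patient_ss[i])
        t2, cet1, mask = generate_tumor_pair(config, hs[i], rng_i)
        clinical = _draw_clinical(config.clinical_ranges, clin_rng)
        patients.append(
            SyntheticPatient(
                patient_id=ids[i],
                volume_t2=t2,
                volume_cet1=cet1,
                mask=mask,
                clinical=clinical,
                latent_heterogeneity=float(hs[i]),
            )
        )
        if config.planted_feature_keys:
            planted_rows.append(
                feat.extract_selected(
                    {"T2w": t2, "CET1w": cet1},
                    mask,
                    list(config.planted_feature_keys),
                    catalog,
                    n_bins=config.n_bins,
                )
            )

    if config.planted_feature_keys:
        planted = pd.DataFrame(planted_rows, index=ids)
        std = planted.std(axis=0, ddof=0).replace(0.0, 1.0)
        z = (planted - planted.mean(axis=0)) / std
        lp = pd.Series(
            z.to_numpy() @ np.asarray(config.effect_sizes, dtype=float), index=ids
        )
    else:
        planted = pd.DataFrame(index=ids)
        lp = pd.Series(np.zeros(n), index=ids)

    for i, p in enumerate(patients):
        p.survival = simulate_survival(float(lp.iloc[i]), config, surv_rng)

    n_disc = int(np.floor(n * config.discovery_fraction + 0.5))
    perm = np.random.default_rng(split_ss).permutation(n)
    discovery = set(perm[:n_disc])
    for i, p in enumerate(patients):
        p.split_label = "discovery" if i in discovery else "validation"

    return SyntheticCohort(config, patients, planted, lp)
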