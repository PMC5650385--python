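"""End-to-end orchestration: simulate -> extract -> normalize ->
fit-signature -> score -> validate, with one config and one seed.

The discovery set fixes everything that could leak: normalization statistics,
the selected signature, and the median risk cutoff are estimated on discovery
patients only and applied frozen to the validation set.  The run report
records the stage order so the no-leakage contract is auditable.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd

from . import features as feat
from .cohort import ClinicalRanges, CohortConfig, SyntheticCohort, generate_cohort
from .imaging import DEFAULT_LOG_SIGMAS
from .signature import fit_lasso_cox, radscore_table
from .survival import DEFAULT_SCHEME, CoxResult, fit_cox_multivariate, stratified_km_analysis

__all__ = [
    "PipelineError",
    "PipelineConfig",
    "RunReport",
    "run_pipeline",
    "extract_feature_table",
    "build_cox_covariates",
    "cohort_config_from_dict",
    "pipeline_config_from_dict",
]


class PipelineError(RuntimeError):
    """A stage-named pipeline failure."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass(frozen=True)
class PipelineConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    n_bins: int = 32
    log_sigmas: tuple[float, ...] = DEFAULT_LOG_SIGMAS
    wavelet: str = "coif1"
    cv_folds: int = 10
    lambda_rule: str = "min"
    dichotomize_radscore: bool = False
    stepdown: bool = False

    @property
    def seed(self) -> int:
        return self.cohort.seed


@dataclass
class RunReport:
    config: dict[str, Any]
    catalog_checksum: str
    n_features: int
    stage_order: list[str]
    selected_terms: list[dict[str, float]]
    intercept: float
    cutoff: float
    cox_tables: dict[str, Any]
    stratified: list[dict[str, Any]]
    n_discovery: int
    n_validation: int

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, default=float)

    def summary(self) -> str:
        lines = [
            f"patients: {self.n_discovery} discovery + {self.n_validation} validation",
            f"features extracted: {self.n_features} (catalog {self.catalog_checksum[:12]})",
            f"signature: {len(self.selected_terms)} terms, "
            f"intercept {self.intercept:.3f}, cutoff {self.cutoff:.3f}",
        ]
        for label, table in self.cox_tables.items():
            rad = [r for r in table["rows"] if r["covariate"].startswith("radscore")]
            if rad:
                r = rad[0]
                lines.append(
                    f"{label}: Rad-score HR {r['hr']:.2f} "
                    f"({r['ci_lo']:.2f}-{r['ci_hi']:.2f}), p={r['p']:.3g}"
                )
        return "\n".join(lines)


def extract_feature_table(
    cohort: SyntheticCohort,
    catalog: feat.FeatureCatalog | None = None,
    n_bins: int = 32,
    log_sigmas: tuple[float, ...] = DEFAULT_LOG_SIGMAS,
    wavelet: str = "coif1",
) -> pd.DataFrame:
    """Full 970-column feature table, one row per patient."""
    catalog = catalog or feat.FeatureCatalog()
    rows = {}
    for p in cohort.patients:
        rows[p.patient_id] = feat.extract_all(
            {"T2w": p.volume_t2, "CET1w": p.volume_cet1},
            p.mask,
            catalog,
            n_bins=n_bins,
            log_sigmas=log_sigmas,
            wavelet=wavelet,
        )
    return pd.DataFrame(rows).T.reindex(columns=catalog.keys)


def build_cox_covariates(
    clinical: pd.DataFrame,
    radscore: pd.Series | None = None,
    dichotomize: bool = False,
    cutoff: float | None = None,
) -> pd.DataFrame:
    """Numeric covariate frame for the multivariate Cox models."""
    cov = pd.DataFrame(
        {
            "age": clinical["age"].astype(float),
            "sex_male": (clinical["sex"] == "male").astype(float),
            "stage_iv": (clinical["stage"] == "IV").astype(float),
            "hemoglobin": clinical["hemoglobin"].astype(float),
            "platelets": clinical["platelets"].astype(float),
        },
        index=clinical.index,
    )
    if radscore is not None:
        if dichotomize:
            if cutoff is None:
                raise ValueError("dichotomized Rad-score needs a cutoff")
            cov["radscore"] = (radscore >= cutoff).astype(float)
        else:
            cov["radscore"] = radscore.astype(float)
    return cov


def _cox_to_dict(result: CoxResult) -> dict[str, Any]:
    return {
        "n": result.n,
        "n_events": result.n_events,
        "aic": result.aic,
        "rows": result.table.to_dict(orient="records"),
    }


def run_pipeline(config: PipelineConfig | None = None, out_dir: str | Path | None = None) -> RunReport:
    """Execute every stage on a synthetic cohort and return the run report.

    If ``out_dir`` is given, the feature table, model JSON, Cox tables,
    stratified-KM table and the report itself are written there.
    """
    config = config or PipelineConfig()
    stage_order: list[str] = []

    def stage(name: str):
        stage_order.append(name)
        return name

    try:
        stage("simulate")
        cohort = generate_cohort(config.cohort)
    except ValueError as err:
        raise PipelineError("simulate", str(err)) from err

    catalog = feat.FeatureCatalog()
    try:
        stage("extract")
        table = extract_feature_table(
            cohort, catalog, config.n_bins, config.log_sigmas, config.wavelet
        )
    except ValueError as err:
        raise PipelineError("extract", str(err)) from err

    clinical = cohort.clinical_frame().set_index("patient_id")
    disc_ids = clinical.index[clinical["split"] == "discovery"]
    val_ids = clinical.index[clinical["split"] == "validation"]

    try:
        stage("normalize")
        disc_norm, stats = feat.zscore_normalize(table.loc[disc_ids])
        val_norm, _ = feat.zscore_normalize(table.loc[val_ids], stats)
    except ValueError as err:
        raise PipelineError("normalize", str(err)) from err

    try:
        stage("fit-signature")
        model = fit_lasso_cox(
            disc_norm,
            clinical.loc[disc_ids, "pfs_months"],
            clinical.loc[disc_ids, "event"],
            cv_folds=config.cv_folds,
            lambda_rule=config.lambda_rule,
            seed=config.seed,
            exclude=stats.zero_variance,
        )
    except ValueError as err:
        raise PipelineError("fit-signature", str(err)) from err

    stage("score")
    norm_all = pd.concat([disc_norm, val_norm]).loc[clinical.index]
    scores = radscore_table(norm_all, model) if model.terms else pd.Series(
        model.intercept, index=clinical.index
    )

    try:
        stage("validate")
        cox_tables: dict[str, Any] = {}
        for label, ids in (("discovery", disc_ids), ("validation", val_ids)):
            cov1 = build_cox_covariates(clinical.loc[ids])
            cov2 = build_cox_covariates(
                clinical.loc[ids],
                scores.loc[ids],
                dichotomize=config.dichotomize_radscore,
                cutoff=model.cutoff,
            )
            for mlabel, cov, incl in (("model1", cov1, False), ("model2", cov2, True)):
                res = fit_cox_multivariate(
                    cov,
                    clinical.loc[ids, "pfs_months"],
                    clinical.loc[ids, "event"],
                    include_radscore=incl,
                    stepdown=config.stepdown,
                    model_label=f"{label}_{mlabel}",
                )
                cox_tables[f"{label}_{mlabel}"] = _cox_to_dict(res)
        risk = ["high" if s >= model.cutoff else "low" for s in scores]
        strat = stratified_km_analysis(clinical, risk, DEFAULT_SCHEME)
    except (ValueError, RuntimeError) as err:
        if isinstance(err, PipelineError):
            raise
        raise PipelineError("validate", str(err)) from err

    report = RunReport(
        config=_config_dict(config),
        catalog_checksum=catalog.checksum(),
        n_features=len(catalog),
        stage_order=stage_order,
        selected_terms=[{k: v} for k, v in model.terms],
        intercept=model.intercept,
        cutoff=model.cutoff,
        cox_tables=cox_tables,
        stratified=strat.to_dict(orient="records"),
        n_discovery=len(disc_ids),
        n_validation=len(val_ids),
    )

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.rename_axis("patient_id").to_csv(out / "features.csv")
        model.to_json(out / "model.json")
        clinical.assign(radscore=scores, risk_group=risk).to_csv(out / "clinical_scored.csv")
        strat.to_csv(out / "stratified_km.csv", index=False)
        rows = []
        for label, t in cox_tables.items():
            for r in t["rows"]:
                rows.append({"model": label, **r})
        pd.DataFrame(rows).to_csv(out / "cox_results.csv", index=False)
        (out / "report.json").write_text(report.to_json() + "\n")
        (out / "report.txt").write_text(report.summary() + "\n")
    return report


def _config_dict(config: PipelineConfig) -> dict[str, Any]:
    d = dataclasses.asdict(config)
    return d


def cohort_config_from_dict(data: dict[str, Any]) -> CohortConfig:
    data = dict(data)
    if "clinical_ranges" in data and isinstance(data["clinical_ranges"], dict):
        cr = dict(data["clinical_ranges"])
        for key in ("age_bounds", "hemoglobin_bounds", "platelet_bounds"):
            if key in cr:
                cr[key] = tuple(cr[key])
        data["clinical_ranges"] = ClinicalRanges(**cr)
    for key in ("grid_shape", "voxel_spacing_mm", "effect_sizes", "planted_feature_keys"):
        if key in data:
            data[key] = tuple(data[key])
    known = {f.name for f in dataclasses.fields(CohortConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown cohort config key(s): {sorted(unknown)}")
    return CohortConfig(**data)


def pipeline_config_from_dict(data: dict[str, Any]) -> PipelineConfig:
    data = dict(data)
    if "cohort" in data:
        data["cohort"] = cohort_config_from_dict(data["cohort"])
    if "log_sigmas" in data:
        data["log_sigmas"] = tuple(data["log_sigmas"])
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown pipeline config key(s): {sorted(unknown)}")
    return PipelineConfig(**data)
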