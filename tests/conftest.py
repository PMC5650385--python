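"""Shared fixtures: a default synthetic patient and the reference cohort fit.

The reference fit (n=100 patients, 70/30 split, default generator settings)
is expensive (~2-4 min: full 970-feature extraction plus cross-validated
lasso-Cox), so it is computed once per session and shared by every test that
needs the end-to-end discovery-set model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pytest

from radprog.cohort import CohortConfig, SyntheticCohort, generate_cohort, generate_tumor_pair
from radprog.features import FeatureCatalog, NormalizationStats, zscore_normalize
from radprog.imaging import ImageVolume, ROIMask
from radprog.pipeline import extract_feature_table
from radprog.signature import RadScoreModel, fit_lasso_cox, radscore_table


@pytest.fixture(scope="session")
def catalog() -> FeatureCatalog:
    return FeatureCatalog()


@pytest.fixture(scope="session")
def default_patient() -> tuple[dict[str, ImageVolume], ROIMask]:
    """One synthetic patient at mid heterogeneity under default settings."""
    t2, cet1, mask = generate_tumor_pair(
        CohortConfig(), 0.4, np.random.default_rng(5)
    )
    return {"T2w": t2, "CET1w": cet1}, mask


@dataclass
class ReferenceFit:
    cohort: SyntheticCohort
    table: pd.DataFrame
    clinical: pd.DataFrame
    stats: NormalizationStats
    model: RadScoreModel
    scores_discovery: pd.Series
    scores_validation: pd.Series


@pytest.fixture(scope="session")
def reference_fit() -> ReferenceFit:
    """Reference cohort (default config) carried through the full pipeline."""
    cohort = generate_cohort(CohortConfig())
    table = extract_feature_table(cohort)
    clinical = cohort.clinical_frame().set_index("patient_id")
    disc = clinical.index[clinical["split"] == "discovery"]
    val = clinical.index[clinical["split"] == "validation"]
    disc_norm, stats = zscore_normalize(table.loc[disc])
    val_norm, _ = zscore_normalize(table.loc[val], stats)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = fit_lasso_cox(
            disc_norm,
            clinical.loc[disc, "pfs_months"],
            clinical.loc[disc, "event"],
            seed=0,
            exclude=stats.zero_variance,
        )
    return ReferenceFit(
        cohort=cohort,
        table=table,
        clinical=clinical,
        stats=stats,
        model=model,
        scores_discovery=radscore_table(disc_norm, model),
        scores_validation=radscore_table(val_norm, model),
    )


@pytest.fixture(scope="module")
def small_cohort() -> SyntheticCohort:
    """A 60-patient cohort with a single heterogeneity-increasing planted
    feature, used for association and marginal-realism checks."""
    cfg = CohortConfig(
        n_patients=60,
        planted_feature_keys=("CET1w_6_GLCM_imc1",),
        effect_sizes=(1.5,),
        seed=7,
    )
    return generate_cohort(cfg)
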