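"""Survival validation of the radiomics signature.

Wraps lifelines for the standard estimators — Cox proportional hazards with
Efron tie handling, the Kaplan-Meier product-limit estimator, and the
log-rank test — behind the pipeline's model-comparison and stratified-
analysis interfaces.  Model 1 contains the clinical covariates only; model 2
additionally contains the Rad-score (continuous by default, dichotomized at
the model cutoff by flag).  Stratified analyses use the study's subgroup
thresholds: age <=40 / 40-50 / >50 years, sex, overall stage III/IV,
hemoglobin <=156 / >156 g/L, platelets <=158 / >158 x10^9/L.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import multivariate_logrank_test

__all__ = [
    "SurvivalRecord",
    "CoxResult",
    "KMCurve",
    "StratificationScheme",
    "DEFAULT_SCHEME",
    "fit_cox_multivariate",
    "km_estimate",
    "log_rank_test",
    "stratified_km_analysis",
]


@dataclass(frozen=True)
class SurvivalRecord:
    """Right-censored progression-free survival: time in months, event flag."""

    time_months: float
    event: int

    def __post_init__(self) -> None:
        if not self.time_months > 0:
            raise ValueError(f"time_months must be > 0, got {self.time_months}")
        if self.event not in (0, 1):
            raise ValueError(f"event must be 0 or 1, got {self.event}")


def _records_frame(records: Sequence[SurvivalRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "time": [r.time_months for r in records],
            "event": [r.event for r in records],
        }
    )


@dataclass
class CoxResult:
    """Per-covariate hazard ratios with Wald 95% CIs and p-values."""

    model_label: str
    table: pd.DataFrame  # columns: covariate, hr, ci_lo, ci_hi, p
    aic: float
    n: int
    n_events: int

    def hr(self, covariate: str) -> float:
        row = self.table.set_index("covariate").loc[covariate]
        return float(row["hr"])


@dataclass
class KMCurve:
    """Product-limit survival estimate evaluated at the event times."""

    event_times: np.ndarray
    survival_prob: np.ndarray
    at_risk: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.survival_prob) > 1e-12):
            raise ValueError("survival probabilities must be non-increasing")


def fit_cox_multivariate(
    covariates: pd.DataFrame,
    time: Sequence[float],
    event: Sequence[int],
    include_radscore: bool = True,
    radscore_column: str = "radscore",
    stepdown: bool = False,
    model_label: str | None = None,
) -> CoxResult:
    """Multivariate Cox PH fit (Efron ties) with optional backward AIC
    step-down elimination.

    ``include_radscore=False`` drops the Rad-score column (model 1);
    zero-variance covariates are dropped with a warning.  Non-convergence
    (e.g. separation) raises with the lifelines diagnostic attached.
    """
    df = covariates.copy()
    if not include_radscore and radscore_column in df.columns:
        df = df.drop(columns=[radscore_column])
    if include_radscore and radscore_column not in df.columns:
        raise ValueError(f"covariates lack the {radscore_column!r} column")
    constant = [c for c in df.columns if df[c].nunique() <= 1]
    if constant:
        warnings.warn(f"dropping zero-variance covariate(s): {constant}", stacklevel=2)
        df = df.drop(columns=constant)
    if df.shape[1] == 0:
        raise ValueError("no usable covariates remain")
    df = df.assign(time=np.asarray(time, dtype=float), event=np.asarray(event, dtype=int))
    if df["event"].sum() < 2:
        raise ValueError("need >= 2 events")

    def _fit(frame: pd.DataFrame) -> CoxPHFitter:
        cph = CoxPHFitter()
        try:
            cph.fit(frame, duration_col="time", event_col="event")
        except ConvergenceError as err:
            raise RuntimeError(
                f"Cox model failed to converge (possible separation): {err}"
            ) from err
        return cph

    cph = _fit(df)
    if stepdown:
        keep = [c for c in df.columns if c not in ("time", "event")]
        best_aic = cph.AIC_partial_
        improved = True
        while improved and len(keep) > 1:
            improved = False
            for drop in list(keep):
                trial_cols = [c for c in keep if c != drop]
                trial = _fit(df[trial_cols + ["time", "event"]])
                if trial.AIC_partial_ < best_aic:
                    best_aic = trial.AIC_partial_
                    keep = trial_cols
                    cph = trial
                    improved = True
                    break
    summary = cph.summary
    table = pd.DataFrame(
        {
            "covariate": summary.index,
            "hr": summary["exp(coef)"].to_numpy(),
            "ci_lo": summary["exp(coef) lower 95%"].to_numpy(),
            "ci_hi": summary["exp(coef) upper 95%"].to_numpy(),
            "p": summary["p"].to_numpy(),
        }
    ).reset_index(drop=True)
    label = model_label or ("model2" if include_radscore else "model1")
    return CoxResult(
        model_label=label,
        table=table,
        aic=float(cph.AIC_partial_),
        n=len(df),
        n_events=int(df["event"].sum()),
    )


def km_estimate(records: Sequence[SurvivalRecord]) -> KMCurve:
    """Kaplan-Meier product-limit estimator, reported at the event times."""
    if not records:
        raise ValueError("no survival records")
    df = _records_frame(records)
    kmf = KaplanMeierFitter()
    kmf.fit(df["time"], df["event"])
    event_times = np.sort(df.loc[df["event"] == 1, "time"].unique())
    if event_times.size == 0:
        return KMCurve(np.array([]), np.array([]), np.array([]))
    surv = kmf.survival_function_at_times(event_times).to_numpy()
    at_risk = np.array(
        [int((df["time"] >= t).sum()) for t in event_times], dtype=int
    )
    return KMCurve(event_times, surv, at_risk)


def log_rank_test(groups: Sequence[Sequence[SurvivalRecord]]) -> tuple[float, float]:
    """k-sample log-rank test; returns (chi-square statistic, two-sided p)."""
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need >= 2 non-empty groups")
    time = np.concatenate([[r.time_months for r in g] for g in groups])
    event = np.concatenate([[r.event for r in g] for g in groups])
    label = np.concatenate([[k] * len(g) for k, g in enumerate(groups)])
    res = multivariate_logrank_test(time, label, event)
    return float(res.test_statistic), float(res.p_value)


@dataclass(frozen=True)
class StratificationScheme:
    """Exhaustive, disjoint clinical subgroup bins for stratified KM."""

    age_breaks: tuple[float, float] = (40.0, 50.0)
    hemoglobin_break: float = 156.0
    platelet_break: float = 158.0

    def bins(self) -> dict[str, Callable[[pd.Series], str]]:
        a1, a2 = self.age_breaks

        def age_bin(row: pd.Series) -> str:
            if row["age"] <= a1:
                return f"<={a1:g}"
            if row["age"] <= a2:
                return f"{a1:g}-{a2:g}"
            return f">{a2:g}"

        return {
            "age": age_bin,
            "sex": lambda row: str(row["sex"]),
            "stage": lambda row: str(row["stage"]),
            "hemoglobin": lambda row: (
                f"<={self.hemoglobin_break:g}"
                if row["hemoglobin"] <= self.hemoglobin_break
                else f">{self.hemoglobin_break:g}"
            ),
            "platelets": lambda row: (
                f"<={self.platelet_break:g}"
                if row["platelets"] <= self.platelet_break
                else f">{self.platelet_break:g}"
            ),
        }


DEFAULT_SCHEME = StratificationScheme()


def _records_of(frame: pd.DataFrame) -> list[SurvivalRecord]:
    return [
        SurvivalRecord(t, int(e))
        for t, e in zip(frame["pfs_months"], frame["event"])
    ]


def stratified_km_analysis(
    clinical: pd.DataFrame,
    risk_group: Sequence[str],
    scheme: StratificationScheme = DEFAULT_SCHEME,
) -> pd.DataFrame:
    """Stratified Kaplan-Meier analyses with log-rank tests.

    ``clinical`` needs columns age, sex, stage, hemoglobin, platelets,
    pfs_months, event; ``risk_group`` is the per-patient low/high Rad-score
    label.  Returns a long-format table with one row per (variable, bin):
    patient/event counts, the across-bin log-rank p of the variable, and the
    within-bin low-vs-high Rad-score log-rank p (NaN when a side is empty).
    A final ``radscore`` variable row pair tests the risk split alone.
    """
    df = clinical.copy()
    df["risk_group"] = list(risk_group)
    rows = []
    variables = dict(scheme.bins())
    for var, binner in variables.items():
        labels = df.apply(binner, axis=1)
        groups = [df[labels == lv] for lv in sorted(labels.unique())]
        if len(groups) >= 2 and all(len(g) > 0 for g in groups):
            _, across_p = log_rank_test([_records_of(g) for g in groups])
        else:
            across_p = float("nan")
        for lv in sorted(labels.unique()):
            sub = df[labels == lv]
            lo = sub[sub["risk_group"] == "low"]
            hi = sub[sub["risk_group"] == "high"]
            if len(lo) and len(hi):
                _, within_p = log_rank_test([_records_of(lo), _records_of(hi)])
            else:
                within_p = float("nan")
            rows.append(
                {
                    "variable": var,
                    "bin": lv,
                    "n": len(sub),
                    "n_events": int(sub["event"].sum()),
                    "across_bins_p": across_p,
                    "radscore_split_p": within_p,
                }
            )
    lo = df[df["risk_group"] == "low"]
    hi = df[df["risk_group"] == "high"]
    if len(lo) and len(hi):
        _, split_p = log_rank_test([_records_of(lo), _records_of(hi)])
    else:
        split_p = float("nan")
    for name, sub in (("low", lo), ("high", hi)):
        rows.append(
            {
                "variable": "radscore",
                "bin": name,
                "n": len(sub),
                "n_events": int(sub["event"].sum()),
                "across_bins_p": split_p,
                "radscore_split_p": float("nan"),
            }
        )
    return pd.DataFrame(rows)
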