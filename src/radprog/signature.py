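"""Rad-score signature: lasso-penalized Cox feature selection, the linear
Rad-score, risk dichotomization, and the published NPC model constants.

The Rad-score of a patient is ``intercept + sum_k coef_k * z_k`` over the
selected z-scored texture features; patients with Rad-score at or above the
model cutoff (the median Rad-score of the fitting set) form the high-risk
group.  A Cox model has no native intercept, so fitted models use a centering
constant: the intercept is minus the mean uncentered linear predictor of the
fitting set (plus an optional offset), making the mean Rad-score zero there.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.util import Surv

__all__ = [
    "RadScoreModel",
    "PUBLISHED_MODEL",
    "fit_lasso_cox",
    "compute_radscore",
    "assign_risk_group",
    "coefficient_magnitude_report",
]


@dataclass
class RadScoreModel:
    """A sparse linear prognostic signature on z-scored radiomics features."""

    terms: tuple[tuple[str, float], ...]
    intercept: float
    cutoff: float
    alpha: float | None = None

    def __post_init__(self) -> None:
        keys = [k for k, _ in self.terms]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate term keys in Rad-score model")
        if not np.isfinite(self.cutoff):
            raise ValueError("cutoff must be finite")

    @property
    def term_keys(self) -> list[str]:
        return [k for k, _ in self.terms]

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "terms": [{"key": k, "coefficient": c} for k, c in self.terms],
            "intercept": self.intercept,
            "cutoff": self.cutoff,
            "alpha": self.alpha,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "RadScoreModel":
        p = Path(source)
        payload = json.loads(p.read_text() if p.exists() else str(source))
        return cls(
            terms=tuple((t["key"], float(t["coefficient"])) for t in payload["terms"]),
            intercept=float(payload["intercept"]),
            cutoff=float(payload["cutoff"]),
            alpha=payload.get("alpha"),
        )


#: The published five-feature NPC signature: coefficients, centering constant
#: and median risk cutoff exactly as printed.
PUBLISHED_MODEL = RadScoreModel(
    terms=(
        ("T2w_3_GLCM_homogeneity1", 2.495),
        ("CET1w_6_GLCM_imc1", 1.474),
        ("CET1w_5_GLCM_correlation", -1.203),
        ("T2w_1_GLCM_inverse_variance", -0.809),
        ("T2w_1_GLRLM_srlgle", -3.839),
    ),
    intercept=-7.995,
    cutoff=-6.863,
)


def _cox_partial_loglik(lp: np.ndarray, time: np.ndarray, event: np.ndarray) -> float:
    """Breslow log partial likelihood of a fixed linear predictor."""
    order = np.argsort(-time, kind="stable")  # decreasing time
    lp_o = lp[order]
    t_o = time[order]
    e_o = event[order]
    elp = np.exp(lp_o - lp_o.max())
    cum = np.cumsum(elp)
    # risk set of subject i (ascending to its time) = cumulative sum up to the
    # last index sharing its time
    ll = 0.0
    n = len(t_o)
    idx = 0
    last_same = np.empty(n, dtype=int)
    i = 0
    while i < n:
        j = i
        while j + 1 < n and t_o[j + 1] == t_o[i]:
            j += 1
        last_same[i : j + 1] = j
        i = j + 1
    for i in range(n):
        if e_o[i]:
            ll += (lp_o[i] - lp_o.max()) - np.log(cum[last_same[i]])
    return float(ll)


def fit_lasso_cox(
    table: pd.DataFrame,
    time: Sequence[float],
    event: Sequence[int],
    cv_folds: int = 10,
    lambda_rule: str = "min",
    seed: int = 0,
    alpha: float | None = None,
    offset: float = 0.0,
    n_alphas: int = 60,
    exclude: Sequence[str] = (),
) -> RadScoreModel:
    """Fit an L1-penalized Cox model and return the sparse Rad-score signature.

    The penalty weight is chosen by ``cv_folds``-fold cross-validated held-out
    log partial likelihood over the coordinate-descent regularization path
    (``lambda_rule='min'`` maximizes the CV likelihood; ``'1se'`` takes the
    strongest penalty within one standard error of it).  Pass ``alpha`` to fix
    the penalty instead.  ``exclude`` names zero-variance features flagged by
    normalization; they are withheld from selection.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if event.sum() < 2:
        raise ValueError(f"need >= 2 events to fit a Cox model, got {int(event.sum())}")
    if lambda_rule not in ("min", "1se"):
        raise ValueError(f"lambda_rule must be 'min' or '1se', got {lambda_rule!r}")
    cols = [c for c in table.columns if c not in set(exclude)]
    X = table[cols].to_numpy(dtype=float)
    y = Surv.from_arrays(event=event.astype(bool), time=time)

    if alpha is None:
        path = CoxnetSurvivalAnalysis(
            l1_ratio=1.0, n_alphas=n_alphas, alpha_min_ratio=0.01, max_iter=200000
        )
        path.fit(X, y)
        alphas = np.asarray(path.alphas_)
        n = len(table)
        folds = cv_folds
        if n < folds:
            warnings.warn(
                f"only {n} rows; reducing CV folds from {cv_folds} to {n}",
                stacklevel=2,
            )
            folds = n
        rng = np.random.default_rng(seed)
        assignment = np.tile(np.arange(folds), n // folds + 1)[:n]
        rng.shuffle(assignment)
        cv_ll = np.zeros((folds, len(alphas)))
        for f in range(folds):
            train = assignment != f
            model = CoxnetSurvivalAnalysis(
                l1_ratio=1.0, alphas=alphas, max_iter=200000, fit_baseline_model=False
            )
            model.fit(X[train], y[train])
            fitted = np.asarray(model.alphas_)
            coefs = np.asarray(model.coef_)  # (p, n_fitted)
            for a_idx, a in enumerate(alphas):
                j = int(np.argmin(np.abs(fitted - a)))
                beta = coefs[:, j]
                lp_all = X @ beta
                # held-out contribution: full-data likelihood minus train-only
                ll_all = _cox_partial_loglik(lp_all, time, event)
                ll_train = _cox_partial_loglik(
                    lp_all[train], time[train], event[train]
                )
                cv_ll[f, a_idx] = ll_all - ll_train
        mean_ll = cv_ll.mean(axis=0)
        se_ll = cv_ll.std(axis=0, ddof=1) / np.sqrt(folds)
        best = int(np.argmax(mean_ll))
        if lambda_rule == "1se":
            ok = mean_ll >= mean_ll[best] - se_ll[best]
            best = int(np.flatnonzero(ok)[0])  # alphas_ descend: first ok = strongest
        alpha = float(alphas[best])

    final = CoxnetSurvivalAnalysis(
        l1_ratio=1.0, alphas=[alpha], max_iter=200000, fit_baseline_model=False
    )
    final.fit(X, y)
    beta = np.asarray(final.coef_)[:, 0]
    nz = np.flatnonzero(beta != 0.0)
    terms = tuple((cols[j], float(beta[j])) for j in nz)
    lp = X[:, nz] @ beta[nz] if nz.size else np.zeros(len(table))
    intercept = float(-lp.mean() + offset)
    scores = lp + intercept
    cutoff = float(np.median(scores))
    return RadScoreModel(terms=terms, intercept=intercept, cutoff=cutoff, alpha=alpha)


def compute_radscore(features: Mapping[str, float] | pd.Series, model: RadScoreModel) -> float:
    """Rad-score = intercept + sum of coefficient x (z-scored) feature value."""
    score = model.intercept
    for key, coef in model.terms:
        if key not in features:
            raise KeyError(f"feature vector is missing signature term {key!r}")
        score += coef * float(features[key])
    return float(score)


def radscore_table(table: pd.DataFrame, model: RadScoreModel) -> pd.Series:
    """Vectorized Rad-scores for a normalized feature table."""
    missing = [k for k in model.term_keys if k not in table.columns]
    if missing:
        raise KeyError(f"feature table is missing signature term(s) {missing}")
    scores = pd.Series(model.intercept, index=table.index, dtype=float)
    for key, coef in model.terms:
        scores += coef * table[key]
    return scores


def assign_risk_group(score: float, model: RadScoreModel) -> str:
    """'high' iff the Rad-score is at or above the model cutoff, else 'low'."""
    if not np.isfinite(score):
        raise ValueError(f"Rad-score must be finite, got {score}")
    return "high" if score >= model.cutoff else "low"


def coefficient_magnitude_report(model: RadScoreModel) -> list[tuple[str, float]]:
    """Terms ordered by decreasing absolute coefficient."""
    if not model.terms:
        raise ValueError("model has no terms")
    return sorted(
        ((k, abs(c)) for k, c in model.terms), key=lambda kv: (-kv[1], kv[0])
    )
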