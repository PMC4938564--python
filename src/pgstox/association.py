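"""Toxicity association models: dichotomisation, logistic fits, survival.

Grades are dichotomised at the clinical thresholds (neutropenia grade >=3,
neuropathy grade >=2).  Score and per-variant models are maximum-likelihood
logistic regressions with Wald 95% confidence intervals and two-sided Wald
p-values; adjustment sets follow the phenotype: neutropenia models adjust
for trial and age, neuropathy models for trial, BMI and the first two
ancestry principal components.  The survival linkage is a proportional-
hazards fit of relapse-free survival on the risk-allele count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .scores import ScoreTable
from .simulate import CASE_THRESHOLDS, GRADE_RANGES

__all__ = [
    "AssociationResult",
    "SurvivalResult",
    "FitFailure",
    "dichotomize",
    "fit_score_model",
    "per_variant_scan",
    "fit_survival",
    "ADJUSTMENT_SETS",
]

# phenotype -> covariate columns entering the adjusted model
ADJUSTMENT_SETS = {
    "neutropenia": ["trial", "age"],
    "neuropathy": ["trial", "bmi", "pc1", "pc2"],
}

_Z975 = 1.959963984540054


class FitFailure(RuntimeError):
    """Model fit failed (separation, non-convergence, degenerate predictor)."""


@dataclass(frozen=True)
class AssociationResult:
    term: str
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    adjusted: bool
    scale: str  # "per-allele" or "per-SD"
    n_used: int

    def __post_init__(self) -> None:
        if not self.ci_low <= self.odds_ratio <= self.ci_high:
            raise ValueError("CI must bracket the odds ratio")


@dataclass(frozen=True)
class SurvivalResult:
    hazard_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    per_k_alleles: int
    n_used: int
    n_events: int

    def rescaled(self, k: int) -> "SurvivalResult":
        """Per-k-allele hazard ratio: HR_k = HR^k (CI bounds likewise)."""
        return SurvivalResult(
            hazard_ratio=self.hazard_ratio**k,
            ci_low=self.ci_low**k,
            ci_high=self.ci_high**k,
            p_value=self.p_value,
            per_k_alleles=k,
            n_used=self.n_used,
            n_events=self.n_events,
        )


def dichotomize(grades, phenotype: str) -> pd.Series:
    """Map toxicity grades to case (1) / control (0) indicators.

    Cases are grade >= 3 for neutropenia and grade >= 2 for neuropathy;
    missing grades propagate as missing.  Out-of-range grades raise.
    """
    if phenotype not in CASE_THRESHOLDS:
        raise ValueError(f"unknown phenotype {phenotype!r}")
    g = pd.Series(grades, dtype="Float64")
    lo, hi = GRADE_RANGES[phenotype]
    observed = g.dropna()
    if ((observed < lo) | (observed > hi)).any():
        bad = observed[(observed < lo) | (observed > hi)].iloc[0]
        raise ValueError(
            f"{phenotype} grade {bad} outside [{lo}, {hi}]"
        )
    case = (g >= CASE_THRESHOLDS[phenotype]).astype("Int64")
    case[g.isna()] = pd.NA
    return case


def _design(
    predictor: pd.Series,
    cohort: pd.DataFrame,
    phenotype: str,
    adjusted: bool,
) -> pd.DataFrame:
    X = pd.DataFrame({"const": 1.0, "predictor": predictor.astype(float)})
    if adjusted:
        for col in ADJUSTMENT_SETS[phenotype]:
            if col not in cohort.columns:
                raise ValueError(f"adjusted model needs covariate {col!r}")
            if col == "trial":
                # largest trial as reference level
                ref = cohort["trial"].value_counts().idxmax()
                dummies = pd.get_dummies(cohort["trial"], prefix="trial")
                dummies = dummies.drop(columns=[f"trial_{ref}"]).astype(float)
                X = pd.concat([X, dummies], axis=1)
            else:
                X[col] = cohort[col].astype(float)
    return X


def _logistic_fit(
    y: pd.Series, X: pd.DataFrame
) -> tuple[float, float, float, int]:
    """Complete-case MLE logistic fit; returns (beta, se, p, n_used) for
    the 'predictor' column."""
    keep = y.notna() & X.notna().all(axis=1)
    y_ = y[keep].astype(float)
    X_ = X.loc[keep]
    n_cases = int(y_.sum())
    n_controls = int(len(y_) - n_cases)
    if n_cases < 10 or n_controls < 10:
        raise FitFailure(
            f"need >=10 cases and >=10 controls, got {n_cases}/{n_controls}"
        )
    if X_["predictor"].nunique() < 2:
        raise FitFailure("degenerate predictor (constant)")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y_, X_).fit(disp=0, maxiter=100)
    except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
        raise FitFailure(f"logistic fit failed: {exc}") from exc
    if not res.mle_retvals.get("converged", False):
        raise FitFailure("logistic fit did not converge")
    beta = float(res.params["predictor"])
    se = float(res.bse["predictor"])
    if not np.isfinite(beta) or not np.isfinite(se) or se > 1e3:
        raise FitFailure("unstable fit (non-finite or exploding SE)")
    p = float(res.pvalues["predictor"])
    return beta, se, p, int(len(y_))


def fit_score_model(
    cohort: pd.DataFrame,
    scores: ScoreTable,
    phenotype: str,
    score_kind: str = "unweighted",
    adjusted: bool = False,
) -> AssociationResult:
    """Logistic regression of toxicity case status on a polygenic score.

    ``score_kind="unweighted"`` uses the risk-allele count (per-allele OR);
    ``"weighted"`` uses the standardised weighted score (per-SD OR).  The
    cohort table must carry ``<phenotype>_case`` (or a grade column, which
    is dichotomised on the fly) plus adjustment covariates when requested.
    """
    case_col = f"{phenotype}_case"
    if case_col in cohort.columns:
        y = pd.Series(cohort[case_col]).astype("Float64")
    elif f"{phenotype}_grade" in cohort.columns:
        y = dichotomize(cohort[f"{phenotype}_grade"], phenotype).astype("Float64")
    else:
        raise ValueError(f"cohort lacks {case_col} and {phenotype}_grade")
    y.index = range(len(y))
    if score_kind == "unweighted":
        predictor = pd.Series(scores.unweighted)
        scale = "per-allele"
    elif score_kind == "weighted":
        predictor = pd.Series(scores.weighted_std)
        scale = "per-SD"
    else:
        raise ValueError("score_kind must be 'unweighted' or 'weighted'")
    cohort = cohort.reset_index(drop=True)
    X = _design(predictor, cohort, phenotype, adjusted)
    beta, se, p, n_used = _logistic_fit(y, X)
    return AssociationResult(
        term=f"{score_kind}_score",
        odds_ratio=float(np.exp(beta)),
        ci_low=float(np.exp(beta - _Z975 * se)),
        ci_high=float(np.exp(beta + _Z975 * se)),
        p_value=p,
        adjusted=adjusted,
        scale=scale,
        n_used=n_used,
    )


def per_variant_scan(
    matrix,
    cohort: pd.DataFrame,
    phenotype: str,
    adjusted: bool = False,
    alpha: float = 5e-4,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """One logistic fit per variant (dosage as predictor), ordered by p.

    ``alpha`` defaults to 5e-4 (~0.05 over 94 variants); a variant is
    flagged significant iff p < alpha.  Per-variant fit failures are
    recorded in the returned dict and excluded from the table.  Returns
    ``(results, failures)`` with results sorted by ascending p-value for
    downstream gene ranking.
    """
    case_col = f"{phenotype}_case"
    if case_col in cohort.columns:
        y = pd.Series(cohort[case_col]).astype("Float64")
    else:
        y = dichotomize(cohort[f"{phenotype}_grade"], phenotype).astype("Float64")
    y.index = range(len(y))
    cohort = cohort.reset_index(drop=True)
    rows = []
    failures: dict[str, str] = {}
    for j, rsid in enumerate(matrix.variant_ids):
        predictor = pd.Series(matrix.dosages[:, j])
        X = _design(predictor, cohort, phenotype, adjusted)
        try:
            beta, se, p, n_used = _logistic_fit(y, X)
        except FitFailure as exc:
            failures[rsid] = str(exc)
            continue
        rows.append(
            {
                "rsid": rsid,
                "odds_ratio": float(np.exp(beta)),
                "ci_low": float(np.exp(beta - _Z975 * se)),
                "ci_high": float(np.exp(beta + _Z975 * se)),
                "p_value": p,
                "significant": p < alpha,
                "n_used": n_used,
            }
        )
    results = pd.DataFrame(rows)
    if not results.empty:
        results = results.sort_values(
            ["p_value", "rsid"], kind="mergesort"
        ).reset_index(drop=True)
    return results, failures


def fit_survival(
    cohort: pd.DataFrame,
    scores: ScoreTable,
    adjust_for_neutropenia: bool = False,
    per_k_alleles: int = 1,
) -> SurvivalResult:
    """Cox proportional-hazards fit of relapse-free survival on the
    risk-allele count (per-allele HR), optionally adjusted for neutropenia
    case status.  ``rescaled(k)`` on the result gives the per-k-allele HR.
    """
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError

    df = pd.DataFrame(
        {
            "time": cohort["rfs_time"].to_numpy(dtype=float),
            "event": cohort["rfs_event"].to_numpy(dtype=int),
            "score": scores.unweighted,
        }
    )
    if adjust_for_neutropenia:
        if "neutropenia_case" in cohort.columns:
            df["neutropenia_case"] = cohort["neutropenia_case"].to_numpy(dtype=float)
        else:
            df["neutropenia_case"] = (
                dichotomize(cohort["neutropenia_grade"], "neutropenia")
                .astype("Float64")
                .to_numpy(dtype=float)
            )
    df = df.dropna()
    n_events = int(df["event"].sum())
    if n_events < 10:
        raise FitFailure(f"need >=10 events, got {n_events}")
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="time", event_col="event")
    except ConvergenceError as exc:
        raise FitFailure(f"Cox fit failed: {exc}") from exc
    beta = float(cph.params_["score"])
    se = float(cph.standard_errors_["score"])
    result = SurvivalResult(
        hazard_ratio=float(np.exp(beta)),
        ci_low=float(np.exp(beta - _Z975 * se)),
        ci_high=float(np.exp(beta + _Z975 * se)),
        p_value=float(cph.summary.loc["score", "p"]),
        per_k_alleles=1,
        n_used=int(len(df)),
        n_events=n_events,
    )
    return result.rescaled(per_k_alleles) if per_k_alleles != 1 else result
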