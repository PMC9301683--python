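"""Recurrent-event models of outpatient visit burden.

Time to the next outpatient visit is modelled on the gap-time scale: the
clock resets at every visit, so a patient with visits at dates
``d1 < ... < dk`` contributes k at-risk intervals — k-1 observed gaps
(event = 1) and a final censored interval running from the last visit to the
study end.  The number of previous visits is the only interval-varying
covariate; phenotype flags, age at first visit, sex, and the upper-airway
disease count are constant within patient.

Two fitters operate on these interval records:

* :func:`fit_cox` — Cox proportional hazards by partial-likelihood
  maximization with Efron tie handling (gap days are integers, ties are
  certain) and Wald 95% confidence intervals;
* :func:`fit_lasso_cox` — an L1-penalized Cox path over a descending
  lambda grid with K-fold cross-validated partial-likelihood deviance,
  folds assigned at the *patient* level so a patient's intervals never
  straddle the train/test split, and the 1-SE rule: the selected lambda is
  the largest whose mean CV deviance is within one standard error of the
  minimum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from datetime import date
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from rhinoreg.errors import ValidationError

__all__ = [
    "IntervalRecord",
    "CoxFitResult",
    "LassoFitResult",
    "build_interval_records",
    "intervals_frame",
    "fit_cox",
    "fit_lasso_cox",
    "forest_table",
]

#: default covariate set for the visit-burden models
DEFAULT_COVARIATES = [
    "prior_visit_count", "age", "sex_female", "upper_airway_count",
    "AR", "NAR", "CRS_any", "CRSsNP", "CRSwNP", "ARS", "RARS", "CRS_AE",
    "CRSwNP_AE", "NERD", "asthma", "allergy", "immunodeficiency_or_suspicion",
    "diabetes", "chronic_respiratory_other", "obesity", "mental", "memory",
    "cardiovascular", "cancer", "musculoskeletal", "obstructive_sleep_apnea",
    "mouth_breathing", "gastroesophageal_reflux", "chronic_otitis_media",
    "tonsil_disease",
]


@dataclass(frozen=True)
class IntervalRecord:
    """One gap-time at-risk interval (previous visit to next visit/censoring)."""

    patient_id: str
    interval_index: int  # 1-based
    gap_days: float
    event: int  # 1 = next visit observed, 0 = censored at study end
    prior_visit_count: int
    covariates: dict = field(default_factory=dict, hash=False)


def build_interval_records(
    visit_dates: Sequence[date],
    covariates: Mapping[str, float],
    patient_id: str,
    study_end: date,
) -> list[IntervalRecord]:
    """Gap-time records for one patient.

    For visits at ``d1 < ... < dk``: records i = 1..k-1 with
    gap = d(i+1) - d(i) and event = 1, prior_visit_count = i; one final
    censored record with gap = study_end - dk and prior_visit_count = k.
    Zero-length censored tails are clamped to half a day so every visit
    yields a record.
    """
    dates = list(visit_dates)
    if not dates:
        return []
    if dates != sorted(dates):
        raise ValidationError("visit_dates must be sorted ascending")
    if len(set(dates)) != len(dates):
        raise ValidationError("visit_dates must be deduplicated (one per day)")
    if dates[-1] > study_end:
        raise ValidationError("study_end precedes the last visit")
    records = []
    k = len(dates)
    for i in range(1, k):
        records.append(
            IntervalRecord(
                patient_id=patient_id,
                interval_index=i,
                gap_days=float((dates[i] - dates[i - 1]).days),
                event=1,
                prior_visit_count=i,
                covariates=dict(covariates),
            )
        )
    tail = float((study_end - dates[-1]).days)
    records.append(
        IntervalRecord(
            patient_id=patient_id,
            interval_index=k,
            gap_days=max(tail, 0.5),
            event=0,
            prior_visit_count=k,
            covariates=dict(covariates),
        )
    )
    return records


def intervals_frame(
    profiles: pd.DataFrame,
    visits: pd.DataFrame,
    patients: pd.DataFrame,
    study_end: date,
) -> pd.DataFrame:
    """Counting-process layout for the whole cohort.

    Returns one row per interval with columns patient_id, interval_index,
    gap_days, event, prior_visit_count, and the model covariates (phenotype
    flags as 0/1, age at first visit in years, sex_female, and
    upper_airway_count = number of distinct rhinitis/rhinosinusitis
    entities).
    """
    vis = visits.copy()
    vis["date"] = pd.to_datetime(vis["date"])
    pat = patients.set_index("patient_id")
    rows = []
    for pid, grp in vis.groupby("patient_id"):
        if pid not in profiles.index:
            continue
        prof = profiles.loc[pid]
        dates = sorted(grp["date"].dt.date.unique())
        birth = pd.Timestamp(pat.loc[pid, "birth_date"])
        age = (pd.Timestamp(dates[0]) - birth).days / 365.25
        cov = {
            "age": age,
            "sex_female": 1.0 if pat.loc[pid, "sex"] == "female" else 0.0,
            "upper_airway_count": float(prof.get("rhinitis_entity_count", 0)),
        }
        for name in DEFAULT_COVARIATES:
            if name in prof.index:
                cov[name] = float(bool(prof[name]))
        for rec in build_interval_records(dates, cov, pid, study_end):
            row = {
                "patient_id": rec.patient_id,
                "interval_index": rec.interval_index,
                "gap_days": rec.gap_days,
                "event": rec.event,
                "prior_visit_count": rec.prior_visit_count,
            }
            row.update(rec.covariates)
            rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class CoxFitResult:
    """Per-covariate estimates and fit diagnostics from the gap-time Cox model."""

    coefficients: pd.Series
    hazard_ratios: pd.Series
    standard_errors: pd.Series
    ci_lower: pd.Series
    ci_upper: pd.Series
    concordance: float
    n_records: int
    n_events: int
    dropped: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)


def fit_cox(
    records: pd.DataFrame,
    covariate_names: Sequence[str],
) -> CoxFitResult:
    """Fit the gap-time Cox model (Efron ties, Wald 95% CIs).

    ``records`` is an interval frame from :func:`intervals_frame` (or any
    frame with gap_days/event plus the covariates).  Covariates constant
    across all records are dropped with a warning.
    """
    from lifelines import CoxPHFitter

    if int(records["event"].sum()) < 2:
        raise ValidationError("need at least 2 events to fit the Cox model")
    msgs: list[str] = []
    kept, dropped = [], []
    for name in covariate_names:
        if records[name].nunique() <= 1:
            dropped.append(name)
            msgs.append(f"covariate {name!r} is constant; dropped")
        else:
            kept.append(name)
    df = records[["gap_days", "event", *kept]].astype(float)

    cph = CoxPHFitter()
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        cph.fit(df, duration_col="gap_days", event_col="event")
        for w in caught:
            text = str(w.message)
            if "convergence" in text.lower() or "collinear" in text.lower():
                msgs.append(text)

    summ = cph.summary
    return CoxFitResult(
        coefficients=summ["coef"].copy(),
        hazard_ratios=summ["exp(coef)"].copy(),
        standard_errors=summ["se(coef)"].copy(),
        ci_lower=summ["exp(coef) lower 95%"].copy(),
        ci_upper=summ["exp(coef) upper 95%"].copy(),
        concordance=float(cph.concordance_index_),
        n_records=len(df),
        n_events=int(df["event"].sum()),
        dropped=dropped,
        warnings=msgs,
    )


# ---------------------------------------------------------------------------
# L1-penalized Cox with patient-level CV and the 1-SE rule


def _cox_deviance(X: np.ndarray, time: np.ndarray, event: np.ndarray,
                  beta: np.ndarray) -> float:
    """-2 x Breslow partial log-likelihood at ``beta`` (deviance up to a constant)."""
    eta = X @ beta
    order = np.argsort(-time, kind="stable")  # decreasing time
    eta_o, t_o, e_o = eta[order], time[order], event[order]
    log_csum = np.logaddexp.accumulate(eta_o)
    # risk set of interval i = all records with time >= t_i; with decreasing
    # sort and ties grouped, the denominator is log_csum at the last index
    # sharing each time value
    n = len(t_o)
    if n == 0:
        return 0.0
    group = np.cumsum(np.r_[0, t_o[1:] != t_o[:-1]])
    last_of_group = np.searchsorted(group, group, side="right") - 1
    ll = float(np.sum((eta_o - log_csum[last_of_group])[e_o == 1]))
    return -2.0 * ll


@dataclass
class LassoFitResult:
    """Cross-validated L1 Cox path and the 1-SE selection."""

    alphas: np.ndarray  # descending lambda grid
    cv_mean_deviance: np.ndarray
    cv_se_deviance: np.ndarray
    alpha_min: float
    alpha_1se: float
    coefficients: pd.Series  # at alpha_1se
    selected: list[str]
    coef_path: pd.DataFrame  # covariates x alphas


def fit_lasso_cox(
    records: pd.DataFrame,
    covariate_names: Sequence[str],
    n_folds: int = 5,
    seed: int = 0,
    n_alphas: int = 100,
    alpha_min_ratio: float = 1e-3,
    max_fold_retries: int = 10,
    alphas: Sequence[float] | None = None,
    tol: float = 1e-7,
) -> LassoFitResult:
    """L1-penalized gap-time Cox with patient-level K-fold CV and 1-SE rule.

    The coefficient path is fitted by coordinate descent (elastic-net Cox,
    pure L1) over ``n_alphas`` log-spaced penalties from the null-model
    lambda down to ``alpha_min_ratio`` times it.  Fold membership is drawn
    per patient; folds without events are redrawn up to
    ``max_fold_retries`` times.  Covariates are standardized internally;
    returned coefficients are on the original scale.
    """
    from sksurv.linear_model import CoxnetSurvivalAnalysis
    from sksurv.util import Surv

    if n_folds < 3:
        raise ValidationError("n_folds must be >= 3")
    X = records[list(covariate_names)].to_numpy(dtype=float)
    time = records["gap_days"].to_numpy(dtype=float)
    event = records["event"].to_numpy(dtype=int)
    y = Surv.from_arrays(event=event.astype(bool), time=time)

    if alphas is not None:
        path = CoxnetSurvivalAnalysis(
            l1_ratio=1.0, alphas=list(alphas), fit_baseline_model=False,
            normalize=True, tol=tol, max_iter=1_000_000,
        )
    else:
        path = CoxnetSurvivalAnalysis(
            l1_ratio=1.0, n_alphas=n_alphas, alpha_min_ratio=alpha_min_ratio,
            fit_baseline_model=False, normalize=True, tol=tol,
        )
    path.fit(X, y)
    alphas = np.asarray(path.alphas_)
    coef_path = np.asarray(path.coef_)  # (n_features, n_alphas)

    patient_ids = records["patient_id"].to_numpy()
    unique_patients = np.unique(patient_ids)
    rng = np.random.default_rng(seed)
    for attempt in range(max_fold_retries):
        assignment = rng.integers(n_folds, size=len(unique_patients))
        fold_of = dict(zip(unique_patients, assignment))
        folds = np.array([fold_of[p] for p in patient_ids])
        if all(event[folds == f].sum() > 0 for f in range(n_folds)):
            break
    else:
        raise ValidationError("could not draw folds with events in every fold")

    # Verweij-van Houwelingen cross-validated deviance: the fold's
    # contribution is the full-data deviance minus the training-fold
    # deviance at the training-fold coefficients, normalized per test-fold
    # event so folds are comparable.
    deviances = np.empty((n_folds, len(alphas)))
    for f in range(n_folds):
        train = folds != f
        n_test_events = float(event[~train].sum())
        fold_fit = CoxnetSurvivalAnalysis(
            l1_ratio=1.0, alphas=alphas, fit_baseline_model=False, normalize=True,
            tol=tol,
        )
        fold_fit.fit(X[train], y[train])
        fold_coefs = np.asarray(fold_fit.coef_)
        n_fit = fold_coefs.shape[1]
        for a in range(len(alphas)):
            beta = fold_coefs[:, min(a, n_fit - 1)]
            dev_full = _cox_deviance(X, time, event, beta)
            dev_train = _cox_deviance(X[train], time[train], event[train], beta)
            deviances[f, a] = (dev_full - dev_train) / n_test_events

    cv_mean = deviances.mean(axis=0)
    cv_se = deviances.std(axis=0, ddof=1) / np.sqrt(n_folds)
    i_min = int(np.argmin(cv_mean))
    threshold = cv_mean[i_min] + cv_se[i_min]
    # alphas are descending: the largest alpha within 1 SE is the first index
    i_1se = int(np.flatnonzero(cv_mean <= threshold)[0])
    coef_1se = pd.Series(coef_path[:, i_1se], index=list(covariate_names))
    return LassoFitResult(
        alphas=alphas,
        cv_mean_deviance=cv_mean,
        cv_se_deviance=cv_se,
        alpha_min=float(alphas[i_min]),
        alpha_1se=float(alphas[i_1se]),
        coefficients=coef_1se,
        selected=[c for c in covariate_names if abs(coef_1se[c]) > 1e-10],
        coef_path=pd.DataFrame(coef_path, index=list(covariate_names), columns=alphas),
    )


def forest_table(fit: CoxFitResult) -> pd.DataFrame:
    """Forest-plot table: covariate, HR, 95% CI, and association direction."""
    direction = []
    for name in fit.hazard_ratios.index:
        lo, hi = fit.ci_lower[name], fit.ci_upper[name]
        if lo > 1.0:
            direction.append("positive")
        elif hi < 1.0:
            direction.append("negative")
        else:
            direction.append("null-crossing")
    return pd.DataFrame(
        {
            "covariate": fit.hazard_ratios.index,
            "hr": fit.hazard_ratios.values,
            "ci_lower": fit.ci_lower.values,
            "ci_upper": fit.ci_upper.values,
            "direction": direction,
        }
    ).set_index("covariate")
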