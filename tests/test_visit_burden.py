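"""Interval construction, Cox fitting, and the penalized path."""

from datetime import date, timedelta

import numpy as np
import pandas as pd
import pytest

from rhinoreg.errors import ValidationError
from rhinoreg.visit_burden import (
    build_interval_records,
    fit_cox,
    fit_lasso_cox,
    forest_table,
    intervals_frame,
)

END = date(2010, 12, 31)
D0 = date(2010, 1, 1)


# ---------------------------------------------------------------------------
# interval construction


def test_two_visits_interval_layout():
    recs = build_interval_records(
        [D0, D0 + timedelta(days=100)], {"x": 1.0}, "p", D0 + timedelta(days=365)
    )
    assert [(r.gap_days, r.event, r.prior_visit_count) for r in recs] == [
        (100.0, 1, 1), (265.0, 0, 2),
    ]


def test_single_visit_one_censored_record():
    recs = build_interval_records([D0], {}, "p", D0 + timedelta(days=365))
    assert len(recs) == 1
    assert recs[0].event == 0 and recs[0].gap_days == 365.0 and recs[0].prior_visit_count == 1


def test_k_visits_k_records_one_censored():
    rng = np.random.default_rng(5)
    for _ in range(30):
        k = int(rng.integers(1, 10))
        days = np.cumsum(rng.integers(1, 90, size=k))
        dates = [D0 + timedelta(days=int(d)) for d in days]
        recs = build_interval_records(dates, {}, "p", dates[-1] + timedelta(days=50))
        assert len(recs) == k
        assert sum(r.event == 0 for r in recs) == 1
        assert recs[-1].event == 0


def test_empty_and_invalid_inputs():
    assert build_interval_records([], {}, "p", END) == []
    with pytest.raises(ValidationError):
        build_interval_records([D0 + timedelta(days=1), D0], {}, "p", END)
    with pytest.raises(ValidationError):
        build_interval_records([D0, D0], {}, "p", END)


def test_intervals_frame_structure():
    profiles = pd.DataFrame(
        {"patient_id": ["a", "b"], "AR": [True, False],
         "rhinitis_entity_count": [1, 1]}
    ).set_index("patient_id")
    visits = pd.DataFrame(
        {"patient_id": ["a", "a", "a", "b"],
         "date": ["2010-01-01", "2010-02-01", "2010-03-01", "2010-06-01"]}
    )
    patients = pd.DataFrame(
        {"patient_id": ["a", "b"], "sex": ["female", "male"],
         "birth_date": ["1980-01-01", "1990-01-01"]}
    )
    iv = intervals_frame(profiles, visits, patients, END)
    assert len(iv) == 4  # records per patient = visits per patient
    assert iv.groupby("patient_id")["event"].apply(lambda e: (e == 0).sum()).eq(1).all()
    assert iv["event"].sum() == 4 - 2  # total events = visits - patients
    assert set(iv.columns) >= {"gap_days", "event", "prior_visit_count", "age",
                               "sex_female", "upper_airway_count", "AR"}


# ---------------------------------------------------------------------------
# Cox fitting — frozen external oracle


def _oracle_fixture():
    """Deterministic multi-patient gap-time data (integer gaps, with ties)."""
    rng = np.random.default_rng(42)
    rows = []
    for pid in range(12):
        x1 = pid % 2
        x2 = round(float(rng.normal()), 2)
        k = int(rng.integers(2, 5))
        for i in range(1, k + 1):
            gap = int(rng.integers(5, 60))
            rows.append(
                {"patient_id": f"p{pid}", "interval_index": i, "gap_days": gap,
                 "event": 1 if i < k else 0, "x1": x1, "x2": x2}
            )
    return pd.DataFrame(rows)


def test_cox_matches_survival_package_oracle():
    """Coefficients/SEs equal survival::coxph (Efron ties) on a frozen fixture."""
    fit = fit_cox(_oracle_fixture(), ["x1", "x2"])
    # frozen from R: coxph(Surv(gap_days, event) ~ x1 + x2, ties="efron")
    assert fit.coefficients["x1"] == pytest.approx(-0.16838987238, abs=1e-5)
    assert fit.coefficients["x2"] == pytest.approx(-0.08787124384, abs=1e-5)
    assert fit.standard_errors["x1"] == pytest.approx(0.5052421615, abs=1e-5)
    assert fit.standard_errors["x2"] == pytest.approx(0.3016796531, abs=1e-5)
    assert fit.concordance == pytest.approx(0.46580188679, abs=1e-6)


def test_hazard_ratio_is_exp_coefficient():
    fit = fit_cox(_oracle_fixture(), ["x1", "x2"])
    for name in ("x1", "x2"):
        assert fit.hazard_ratios[name] == pytest.approx(
            np.exp(fit.coefficients[name]), rel=1e-10
        )
        assert fit.ci_lower[name] < fit.hazard_ratios[name] < fit.ci_upper[name]


def test_constant_covariate_dropped_with_warning():
    df = _oracle_fixture()
    df["flat"] = 1.0
    fit = fit_cox(df, ["x1", "x2", "flat"])
    assert "flat" in fit.dropped
    assert "flat" not in fit.coefficients.index


def test_too_few_events_rejected():
    df = _oracle_fixture().head(2).copy()
    df["event"] = 0
    with pytest.raises(ValidationError):
        fit_cox(df, ["x1"])


# ---------------------------------------------------------------------------
# simulation helpers


def _simulate_gap_cohort(n_patients, log_hr, seed, base_rate=4.0, years=2.0,
                         n_covariates=1, p_exposed=0.5):
    """Exponential-gap renewal cohort with one effective binary covariate.

    The first covariate multiplies the visit rate by exp(log_hr); any others
    are pure noise.  Returns an interval frame built through the public
    constructor.
    """
    rng = np.random.default_rng(seed)
    study_end = D0 + timedelta(days=int(round(years * 365.25)))
    frames = []
    for i in range(n_patients):
        x = (rng.random(n_covariates) < p_exposed).astype(float)
        rate = base_rate * np.exp(log_hr * x[0]) / 365.25  # per day
        dates = [D0]
        current = D0
        while True:
            gap = max(1, int(round(rng.exponential(1 / rate))))
            current = current + timedelta(days=gap)
            if current > study_end:
                break
            dates.append(current)
        cov = {f"x{j}": float(x[j]) for j in range(n_covariates)}
        recs = build_interval_records(dates, cov, f"p{i}", study_end)
        frames.append(pd.DataFrame([{
            "patient_id": r.patient_id, "gap_days": r.gap_days, "event": r.event,
            "prior_visit_count": r.prior_visit_count, **r.covariates,
        } for r in recs]))
    return pd.concat(frames, ignore_index=True)


def test_planted_rate_ratio_recovered():
    """A covariate doubling the visit rate fits to an HR near 2."""
    iv = _simulate_gap_cohort(n_patients=800, log_hr=np.log(2.0), seed=21)
    fit = fit_cox(iv, ["x0"])
    assert 1.7 < fit.hazard_ratios["x0"] < 2.35


def test_null_concordance_near_half():
    iv = _simulate_gap_cohort(n_patients=1000, log_hr=0.0, seed=22)
    fit = fit_cox(iv, ["x0"])
    assert abs(fit.concordance - 0.5) < 0.03


def test_forest_directions():
    fit = fit_cox(_simulate_gap_cohort(600, np.log(2.0), seed=23), ["x0"])
    tbl = forest_table(fit)
    assert tbl.loc["x0", "direction"] == "positive"
    null_fit = fit_cox(_simulate_gap_cohort(300, 0.0, seed=24), ["x0"])
    assert forest_table(null_fit).loc["x0", "direction"] == "null-crossing"


# ---------------------------------------------------------------------------
# penalized path


def test_lasso_near_zero_penalty_matches_unpenalized():
    rng = np.random.default_rng(0)
    n = 150
    X = rng.normal(size=(n, 2))
    t = rng.exponential(100, n) * np.exp(-0.5 * X[:, 0])  # continuous, tie-free
    e = (rng.random(n) < 0.8).astype(int)
    df = pd.DataFrame({"patient_id": [f"p{i}" for i in range(n)],
                       "gap_days": t, "event": e, "x1": X[:, 0], "x2": X[:, 1]})
    unpen = fit_cox(df, ["x1", "x2"])
    lasso = fit_lasso_cox(df, ["x1", "x2"], n_folds=3, seed=1,
                          alphas=[1e-8], tol=1e-9)
    np.testing.assert_allclose(
        lasso.coef_path.iloc[:, -1].values, unpen.coefficients.values, atol=1e-4
    )


def test_lasso_large_penalty_empty_model():
    iv = _simulate_gap_cohort(200, np.log(2.0), seed=30, n_covariates=3)
    fit = fit_lasso_cox(iv, ["x0", "x1", "x2"], n_folds=3, seed=2, alphas=[100.0, 50.0])
    assert (fit.coef_path.iloc[:, 0] == 0).all()


def test_lasso_selects_strong_planted_predictor():
    iv = _simulate_gap_cohort(600, np.log(2.0), seed=31, n_covariates=6)
    fit = fit_lasso_cox(iv, [f"x{j}" for j in range(6)], n_folds=4, seed=3)
    assert "x0" in fit.selected


def test_lasso_1se_at_least_min_and_deterministic():
    iv = _simulate_gap_cohort(300, np.log(1.5), seed=32, n_covariates=4)
    covs = [f"x{j}" for j in range(4)]
    a = fit_lasso_cox(iv, covs, n_folds=4, seed=9)
    b = fit_lasso_cox(iv, covs, n_folds=4, seed=9)
    assert a.alpha_1se >= a.alpha_min
    assert a.alpha_1se == b.alpha_1se
    assert (a.coefficients == b.coefficients).all()
    # sparsity grows (weakly) as the penalty relaxes along the path
    nnz = (a.coef_path.abs() > 1e-10).sum(axis=0).values  # columns: descending alpha
    assert nnz[0] <= nnz[-1]
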