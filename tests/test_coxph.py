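"""Proportional-hazards machinery against hand calculations and independent
oracles (scipy optimisation of the hand-coded partial likelihood, lifelines)."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

from crcpear import coxph
from crcpear.coxph import (CoxFit, RankDeficiencyError, carrier_hr_report,
                           cumulative_incidence, fit_cox, fit_cox_arrays,
                           supremum_ph_test)


def _hand_neg_loglik(beta, time, event, x):
    """Breslow log partial likelihood for one covariate, coded from the
    definition (risk set = subjects with time >= t)."""
    ll = 0.0
    for i in range(len(time)):
        if event[i]:
            risk = np.flatnonzero(time >= time[i])
            ll += beta * x[i] - np.log(np.exp(beta * x[risk]).sum())
    return -ll


def test_beta_matches_hand_partial_likelihood(tiny_survival):
    d = tiny_survival
    fit = fit_cox(d, ["x"], cluster_by=None)
    res = minimize_scalar(
        _hand_neg_loglik, bounds=(-5, 5), method="bounded",
        args=(d["time_y"].to_numpy(), d["event"].to_numpy(),
              d["x"].to_numpy()))
    assert fit.beta[0] == pytest.approx(res.x, abs=1e-6)
    assert fit.loglik == pytest.approx(-res.fun, abs=1e-9)


def test_matches_lifelines_no_ties(cohort):
    lifelines = pytest.importorskip("lifelines")
    sub = cohort.iloc[:500][["time_y", "event", "carrier", "age_y", "bmi",
                             "pedigree_id"]].copy()
    assert sub["time_y"].is_unique  # continuous times: Breslow == Efron
    fit = fit_cox(sub, ["carrier", "age_y", "bmi"], cluster_by=None)
    cph = lifelines.CoxPHFitter()
    cph.fit(sub.drop(columns="pedigree_id"), duration_col="time_y",
            event_col="event", fit_options={"precision": 1e-12})
    np.testing.assert_allclose(fit.beta, cph.params_.to_numpy(), atol=1e-6)
    model_se = np.sqrt(np.diag(fit.cov_model))
    np.testing.assert_allclose(model_se, cph.standard_errors_.to_numpy(),
                               rtol=1e-5)


def test_cluster_robust_matches_lifelines(cohort):
    lifelines = pytest.importorskip("lifelines")
    sub = cohort.iloc[:500][["time_y", "event", "carrier", "age_y",
                             "pedigree_id"]].copy()
    fit = fit_cox(sub, ["carrier", "age_y"], cluster_by="pedigree_id")
    cph = lifelines.CoxPHFitter()
    cph.fit(sub, duration_col="time_y", event_col="event", robust=True,
            cluster_col="pedigree_id", fit_options={"precision": 1e-12})
    np.testing.assert_allclose(fit.se_robust,
                               cph.standard_errors_.to_numpy(), rtol=1e-4)


def test_singleton_clusters_equal_unclustered(cohort):
    sub = cohort.iloc[:300].copy()
    sub["own_cluster"] = np.arange(len(sub))
    a = fit_cox(sub, ["carrier", "age_y"], cluster_by="own_cluster")
    b = fit_cox(sub, ["carrier", "age_y"], cluster_by=None)
    np.testing.assert_allclose(a.se_robust, b.se_robust, rtol=1e-10)


def test_time_scale_invariance(tiny_survival):
    d = tiny_survival
    a = fit_cox(d, ["x"], cluster_by=None)
    d2 = d.assign(time_y=d["time_y"] * 365.25)
    b = fit_cox(d2, ["x"], cluster_by=None)
    assert a.beta[0] == pytest.approx(b.beta[0], abs=1e-10)
    assert a.se_robust[0] == pytest.approx(b.se_robust[0], abs=1e-10)


def test_efron_equals_breslow_without_ties(tiny_survival):
    a = fit_cox(tiny_survival, ["x"], cluster_by=None, ties="breslow")
    b = fit_cox(tiny_survival, ["x"], cluster_by=None, ties="efron")
    assert a.beta[0] == pytest.approx(b.beta[0], abs=1e-9)


def test_constant_covariate_raises(tiny_survival):
    d = tiny_survival.assign(x=1.0)
    with pytest.raises((RankDeficiencyError, ValueError)):
        fit_cox(d, ["x"], cluster_by=None)


def test_primary_fit_on_cohort(cohort):
    from crcpear.experiments import fit_primary_model
    fit = fit_primary_model(cohort)
    assert fit.converged
    assert fit.n == len(cohort)
    assert fit.n_events == int(cohort["event"].sum())
    assert (fit.ci_lo <= fit.hr).all() and (fit.hr <= fit.ci_hi).all()


def test_km_hand_example():
    d = pd.DataFrame({"g": [0, 0, 0], "time_y": [1.0, 2.0, 3.0],
                      "event": [1, 1, 0]})
    curve, = cumulative_incidence(d, group_by="g")
    np.testing.assert_allclose(curve.incidence, [1 / 3, 2 / 3])
    np.testing.assert_allclose(curve.time, [1.0, 2.0])
    assert not curve.adjusted


def test_adjusted_incidence_monotone(cohort):
    curves = cumulative_incidence(cohort, group_by="carrier",
                                  adjust=["sex", "age_y"])
    assert len(curves) == 2
    for c in curves:
        assert c.adjusted
        assert (np.diff(c.incidence) >= -1e-12).all()
        assert c.incidence[-1] < 0.2  # rare outcome


def test_supremum_null_calibration(rng):
    """Under proportional hazards the test should reject near its level."""
    n_datasets, n = 300, 80
    rejections = 0
    for _ in range(n_datasets):
        x = rng.binomial(1, 0.4, size=n).astype(float)
        t = rng.exponential(1.0 / np.exp(0.3 * x))
        c = rng.uniform(0.2, 2.0, size=n)
        time = np.minimum(t, c)
        event = (t <= c).astype(int)
        if event.sum() < 5 or len(np.unique(x[event == 1])) < 2:
            continue
        fit = fit_cox_arrays(time, event, x[:, None], terms=["x"])
        if not fit.converged:
            continue
        res = supremum_ph_test(fit, n_replications=200, seed=rng)
        rejections += res.p[0] < 0.05
    rate = rejections / n_datasets
    assert 0.01 <= rate <= 0.10


def test_supremum_on_cohort(cohort):
    from crcpear.experiments import fit_primary_model
    fit = fit_primary_model(cohort)
    res = supremum_ph_test(fit, n_replications=200, seed=5)
    assert res.terms == fit.terms
    assert ((res.p > 0) & (res.p <= 1)).all()


def test_carrier_hr_report_formatting():
    fit = CoxFit(
        terms=["carrier"], beta=np.array([0.0]),
        cov_model=np.array([[1.0]]), cov_robust=np.array([[1.0]]),
        hr=np.array([1.0]), ci_lo=np.array([0.14]), ci_hi=np.array([7.10]),
        p=np.array([1.0]), se_robust=np.array([1.0]), n=4, n_events=2,
        converged=True, ties_method="breslow", loglik=0.0, score_norm=0.0)
    rec = carrier_hr_report(fit)
    assert rec["formatted"] == "1.00 (0.14–7.10; p=1.000)"
    assert rec["hr_rounded"] == 1.0
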