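"""Methylation PLS-DA: transforms, PLS core vs the sklearn oracle, PRESS,
factor selection, VIP and V-plot classification."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from crcpear.plsda import (adjusted_outcome, pls_fit, press_cv,
                           qc_duplicate_filter, rank_inverse_normal,
                           run_plsda, v_plot, vdv_select, vip_scores)


# ---------------------------------------------------------------- QC / INT

def test_qc_keeps_concordant_duplicates():
    keep, value = qc_duplicate_filter(10.0, 11.0)
    assert keep and value == pytest.approx(10.5)


def test_qc_rejects_discordant_duplicates():
    # |d1 - d2|/sqrt(2) = 14.1 percentage points >= 5
    keep, value = qc_duplicate_filter(0.0, 20.0)
    assert not keep and value is None


def test_qc_bounds_enforced():
    with pytest.raises(ValueError):
        qc_duplicate_filter(-1.0, 50.0)
    with pytest.raises(ValueError):
        qc_duplicate_filter(10.0, 101.0)


def test_int_blom_hand_example():
    out = rank_inverse_normal(np.array([5.0, 1.0, 3.0]))
    expected = norm.ppf((np.array([3, 1, 2]) - 0.375) / 3.25)
    np.testing.assert_allclose(out, expected, atol=1e-12)
    assert out[2] == pytest.approx(0.0, abs=1e-12)


def test_int_is_monotone_and_scale_free(rng):
    x = rng.gamma(2.0, size=200)
    a = rank_inverse_normal(x)
    b = rank_inverse_normal(100.0 * x + 5.0)
    np.testing.assert_allclose(a, b, atol=1e-12)
    assert (np.diff(a[np.argsort(x)]) >= 0).all()


def test_int_propagates_missing_and_handles_ties():
    x = np.array([1.0, np.nan, 2.0, 2.0, 3.0])
    out = rank_inverse_normal(x)
    assert np.isnan(out[1])
    assert out[2] == out[3]


# ---------------------------------------------------------- adjusted outcome

def test_adjusted_outcome_standardised(rng):
    n = 400
    covs = pd.DataFrame({"age": rng.normal(50, 10, n),
                         "sex": rng.binomial(1, 0.5, n)})
    case = rng.binomial(1, 0.05, n)
    case[0] = 1  # ensure non-constant
    y, method = adjusted_outcome(case, covs)
    assert method == "logistic"
    assert y.mean() == pytest.approx(0.0, abs=1e-10)
    assert y.std(ddof=1) == pytest.approx(1.0, abs=1e-10)


def test_adjusted_outcome_separation_falls_back(rng):
    n = 100
    x = np.r_[np.zeros(50), np.ones(50)]
    case = x.astype(int)  # perfectly separated
    covs = pd.DataFrame({"x": x})
    with pytest.warns(RuntimeWarning):
        y, method = adjusted_outcome(case, covs)
    assert method == "linear"


def test_adjusted_outcome_constant_case_rejected():
    covs = pd.DataFrame({"x": [1.0, 2.0, 3.0]})
    with pytest.raises(ValueError):
        adjusted_outcome(np.zeros(3), covs)


# ------------------------------------------------------------------ PLS core

def test_pls_matches_sklearn_oracle(rng):
    sklearn = pytest.importorskip("sklearn.cross_decomposition")
    n, p, a = 60, 8, 3
    X = rng.normal(size=(n, p))
    y = X @ rng.normal(size=p) + rng.normal(size=n)
    ours = pls_fit(X, y, a_max=a)
    ref = sklearn.PLSRegression(n_components=a, scale=True).fit(X, y[:, None])
    np.testing.assert_allclose(ours.predict(X, a),
                               ref.predict(X).ravel(), atol=1e-8)


def test_pls_one_factor_equals_scaled_regression_direction(rng):
    X = rng.normal(size=(50, 4))
    y = rng.normal(size=50)
    model = pls_fit(X, y, a_max=1)
    Xs = (X - model.x_mean) / model.x_sd
    ys = (y - model.y_mean) / model.y_sd
    w = Xs.T @ ys
    w /= np.linalg.norm(w)
    np.testing.assert_allclose(np.abs(model.weights[:, 0]), np.abs(w),
                               atol=1e-10)


def test_press_zero_factors_is_loo_mean():
    X = np.array([[0.0, 1.0], [1.0, 0.0], [2.0, 2.0]])
    y = np.array([1.0, 2.0, 3.0])
    press, sq = press_cv(X, y, a_max=1)
    # LOO means: 2.5, 2.0, 1.5 -> squared residuals 2.25, 0, 2.25
    assert press[0] == pytest.approx(4.5)
    np.testing.assert_allclose(sq[:, 0], [2.25, 0.0, 2.25])


def test_press_detects_predictive_structure(rng):
    n, p = 80, 6
    X = rng.normal(size=(n, p))
    y = 2.0 * X[:, 0] + 0.1 * rng.normal(size=n)
    press, _ = press_cv(X, y, a_max=3)
    assert press[1] < press[0]  # one factor beats the null model


def test_vdv_identical_columns_select_zero(rng):
    sq = np.tile(rng.gamma(1.0, size=(40, 1)), (1, 3))
    selected, pvals = vdv_select(sq, seed=1)
    assert selected == 0
    np.testing.assert_allclose(pvals, 1.0)


def test_vdv_selects_clearly_better_column(rng):
    n = 60
    sq = np.column_stack([np.full(n, 4.0) + rng.uniform(0, 0.1, n),
                          rng.uniform(0, 0.1, n),
                          rng.uniform(0, 0.1, n)])
    selected, pvals = vdv_select(sq, seed=1)
    assert selected == 1
    assert pvals[0] < 0.01


def test_vip_sum_of_squares_equals_site_count(rng):
    X = rng.normal(size=(50, 16))
    y = rng.normal(size=50)
    model = pls_fit(X, y, a_max=3)
    vip = vip_scores(model, 3)
    assert (vip ** 2).sum() == pytest.approx(16.0)


def test_vip_two_driver_sites(rng):
    """With exactly two informative, equally weighted sites the one-factor
    VIP concentrates there: each scores near sqrt(p/2) = sqrt(8)."""
    n, p = 3000, 16
    X = rng.normal(size=(n, p))
    y = X[:, 0] + X[:, 1]
    model = pls_fit(X, y, a_max=1)
    vip = vip_scores(model, 1)
    assert vip[0] == pytest.approx(np.sqrt(8.0), rel=0.05)
    assert vip[1] == pytest.approx(np.sqrt(8.0), rel=0.05)
    assert vip[2:].max() < 1.0


# ------------------------------------------------------------------ V-plot

def test_v_plot_quadrants(rng):
    n = 500
    X = rng.normal(size=(n, 4))
    y = 1.5 * X[:, 0] - 1.5 * X[:, 1] + 0.2 * rng.normal(size=n)
    model = pls_fit(X, y, a_max=2)
    table = v_plot(model, X, y, vip_threshold=1.1, a=2)
    frame = table.to_frame()
    assert frame.loc[0, "quadrant"] == "higher-risk"
    assert frame.loc[1, "quadrant"] == "lower-risk"
    assert set(frame.loc[2:, "quadrant"]) == {"below-threshold"}


def test_run_plsda_drops_incomplete_subjects(sim):
    meth = sim.methylation.copy()
    meth.iloc[0, 0] = np.nan
    meth.iloc[5, 3] = np.nan
    meta = sim.meth_meta.set_index("id")
    covs = pd.DataFrame({"age": np.linspace(30, 70, len(meth)),
                         "sex": np.tile([0, 1], len(meth) // 2 + 1)[:len(meth)]},
                        index=meth.index)
    res = run_plsda(meth, meta["case"].to_numpy(), covs, seed=3)
    assert res.n_excluded_missing == 2
    assert res.n_subjects == len(meth) - 2
    assert len(res.vplot.site) == 16


def test_run_plsda_recovers_planted_structure(sim):
    from crcpear.config import METHYLATION_ADJUSTMENT
    meta = sim.meth_meta.set_index("id")
    covs = sim.cohort_table.set_index("id").loc[
        meta.index, [c for c in METHYLATION_ADJUSTMENT
                     if c != "time_interval_y"]].copy()
    covs["time_interval_y"] = meta["time_interval_y"]
    res = run_plsda(sim.methylation, meta["case"].to_numpy(), covs, seed=3)
    frame = res.vplot.to_frame()
    hi = set(frame.loc[frame["quadrant"] == "higher-risk", "site"])
    lo = set(frame.loc[frame["quadrant"] == "lower-risk", "site"])
    truth_hi = set(sim.truth["planted_sites_higher_risk"])
    truth_lo = set(sim.truth["planted_sites_lower_risk"])
    # planted sites dominate the flagged quadrants
    assert truth_hi <= hi or len(truth_hi & hi) >= 1
    assert truth_lo <= lo or len(truth_lo & lo) >= 1
    assert res.selected_factors >= 1
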