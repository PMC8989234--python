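"""Descriptive statistics: group comparisons, paired changes, odds ratios."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from crcpear.descriptives import (compare_groups, fisher_exact_2x2,
                                  odds_ratio, paired_change,
                                  prevalence_change)


# ------------------------------------------------------------ group tests

def test_fisher_hand_example():
    # classic 4-vs-4 table
    assert fisher_exact_2x2(3, 1, 1, 3) == pytest.approx(0.485714, abs=1e-6)


def test_fisher_matches_hypergeometric_oracle():
    a, b, c, d = 7, 2, 3, 8
    p_pkg = fisher_exact_2x2(a, b, c, d)
    # oracle: sum hypergeometric probabilities no larger than the observed
    row1, col1, n = a + b, a + c, a + b + c + d
    probs = [stats.hypergeom.pmf(k, n, row1, col1)
             for k in range(max(0, col1 - (n - row1)), min(row1, col1) + 1)]
    p_obs = stats.hypergeom.pmf(a, n, row1, col1)
    oracle = sum(p for p in probs if p <= p_obs * (1 + 1e-9))
    assert p_pkg == pytest.approx(oracle, rel=1e-9)


def test_compare_groups_mixed_variables():
    rng = np.random.default_rng(4)
    n = 300
    frame = pd.DataFrame({
        "g": rng.binomial(1, 0.4, n),
        "age": rng.normal(50, 10, n),
        "smoker": rng.binomial(1, 0.3, n),
    })
    out = compare_groups(frame, "g", ["age", "smoker"])
    by_var = {c.variable: c for c in out}
    assert by_var["age"].kind == "continuous"
    assert by_var["age"].test == "large_sample_z"
    assert by_var["smoker"].kind == "binary"
    assert by_var["smoker"].test == "fisher_exact"
    assert 0 <= by_var["age"].p <= 1
    # no true group difference: should rarely be significant
    assert by_var["age"].p > 0.001


def test_compare_groups_needs_two_levels():
    frame = pd.DataFrame({"g": [1, 1, 1], "x": [1.0, 2.0, 3.0]})
    with pytest.raises(ValueError):
        compare_groups(frame, "g", ["x"])


def test_compare_groups_z_matches_hand():
    frame = pd.DataFrame({"g": [0] * 4 + [1] * 4,
                          "x": [1.0, 2.0, 3.0, 4.0, 3.0, 4.0, 5.0, 6.0]})
    out, = compare_groups(frame, "g", ["x"])
    s = np.std([1, 2, 3, 4], ddof=1)
    z = 2.0 / np.sqrt(s ** 2 / 4 + s ** 2 / 4)
    assert out.p == pytest.approx(2 * stats.norm.sf(z), abs=1e-12)


# ------------------------------------------------------------ paired change

def _waves(base, follow):
    return (pd.DataFrame({"v": base}), pd.DataFrame({"v": follow}))


def test_paired_continuous_matches_scipy():
    rng = np.random.default_rng(9)
    x0 = rng.normal(25, 3, 60)
    x1 = x0 + rng.normal(0.5, 1.0, 60)
    b, f = _waves(x0, x1)
    out, = paired_change(b, f, ["v"])
    assert out.test == "paired_t"
    assert out.p == pytest.approx(stats.ttest_rel(x1, x0).pvalue, rel=1e-12)
    assert out.ci_lo < out.change < out.ci_hi


def test_mcnemar_chi_square_branch():
    # 15 gained, 5 lost among 100: chi2 = (15-5)^2/20 = 5
    x0 = np.r_[np.ones(40), np.zeros(60)]
    x1 = x0.copy()
    x1[:5] = 0      # lost
    x1[40:55] = 1   # gained
    b, f = _waves(x0, x1)
    out, = paired_change(b, f, ["v"])
    assert out.test == "mcnemar"
    assert out.p == pytest.approx(stats.chi2.sf(5.0, 1), rel=1e-12)
    assert out.change == pytest.approx(10.0)  # percentage points


def test_mcnemar_exact_branch_few_discordant():
    x0 = np.r_[np.ones(10), np.zeros(40)]
    x1 = x0.copy()
    x1[0] = 0            # 1 lost
    x1[10:15] = 1        # 5 gained
    b, f = _waves(x0, x1)
    out, = paired_change(b, f, ["v"])
    assert out.test == "mcnemar_exact"
    assert out.p == pytest.approx(stats.binomtest(5, 6, 0.5).pvalue, rel=1e-12)


def test_mcnemar_no_discordant_pairs():
    x0 = np.r_[np.ones(5), np.zeros(5)]
    b, f = _waves(x0, x0.copy())
    out, = paired_change(b, f, ["v"])
    assert out.p == 1.0 and out.change == 0.0


def test_paired_waves_must_align():
    with pytest.raises(ValueError):
        paired_change(pd.DataFrame({"v": [1.0, 2.0]}),
                      pd.DataFrame({"v": [1.0]}), ["v"])


def test_prevalence_change_from_printed_percentages():
    assert prevalence_change(25.5, 14.9) == pytest.approx(-10.6)


# ------------------------------------------------------------ odds ratios

def test_odds_ratio_hand_example():
    res = odds_ratio(10, 20, 30, 40)
    assert res.odds_ratio == pytest.approx(2.0 / 3.0)
    se = np.sqrt(1 / 10 + 1 / 20 + 1 / 30 + 1 / 40)
    lo = np.exp(np.log(2 / 3) - 1.959963984540054 * se)
    hi = np.exp(np.log(2 / 3) + 1.959963984540054 * se)
    assert res.ci_lo == pytest.approx(lo, rel=1e-9)
    assert res.ci_hi == pytest.approx(hi, rel=1e-9)
    assert not res.corrected


def test_odds_ratio_zero_cell_correction():
    res = odds_ratio(0, 10, 5, 20)
    assert res.corrected
    assert res.odds_ratio == pytest.approx(0.5 * 20.5 / (10.5 * 5.5))


def test_odds_ratio_logistic_equals_woolf():
    rng = np.random.default_rng(2)
    exposure = rng.binomial(1, 0.4, 500)
    case = rng.binomial(1, 0.2 + 0.2 * exposure)
    a = int(((case == 1) & (exposure == 1)).sum())
    b = int(((case == 0) & (exposure == 1)).sum())
    c = int(((case == 1) & (exposure == 0)).sum())
    d = int(((case == 0) & (exposure == 0)).sum())
    table = odds_ratio(a, b, c, d)
    logit = odds_ratio(case=case, exposure=exposure)
    assert logit.odds_ratio == pytest.approx(table.odds_ratio, rel=1e-6)
    assert logit.ci_lo == pytest.approx(table.ci_lo, rel=1e-4)


def test_odds_ratio_exposure_inversion_symmetry():
    a = odds_ratio(12, 34, 56, 78)
    b = odds_ratio(56, 78, 12, 34)
    assert a.odds_ratio == pytest.approx(1.0 / b.odds_ratio, rel=1e-12)
    assert a.p == pytest.approx(b.p, rel=1e-12)


def test_odds_ratio_requires_all_cells():
    with pytest.raises(ValueError):
        odds_ratio(1, 2, 3)
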