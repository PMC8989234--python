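"""Descriptive-table statistics and the generic odds-ratio operation.

Group comparisons use the large-sample z-test on means and Fisher's exact
test on 2x2 tables; within-subject changes use the paired t-statistic and
McNemar's test; odds ratios come from the 2x2 cross product with a Woolf
confidence interval or, with covariates, from a logistic model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import norm

Z975 = norm.ppf(0.975)


@dataclass
class GroupComparison:
    variable: str
    kind: str                     # "continuous" | "binary"
    group_summaries: dict         # per group: n and mean/sd or count/percent
    test: str
    p: float | None
    note: str = ""


@dataclass
class PairedChange:
    variable: str
    kind: str
    baseline: float
    followup: float
    change: float
    ci_lo: float
    ci_hi: float
    test: str
    p: float
    note: str = ""


@dataclass
class OddsRatioResult:
    odds_ratio: float
    ci_lo: float
    ci_hi: float
    p: float
    method: str
    corrected: bool = False


# ----------------------------------------------------------------------

def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p (minimum-likelihood tail convention)."""
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def compare_groups(cohort: pd.DataFrame, group: str,
                   variables: Sequence[str],
                   binary_vars: Sequence[str] | None = None
                   ) -> list[GroupComparison]:
    """Compare each variable between the two levels of ``group``.

    Continuous variables use the large-sample z-test on means; binary
    variables use Fisher's exact test on the 2x2 table.
    """
    levels = sorted(cohort[group].dropna().unique())
    if len(levels) != 2:
        raise ValueError(f"{group} must have exactly two levels, got {levels}")
    g0 = cohort[cohort[group] == levels[0]]
    g1 = cohort[cohort[group] == levels[1]]
    if len(g0) == 0 or len(g1) == 0:
        raise ValueError("both groups must be non-empty")
    binary_vars = set(binary_vars or [])
    out = []
    for var in variables:
        is_binary = var in binary_vars or set(
            cohort[var].dropna().unique()) <= {0, 1}
        if is_binary:
            a, b = int(g1[var].sum()), int((1 - g1[var]).sum())
            c, d = int(g0[var].sum()), int((1 - g0[var]).sum())
            p = fisher_exact_2x2(a, b, c, d)
            summaries = {
                str(levels[1]): {"n": len(g1), "count": a,
                                 "percent": 100.0 * a / len(g1)},
                str(levels[0]): {"n": len(g0), "count": c,
                                 "percent": 100.0 * c / len(g0)},
            }
            out.append(GroupComparison(var, "binary", summaries,
                                       "fisher_exact", p))
        else:
            m1, s1, n1 = g1[var].mean(), g1[var].std(ddof=1), len(g1)
            m0, s0, n0 = g0[var].mean(), g0[var].std(ddof=1), len(g0)
            se = math.sqrt(s1 ** 2 / n1 + s0 ** 2 / n0)
            summaries = {
                str(levels[1]): {"n": n1, "mean": m1, "sd": s1},
                str(levels[0]): {"n": n0, "mean": m0, "sd": s0},
            }
            if se == 0:
                out.append(GroupComparison(var, "continuous", summaries,
                                           "large_sample_z", None,
                                           note="zero variance"))
            else:
                z = (m1 - m0) / se
                out.append(GroupComparison(var, "continuous", summaries,
                                           "large_sample_z",
                                           float(2 * norm.sf(abs(z)))))
    return out


def paired_change(baseline: pd.DataFrame, followup: pd.DataFrame,
                  variables: Sequence[str],
                  binary_vars: Sequence[str] | None = None
                  ) -> list[PairedChange]:
    """Within-subject change between two waves (same subjects, same order).

    Continuous: paired t with the CI of the mean difference.  Binary:
    McNemar's chi-square (no continuity correction) with a Wald CI for the
    difference of proportions, in percentage points.
    """
    if len(baseline) != len(followup):
        raise ValueError("waves must contain the same subjects")
    n = len(baseline)
    binary_vars = set(binary_vars or [])
    out = []
    for var in variables:
        x0 = baseline[var].to_numpy(dtype=float)
        x1 = followup[var].to_numpy(dtype=float)
        is_binary = var in binary_vars or (
            set(np.unique(x0)) | set(np.unique(x1))) <= {0.0, 1.0}
        if is_binary:
            b = int(((x0 == 0) & (x1 == 1)).sum())  # gained
            c = int(((x0 == 1) & (x1 == 0)).sum())  # lost
            diff = 100.0 * (b - c) / n
            se = 100.0 * math.sqrt(max(b + c - (b - c) ** 2 / n, 0.0)) / n
            if b + c == 0:
                p, test, note = 1.0, "mcnemar_exact", "no discordant pairs"
            elif b + c < 10:
                p = float(stats.binomtest(b, b + c, 0.5).pvalue)
                test, note = "mcnemar_exact", "exact binomial (few discordant pairs)"
            else:
                chi2 = (b - c) ** 2 / (b + c)
                p = float(stats.chi2.sf(chi2, df=1))
                test, note = "mcnemar", ""
            out.append(PairedChange(var, "binary", 100.0 * x0.mean(),
                                    100.0 * x1.mean(), diff,
                                    diff - Z975 * se, diff + Z975 * se,
                                    test, p, note))
        else:
            d = x1 - x0
            md = float(d.mean())
            se = float(d.std(ddof=1) / math.sqrt(n))
            tres = stats.ttest_rel(x1, x0)
            out.append(PairedChange(var, "continuous", float(x0.mean()),
                                    float(x1.mean()), md,
                                    md - Z975 * se, md + Z975 * se,
                                    "paired_t", float(tres.pvalue)))
    return out


def prevalence_change(baseline_pct: float, followup_pct: float) -> float:
    """Change in prevalence, percentage points, from printed percentages."""
    return round(followup_pct - baseline_pct, 10)


# ----------------------------------------------------------------------

def odds_ratio(a: int | None = None, b: int | None = None,
               c: int | None = None, d: int | None = None, *,
               case: np.ndarray | None = None,
               exposure: np.ndarray | None = None,
               covariates: pd.DataFrame | None = None) -> OddsRatioResult:
    """Odds ratio with 95% CI.

    2x2 form (``a``=exposed cases, ``b``=exposed controls, ``c``=unexposed
    cases, ``d``=unexposed controls): cross-product estimate with the Woolf
    interval; a zero cell triggers the Haldane-Anscombe 0.5 correction,
    flagged.  Vector form: logistic regression Wald inference, which equals
    the 2x2 form exactly when no covariates are supplied.
    """
    if case is not None:
        import statsmodels.api as sm

        case = np.asarray(case, dtype=float)
        exposure = np.asarray(exposure, dtype=float)
        cols = [exposure]
        if covariates is not None:
            cols.extend(np.asarray(covariates, dtype=float).T)
        X = sm.add_constant(np.column_stack(cols))
        model = sm.Logit(case, X).fit(disp=0)
        beta = float(model.params[1])
        se = float(model.bse[1])
        return OddsRatioResult(math.exp(beta), math.exp(beta - Z975 * se),
                               math.exp(beta + Z975 * se),
                               float(2 * norm.sf(abs(beta / se))), "logistic")
    cells = [a, b, c, d]
    if any(v is None or v < 0 for v in cells):
        raise ValueError("all four cells required and non-negative")
    corrected = 0 in cells
    if corrected:
        cells = [v + 0.5 for v in cells]
    a_, b_, c_, d_ = cells
    if min(a_ + b_, c_ + d_, a_ + c_, b_ + d_) <= 0:
        raise ValueError("a margin of the 2x2 table is zero")
    log_or = math.log(a_ * d_ / (b_ * c_))
    se = math.sqrt(1 / a_ + 1 / b_ + 1 / c_ + 1 / d_)
    return OddsRatioResult(math.exp(log_or), math.exp(log_or - Z975 * se),
                           math.exp(log_or + Z975 * se),
                           float(2 * norm.sf(abs(log_or / se))),
                           "woolf", corrected=corrected)
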