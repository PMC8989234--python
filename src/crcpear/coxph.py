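"""Proportional-hazards estimation with family-clustered robust variance.

The model is the semiparametric Cox model: hazard for subject ``i`` is
``h0(t) * exp(x_i' beta)``.  ``beta`` maximises the partial likelihood
(Breslow tie handling by default, Efron behind a flag) by Newton iteration
with step-halving.  Standard errors are cluster-robust: per-subject score
residuals are summed within pedigrees before the sandwich outer product,
which gives valid marginal inference under within-family correlation.
A Kolmogorov-type supremum test on the cumulative score process, with
multiplier (wild) resampling, checks the proportionality assumption.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

Z975 = norm.ppf(0.975)


class RankDeficiencyError(ValueError):
    """A covariate is constant or collinear on the risk sets."""


@dataclass
class CoxFit:
    terms: list[str]
    beta: np.ndarray
    cov_model: np.ndarray
    cov_robust: np.ndarray
    hr: np.ndarray
    ci_lo: np.ndarray
    ci_hi: np.ndarray
    p: np.ndarray
    se_robust: np.ndarray
    n: int
    n_events: int
    converged: bool
    ties_method: str
    loglik: float
    score_norm: float
    diagnostic: str = ""
    _state: dict = field(default_factory=dict, repr=False)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({
            "term": self.terms, "coef": self.beta, "hr": self.hr,
            "se_robust": self.se_robust, "ci_lo": self.ci_lo,
            "ci_hi": self.ci_hi, "p": self.p,
        })

    def term_index(self, term: str) -> int:
        try:
            return self.terms.index(term)
        except ValueError as exc:
            raise KeyError(f"term {term!r} not in model") from exc


@dataclass
class PHTestResult:
    terms: list[str]
    sup_statistic: np.ndarray
    p: np.ndarray
    n_replications: int


@dataclass
class IncidenceCurve:
    group: str
    time: np.ndarray
    incidence: np.ndarray
    se: np.ndarray
    adjusted: bool
    zero_events: bool = False


# ----------------------------------------------------------------------
# Partial likelihood machinery
# ----------------------------------------------------------------------

class _CoxData:
    """Sorted design with tie-group bookkeeping (ascending time)."""

    def __init__(self, time: np.ndarray, event: np.ndarray, X: np.ndarray,
                 clusters: np.ndarray):
        order = np.lexsort((1 - event, time))  # within a time, events last is
        # irrelevant for Breslow/Efron (risk sets defined by time only)
        self.order = order
        self.time = time[order]
        self.event = event[order].astype(bool)
        self.X = X[order]
        self.clusters = clusters[order]
        self.n, self.p = self.X.shape
        # first index of each subject's time group = start of its risk set
        uniq, first = np.unique(self.time, return_index=True)
        self.risk_start = first[np.searchsorted(uniq, self.time)]
        # event groups, ascending by time
        ev_times = np.unique(self.time[self.event])
        self.group_start = first[np.searchsorted(uniq, ev_times)]
        self.group_time = ev_times
        self.group_members = [
            np.flatnonzero(self.event & (self.time == t)) for t in ev_times
        ]
        self.group_d = np.array([len(g) for g in self.group_members])
        self.has_ties = bool((self.group_d > 1).any())


def _rev_cumsum(a: np.ndarray) -> np.ndarray:
    return np.cumsum(a[::-1], axis=0)[::-1]


def _loglik_derivs(data: _CoxData, beta: np.ndarray, ties: str,
                   want_derivs: bool = True):
    """Breslow/Efron partial log-likelihood, score and information."""
    eta = data.X @ beta
    eta = eta - eta.max()  # scale-stabilise; cancels in all ratios and adds
    # a constant per event to the log-likelihood (harmless for comparisons
    # within one fit)
    w = np.exp(eta)
    wx = w[:, None] * data.X
    S0 = _rev_cumsum(w)
    S1 = _rev_cumsum(wx)
    s = data.group_start
    d = data.group_d
    ev = data.event
    ll = float(eta[ev].sum())
    if want_derivs:
        wxx = wx[:, :, None] * data.X[:, None, :]
        S2 = _rev_cumsum(wxx.reshape(data.n, -1)).reshape(data.n, data.p, data.p)
    U = None
    I = None
    if ties == "breslow" or not data.has_ties:
        ll -= float(np.sum(d * np.log(S0[s])))
        if want_derivs:
            m = S1[s] / S0[s][:, None]
            U = data.X[ev].sum(axis=0) - (d[:, None] * m).sum(axis=0)
            V = S2[s] / S0[s][:, None, None] - m[:, :, None] * m[:, None, :]
            I = np.einsum("g,gij->ij", d.astype(float), V)
    else:  # Efron
        U = np.zeros(data.p)
        I = np.zeros((data.p, data.p))
        xsum = np.zeros(data.p)
        for g, members in enumerate(data.group_members):
            dg = len(members)
            w0 = w[members].sum()
            w1 = wx[members].sum(axis=0)
            w2 = (wxx[members].sum(axis=0) if want_derivs else None)
            if not want_derivs:
                for l in range(dg):
                    ll -= math.log(S0[s[g]] - (l / dg) * w0)
                continue
            xsum += data.X[members].sum(axis=0)
            for l in range(dg):
                phi = l / dg
                s0l = S0[s[g]] - phi * w0
                ll -= math.log(s0l)
                if want_derivs:
                    s1l = S1[s[g]] - phi * w1
                    s2l = S2[s[g]] - phi * w2
                    ml = s1l / s0l
                    U -= ml
                    I += s2l / s0l - np.outer(ml, ml)
        if want_derivs:
            U = xsum + U
    return ll, U, I, w, S0, S1


def _newton(data: _CoxData, ties: str, tol: float = 1e-9,
            max_iter: int = 100) -> tuple[np.ndarray, bool, str, float, float]:
    beta = np.zeros(data.p)
    ll, U, I, *_ = _loglik_derivs(data, beta, ties)
    diagnostic = ""
    converged = False
    for _ in range(max_iter):
        score_norm = float(np.max(np.abs(U)))
        if score_norm < tol:
            converged = True
            break
        try:
            step = np.linalg.solve(I, U)
        except np.linalg.LinAlgError:
            diagnostic = "singular information matrix"
            break
        new_beta, new_ll = beta, ll
        for _half in range(40):
            cand = beta + step
            cll, cU, cI, *_ = _loglik_derivs(data, cand, ties)
            if np.isfinite(cll) and cll >= ll - 1e-12:
                new_beta, new_ll, U, I = cand, cll, cU, cI
                break
            step = step / 2.0
        else:
            diagnostic = "step-halving failed to improve the likelihood"
            break
        beta, ll = new_beta, new_ll
        if np.max(np.abs(beta)) > 200.0:
            diagnostic = ("monotone likelihood suspected (diverging "
                          "coefficient); no events in one exposure level?")
            break
    else:
        diagnostic = diagnostic or "maximum iterations reached"
    score_norm = float(np.max(np.abs(U)))
    if converged:
        diagnostic = ""
    return beta, converged, diagnostic, ll, score_norm


def _score_residuals(data: _CoxData, beta: np.ndarray, ties: str) -> np.ndarray:
    """Per-subject efficient score contributions (sorted order).

    For Efron fits with tied events the denominators are the tie-group
    averages; with no ties this reduces exactly to the Breslow formula.
    """
    _, _, _, w, S0, S1 = _loglik_derivs(data, beta, ties, want_derivs=False)
    s = data.group_start
    d = data.group_d
    G = len(d)
    p = data.p
    use_efron = ties == "efron" and data.has_ties
    a_g = np.empty(G)          # sum_l 1/S0_l
    b_g = np.empty((G, p))     # sum_l S1_l/S0_l^2
    xbar_g = np.empty((G, p))  # mean_l S1_l/S0_l
    for g, members in enumerate(data.group_members):
        if not use_efron or d[g] == 1:
            a_g[g] = d[g] / S0[s[g]]
            b_g[g] = d[g] * S1[s[g]] / S0[s[g]] ** 2
            xbar_g[g] = S1[s[g]] / S0[s[g]]
        else:
            w0 = w[members].sum()
            w1 = (w[members, None] * data.X[members]).sum(axis=0)
            aa, bb, xb = 0.0, np.zeros(p), np.zeros(p)
            for l in range(d[g]):
                phi = l / d[g]
                s0l = S0[s[g]] - phi * w0
                s1l = S1[s[g]] - phi * w1
                aa += 1.0 / s0l
                bb += s1l / s0l ** 2
                xb += s1l / s0l
            a_g[g], b_g[g], xbar_g[g] = aa, bb, xb / d[g]
    A = np.concatenate([[0.0], np.cumsum(a_g)])
    B = np.vstack([np.zeros(p), np.cumsum(b_g, axis=0)])
    k = np.searchsorted(data.group_time, data.time, side="right")
    resid = -w[:, None] * (data.X * A[k][:, None] - B[k])
    ev_idx = np.flatnonzero(data.event)
    grp_of_event = np.searchsorted(data.group_time, data.time[ev_idx])
    resid[ev_idx] += data.X[ev_idx] - xbar_g[grp_of_event]
    return resid


# ----------------------------------------------------------------------
# Public fitting API
# ----------------------------------------------------------------------

def fit_cox_arrays(time: np.ndarray, event: np.ndarray, X: np.ndarray,
                   terms: Sequence[str], clusters: np.ndarray | None = None,
                   ties: str = "breslow", tol: float = 1e-9,
                   max_iter: int = 100) -> CoxFit:
    """Fit the Cox model on raw arrays; see :func:`fit_cox`."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    terms = list(terms)
    if ties not in ("breslow", "efron"):
        raise ValueError(f"unknown ties method {ties!r}")
    if event.sum() < 1:
        raise ValueError("no events in the data")
    if np.any(time <= 0):
        raise ValueError("follow-up times must be positive")
    sds = X.std(axis=0)
    for j, sd in enumerate(sds):
        if sd == 0.0:
            raise RankDeficiencyError(
                f"covariate {terms[j]!r} is constant; drop it from the model")
    if clusters is None:
        clusters = np.arange(len(time))
    clusters = np.asarray(clusters)

    data = _CoxData(time, event, X, clusters)
    beta, converged, diagnostic, ll, score_norm = _newton(data, ties, tol, max_iter)

    _, U, I, *_ = _loglik_derivs(data, beta, ties)
    try:
        cov_model = np.linalg.inv(I)
    except np.linalg.LinAlgError as exc:
        raise RankDeficiencyError(
            "information matrix singular at the optimum; collinear covariates?"
        ) from exc
    resid = _score_residuals(data, beta, ties)
    codes, _ = pd.factorize(data.clusters)
    Gmat = np.zeros((codes.max() + 1, data.p))
    np.add.at(Gmat, codes, resid)
    meat = Gmat.T @ Gmat
    cov_robust = cov_model @ meat @ cov_model

    se = np.sqrt(np.diag(cov_robust))
    z = np.divide(beta, se, out=np.zeros_like(beta), where=se > 0)
    pvals = 2.0 * norm.sf(np.abs(z))
    fit = CoxFit(
        terms=terms, beta=beta, cov_model=cov_model, cov_robust=cov_robust,
        hr=np.exp(beta), ci_lo=np.exp(beta - Z975 * se),
        ci_hi=np.exp(beta + Z975 * se), p=pvals, se_robust=se,
        n=data.n, n_events=int(event.sum()), converged=converged,
        ties_method=ties, loglik=ll, score_norm=score_norm,
        diagnostic=diagnostic,
    )
    fit._state = {"data": data}
    return fit


def fit_cox(cohort: pd.DataFrame, terms: Sequence[str],
            cluster_by: str | None = "pedigree_id",
            duration_col: str = "time_y", event_col: str = "event",
            ties: str = "breslow") -> CoxFit:
    """Fit a family-clustered Cox model on a cohort table.

    ``terms`` are covariate column names (the carrier indicator included);
    ``cluster_by`` names the grouping column for the sandwich variance
    (``None`` treats every subject as its own cluster, which reproduces the
    ordinary robust variance exactly).
    """
    X = cohort[list(terms)].to_numpy(dtype=float)
    clusters = cohort[cluster_by].to_numpy() if cluster_by else None
    return fit_cox_arrays(cohort[duration_col].to_numpy(),
                          cohort[event_col].to_numpy(), X, terms,
                          clusters=clusters, ties=ties)


# ----------------------------------------------------------------------
# Supremum proportional-hazards diagnostic
# ----------------------------------------------------------------------

def supremum_ph_test(fit: CoxFit, n_replications: int = 1000,
                     seed: int | np.random.Generator | None = None) -> PHTestResult:
    """Kolmogorov-type supremum test on the cumulative score process.

    The observed statistic per term is the supremum over event times of the
    standardised cumulative score process; its null distribution is
    simulated with standard-normal multipliers on the per-event score
    increments, with the usual correction for the estimated coefficients
    (Lin-Wei-Ying style wild resampling).
    """
    if not fit.converged:
        raise ValueError("supremum test refuses a non-converged fit")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    data: _CoxData = fit._state["data"]
    _, _, _, w, S0, S1 = _loglik_derivs(data, fit.beta, fit.ties_method,
                                        want_derivs=False)
    s = data.group_start
    p = data.p
    # per-event increments x_i - xbar(t_i), ordered by event time
    ev_idx = np.flatnonzero(data.event)
    ev_order = np.argsort(data.time[ev_idx], kind="stable")
    ev_idx = ev_idx[ev_order]
    grp = np.searchsorted(data.group_time, data.time[ev_idx])
    xbar = S1[s] / S0[s][:, None]
    inc = data.X[ev_idx] - xbar[grp]           # (E, p)
    E = len(ev_idx)
    # cumulative information at each event, for the estimation correction
    wxx_s2 = _rev_cumsum((w[:, None, None] * data.X[:, :, None]
                          * data.X[:, None, :]).reshape(data.n, -1)
                         ).reshape(data.n, p, p)
    V_g = (wxx_s2[s] / S0[s][:, None, None]
           - xbar[:, :, None] * xbar[:, None, :])
    info_inc = V_g * data.group_d[:, None, None]
    Icum = np.cumsum(info_inc, axis=0)         # (G, p, p)
    Iinv = np.linalg.inv(Icum[-1])
    C = np.einsum("gij,jk->gik", Icum, Iinv)[grp]  # (E, p, p)

    scale = np.sqrt(np.diag(Icum[-1]))
    W_obs = np.cumsum(inc, axis=0)  # total score ~ 0 at the MLE
    sup_obs = np.max(np.abs(W_obs), axis=0) / scale

    # replicates in blocks to bound memory
    exceed = np.zeros(p, dtype=int)
    block = max(1, min(n_replications, int(2e7 // max(E * p, 1))))
    done = 0
    while done < n_replications:
        r = min(block, n_replications - done)
        G = rng.standard_normal((r, E))
        winc = G[:, :, None] * inc[None, :, :]
        Wstar = np.cumsum(winc, axis=1)
        total = winc.sum(axis=1)                    # (r, p)
        Wstar -= np.einsum("eij,rj->rei", C, total)
        sup_star = np.max(np.abs(Wstar), axis=1) / scale
        exceed += (sup_star >= sup_obs[None, :]).sum(axis=0)
        done += r
    pvals = (exceed + 1) / (n_replications + 1)
    return PHTestResult(terms=list(fit.terms), sup_statistic=sup_obs,
                        p=pvals, n_replications=n_replications)


# ----------------------------------------------------------------------
# Cumulative incidence
# ----------------------------------------------------------------------

def _km_incidence(time: np.ndarray, event: np.ndarray
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Product-limit cumulative incidence with Greenwood standard errors."""
    order = np.argsort(time, kind="stable")
    t, e = time[order], event[order]
    uniq = np.unique(t[e == 1])
    n = len(t)
    at_risk = n - np.searchsorted(t, uniq, side="left")
    d = np.array([int(((t == u) & (e == 1)).sum()) for u in uniq])
    surv = np.cumprod(1.0 - d / at_risk)
    greenwood = np.cumsum(d / (at_risk * (at_risk - d).clip(min=1)))
    se = surv * np.sqrt(greenwood)
    return uniq, 1.0 - surv, se


def cumulative_incidence(cohort: pd.DataFrame, group_by: str = "carrier",
                         adjust: Sequence[str] | None = None,
                         duration_col: str = "time_y", event_col: str = "event",
                         ) -> list[IncidenceCurve]:
    """Cumulative incidence per group.

    Unadjusted: one minus the Kaplan-Meier estimator with Greenwood
    standard errors.  Adjusted: per-group Cox fit on the adjustment
    covariates with a Breslow baseline, directly standardised by averaging
    the predicted incidence over the whole cohort's covariate distribution
    (the delta-method SE reflects baseline-hazard uncertainty only).
    """
    curves: list[IncidenceCurve] = []
    for value, sub in cohort.groupby(group_by, sort=True):
        if len(sub) == 0:
            continue
        label = f"{group_by}={value}"
        time = sub[duration_col].to_numpy(dtype=float)
        event = sub[event_col].to_numpy(dtype=int)
        if event.sum() == 0:
            tmax = float(time.max()) if len(time) else 0.0
            curves.append(IncidenceCurve(label, np.array([0.0, tmax]),
                                         np.zeros(2), np.zeros(2),
                                         adjusted=bool(adjust), zero_events=True))
            continue
        if not adjust:
            t, inc, se = _km_incidence(time, event)
            curves.append(IncidenceCurve(label, t, inc, se, adjusted=False))
            continue
        fit = fit_cox(sub, list(adjust), cluster_by=None,
                      duration_col=duration_col, event_col=event_col)
        data: _CoxData = fit._state["data"]
        # Breslow baseline and standardisation risks under one shared shift
        # (H0 * risk is invariant to the shift; raw S0 alone is not)
        eta_fit = data.X @ fit.beta
        shift = float(eta_fit.max())
        S0 = _rev_cumsum(np.exp(eta_fit - shift))
        s = data.group_start
        h0_inc = data.group_d / S0[s]
        H0 = np.cumsum(h0_inc)
        varH0 = np.cumsum(data.group_d / S0[s] ** 2)
        # standardise over the full cohort's covariate distribution
        Xall = cohort[list(adjust)].to_numpy(dtype=float)
        risk = np.exp(Xall @ fit.beta - shift)
        Smat = np.exp(-np.outer(H0, risk))       # (G, n_all)
        inc = 1.0 - Smat.mean(axis=1)
        dinc = (Smat * risk[None, :]).mean(axis=1)
        se = dinc * np.sqrt(varH0)
        curves.append(IncidenceCurve(label, data.group_time, inc, se,
                                     adjusted=True))
    return curves


# ----------------------------------------------------------------------
# Reporting
# ----------------------------------------------------------------------

def carrier_hr_report(fit: CoxFit, term: str = "carrier") -> dict:
    """Rounded and machine-precision HR (95% CI; p) for one model term."""
    j = fit.term_index(term)
    rec = {
        "term": term,
        "hr": float(fit.hr[j]),
        "ci_lo": float(fit.ci_lo[j]),
        "ci_hi": float(fit.ci_hi[j]),
        "p": float(fit.p[j]),
        "hr_rounded": round(float(fit.hr[j]), 2),
        "ci_lo_rounded": round(float(fit.ci_lo[j]), 2),
        "ci_hi_rounded": round(float(fit.ci_hi[j]), 2),
        "p_rounded": round(float(fit.p[j]), 3),
    }
    rec["formatted"] = (f"{rec['hr_rounded']:.2f} ({rec['ci_lo_rounded']:.2f}"
                        f"–{rec['ci_hi_rounded']:.2f}; p={rec['p_rounded']:.3f})")
    return rec
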