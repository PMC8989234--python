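"""Promoter-methylation discriminant analysis.

Pipeline: duplicate-measurement QC, rank-based inverse-normal
transformation per CpG site, risk standardisation (logistic response
residuals of case status on the covariates), PLS regression on the single
continuous adjusted outcome (NIPALS, PLS1), leave-one-out PRESS, van der
Voet sign-flip selection of the factor count, Wold VIP scores, and the
V-plot quadrant classification of the 16 sites.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

N_SITES = 16


# ----------------------------------------------------------------------
# QC and transformation
# ----------------------------------------------------------------------

def qc_duplicate_filter(dup1: float, dup2: float,
                        sd_threshold: float = 5.0) -> tuple[bool, float | None]:
    """Keep the mean of duplicate percent measurements unless their sample
    SD (|d1 - d2| / sqrt(2)) reaches the threshold (percentage points)."""
    for v in (dup1, dup2):
        if not (0.0 <= v <= 100.0):
            raise ValueError(f"measurement {v} outside [0, 100] percent")
    sd = abs(dup1 - dup2) / np.sqrt(2.0)
    if sd >= sd_threshold:
        return False, None
    return True, (dup1 + dup2) / 2.0


def rank_inverse_normal(values: np.ndarray, offset: float = 3.0 / 8.0
                        ) -> np.ndarray:
    """Rank-based inverse-normal transform, Blom offset by default.

    Ties receive average ranks; missing values propagate.  A constant
    vector maps to all zeros (with a degeneracy warning).
    """
    v = np.asarray(values, dtype=float)
    out = np.full(v.shape, np.nan)
    mask = ~np.isnan(v)
    x = v[mask]
    n = len(x)
    if n < 2:
        raise ValueError("need at least 2 non-missing values")
    if np.all(x == x[0]):
        warnings.warn("all values identical; transform degenerates to zeros",
                      RuntimeWarning)
        out[mask] = 0.0
        return out
    r = rankdata(x, method="average")
    out[mask] = norm.ppf((r - offset) / (n + 1.0 - 2.0 * offset))
    return out


# ----------------------------------------------------------------------
# Risk standardisation
# ----------------------------------------------------------------------

def adjusted_outcome(case: np.ndarray, covariates: pd.DataFrame
                     ) -> tuple[np.ndarray, str]:
    """Continuous standardised response for the PLS step.

    Case status is regressed on the covariates by logistic regression; the
    response residual (observed minus fitted probability) is centred and
    scaled to unit variance.  On separation or non-convergence the fit
    falls back to linear-probability residuals, with a warning.
    """
    import statsmodels.api as sm

    case = np.asarray(case, dtype=float)
    if case.sum() == 0 or case.sum() == len(case):
        raise ValueError("case status is constant; outcome not adjustable")
    X = sm.add_constant(covariates.to_numpy(dtype=float))
    method = "logistic"
    resid = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            model = sm.Logit(case, X).fit(disp=0, maxiter=200)
            fitted = model.predict(X)
            # reject only genuine separation: diverging coefficients or
            # fitted probabilities pinned to 0/1
            if (model.mle_retvals.get("converged", False)
                    and np.all(np.isfinite(model.params))
                    and np.max(np.abs(model.params)) < 1e3
                    and np.all(np.isfinite(fitted))
                    and fitted[case == 1].min() < 1.0 - 1e-8
                    and fitted[case == 0].max() > 1e-8):
                resid = case - fitted
        except Exception:
            resid = None
    if resid is None:
        warnings.warn("logistic adjustment failed (separation?); using "
                      "linear-probability residuals", RuntimeWarning)
        method = "linear"
        beta, *_ = np.linalg.lstsq(X, case, rcond=None)
        resid = case - X @ beta
    sd = resid.std(ddof=1)
    if sd < 1e-12:
        warnings.warn("residuals are degenerate (covariates fully determine "
                      "case status)", RuntimeWarning)
        return np.zeros_like(resid), method
    return (resid - resid.mean()) / sd, method


# ----------------------------------------------------------------------
# PLS core
# ----------------------------------------------------------------------

@dataclass
class PLSModel:
    x_mean: np.ndarray
    x_sd: np.ndarray
    y_mean: float
    y_sd: float
    weights: np.ndarray      # (p, A) w_a
    scores: np.ndarray       # (n, A) t_a
    x_loadings: np.ndarray   # (p, A) p_a
    y_loadings: np.ndarray   # (A,)   q_a
    x_variance_explained: np.ndarray  # percent per factor
    press_by_factors: np.ndarray | None = None
    selected_factors: int | None = None
    vdv_p_by_factors: np.ndarray | None = None
    vip: np.ndarray | None = None

    @property
    def a_max(self) -> int:
        return self.weights.shape[1]

    def coefficients(self, a: int) -> np.ndarray:
        """Standardised-scale regression coefficients using ``a`` factors."""
        W = self.weights[:, :a]
        P = self.x_loadings[:, :a]
        q = self.y_loadings[:a]
        return W @ np.linalg.solve(P.T @ W, q)

    def predict(self, X: np.ndarray, a: int) -> np.ndarray:
        Xs = (X - self.x_mean) / self.x_sd
        return self.y_mean + self.y_sd * (Xs @ self.coefficients(a))


def _nipals(Xs: np.ndarray, ys: np.ndarray, a_max: int):
    n, p = Xs.shape
    W = np.zeros((p, a_max))
    T = np.zeros((n, a_max))
    P = np.zeros((p, a_max))
    q = np.zeros(a_max)
    Xa, ya = Xs.copy(), ys.copy()
    total_ss = float((Xs ** 2).sum())
    xvar = np.zeros(a_max)
    used = 0
    for a in range(a_max):
        w = Xa.T @ ya
        nw = np.linalg.norm(w)
        if nw < 1e-12 * max(1.0, np.linalg.norm(ya)):
            break
        w /= nw
        t = Xa @ w
        tt = float(t @ t)
        if tt < 1e-24:
            break
        pl = Xa.T @ t / tt
        ql = float(ya @ t / tt)
        Xa = Xa - np.outer(t, pl)
        ya = ya - ql * t
        W[:, a], T[:, a], P[:, a], q[a] = w, t, pl, ql
        xvar[a] = 100.0 * tt * float(pl @ pl) / total_ss if total_ss > 0 else 0.0
        used = a + 1
    return W[:, :used], T[:, :used], P[:, :used], q[:used], xvar[:used]


def pls_fit(X: np.ndarray, y: np.ndarray, a_max: int = 8) -> PLSModel:
    """PLS1 regression of the adjusted outcome on column-standardised X."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n <= a_max:
        raise ValueError("need more subjects than factors")
    x_sd = X.std(axis=0, ddof=1)
    for j, sd in enumerate(x_sd):
        if sd < 1e-12:
            raise ValueError(f"methylation site {j + 1} is constant")
    x_mean = X.mean(axis=0)
    y_mean, y_sd = float(y.mean()), float(y.std(ddof=1))
    y_sd = y_sd if y_sd > 0 else 1.0
    Xs = (X - x_mean) / x_sd
    ys = (y - y_mean) / y_sd
    W, T, P, q, xvar = _nipals(Xs, ys, a_max)
    return PLSModel(x_mean=x_mean, x_sd=x_sd, y_mean=y_mean, y_sd=y_sd,
                    weights=W, scores=T, x_loadings=P, y_loadings=q,
                    x_variance_explained=xvar)


def press_cv(X: np.ndarray, y: np.ndarray, a_max: int = 8
             ) -> tuple[np.ndarray, np.ndarray]:
    """Leave-one-out PRESS for factor counts 0..a_max.

    Returns ``(press, sq_resid)`` where ``sq_resid[i, A]`` is subject i's
    squared held-out prediction residual with A factors (A = 0 uses the
    leave-one-out mean of y).  Standardisation is recomputed inside each
    training fold.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n <= a_max + 1:
        raise ValueError("too few subjects for leave-one-out PRESS")
    sq = np.zeros((n, a_max + 1))
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        Xtr, ytr = X[mask], y[mask]
        mu = ytr.mean()
        sq[i, 0] = (y[i] - mu) ** 2
        model = pls_fit(Xtr, ytr, a_max=a_max)
        xs = (X[i] - model.x_mean) / model.x_sd
        for a in range(1, a_max + 1):
            aa = min(a, model.a_max)
            pred = model.y_mean + model.y_sd * float(xs @ model.coefficients(aa))
            sq[i, a] = (y[i] - pred) ** 2
    return sq.sum(axis=0), sq


def vdv_select(sq_resid: np.ndarray, p_threshold: float = 0.10,
               n_randomizations: int = 2000,
               seed: int | np.random.Generator | None = None
               ) -> tuple[int, np.ndarray]:
    """van der Voet factor selection by sign-flip randomisation.

    For each candidate factor count A the statistic is the sum of paired
    differences between its squared cross-validation residuals and those of
    the PRESS-minimising count; the null is simulated by random sign flips.
    Returns the smallest A whose two-sided p exceeds ``p_threshold``, plus
    the p-value per candidate.
    """
    sq = np.asarray(sq_resid, dtype=float)
    n, n_cand = sq.shape
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    a_min = int(sq.sum(axis=0).argmin())
    flips = rng.choice([-1.0, 1.0], size=(n_randomizations, n))
    pvals = np.empty(n_cand)
    for a in range(n_cand):
        d = sq[:, a] - sq[:, a_min]
        t_obs = abs(d.sum())
        t_null = np.abs(flips @ d)
        pvals[a] = (np.sum(t_null >= t_obs - 1e-12) + 1) / (n_randomizations + 1)
    selected = int(np.flatnonzero(pvals > p_threshold)[0])
    return selected, pvals


def vip_scores(model: PLSModel, a: int | None = None) -> np.ndarray:
    """Wold's variable importance in projection with ``a`` factors.

    ``VIP_j = sqrt(p * sum_a SS_a (w_ja/||w_a||)^2 / sum_a SS_a)`` where
    ``SS_a = q_a^2 t_a't_a``; the squared scores sum to the predictor count.
    """
    if a is None:
        a = model.selected_factors or model.a_max
    a = max(1, min(a, model.a_max))
    W = model.weights[:, :a]
    T = model.scores[:, :a]
    q = model.y_loadings[:a]
    ss = q ** 2 * np.einsum("ia,ia->a", T, T)
    wnorm2 = (W ** 2).sum(axis=0)
    wnorm2[wnorm2 == 0] = 1.0
    p = W.shape[0]
    denom = ss.sum()
    if denom <= 0:
        return np.ones(p)
    return np.sqrt(p * (W ** 2 / wnorm2[None, :]) @ ss / denom)


# ----------------------------------------------------------------------
# V-plot and correlations
# ----------------------------------------------------------------------

@dataclass
class VPlotTable:
    site: np.ndarray          # 1..16
    vip: np.ndarray
    corr: np.ndarray          # raw Pearson correlation with adjusted outcome
    corr_rescaled: np.ndarray
    quadrant: list[str]
    vip_threshold: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "site": self.site, "vip": self.vip, "corr": self.corr,
            "corr_rescaled": self.corr_rescaled, "quadrant": self.quadrant,
        })


def v_plot(model: PLSModel, X: np.ndarray, y_adj: np.ndarray,
           vip_threshold: float = 1.1, a: int | None = None) -> VPlotTable:
    """VIP score against the centred/rescaled site-outcome correlation.

    Sites with VIP above the threshold land in the higher-risk quadrant
    when their rescaled correlation is positive and the lower-risk quadrant
    when negative; the rest are below threshold.
    """
    vip = vip_scores(model, a)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y_adj, dtype=float)
    corr = np.array([np.corrcoef(X[:, j], y)[0, 1] for j in range(X.shape[1])])
    sd = corr.std(ddof=0)
    rescaled = (corr - corr.mean()) / (sd if sd > 0 else 1.0)
    quad = []
    for v, c in zip(vip, rescaled):
        if v > vip_threshold and c > 0:
            quad.append("higher-risk")
        elif v > vip_threshold and c < 0:
            quad.append("lower-risk")
        else:
            quad.append("below-threshold")
    return VPlotTable(site=np.arange(1, X.shape[1] + 1), vip=vip, corr=corr,
                      corr_rescaled=rescaled, quadrant=quad,
                      vip_threshold=vip_threshold)


def correlation_matrix(X: np.ndarray | pd.DataFrame,
                       min_pairs: int = 3) -> pd.DataFrame:
    """Pairwise-complete Pearson matrix across the CpG columns."""
    df = pd.DataFrame(X)
    corr = df.corr(method="pearson", min_periods=min_pairs)
    np.fill_diagonal(corr.values, 1.0)
    return corr


# ----------------------------------------------------------------------
# Full pipeline
# ----------------------------------------------------------------------

@dataclass
class PLSDAResult:
    model: PLSModel
    y_adjusted: np.ndarray
    adjustment_method: str
    press: np.ndarray
    selected_factors: int
    vdv_p: np.ndarray
    vplot: VPlotTable
    correlations: pd.DataFrame
    n_subjects: int
    n_excluded_missing: int


def run_plsda(methylation: pd.DataFrame, case: np.ndarray,
              covariates: pd.DataFrame, a_max: int = 8,
              vip_threshold: float = 1.1, p_threshold: float = 0.10,
              n_randomizations: int = 2000,
              seed: int | None = None) -> PLSDAResult:
    """Transform, adjust, fit, select, score and classify in one call.

    ``methylation`` holds proportions (or percent; scale is irrelevant
    after the rank transform) for the 16 sites; subjects with any missing
    site are excluded.  The only stochastic step is the van der Voet
    sign-flip test, governed by ``seed``.
    """
    meth = pd.DataFrame(methylation)
    complete = ~meth.isna().any(axis=1)
    n_excluded = int((~complete).sum())
    meth = meth.loc[complete]
    case = np.asarray(case)[complete.to_numpy()]
    covs = covariates.loc[complete.to_numpy()] if isinstance(covariates, pd.DataFrame) \
        else pd.DataFrame(np.asarray(covariates)[complete.to_numpy()])

    Xt = np.column_stack([rank_inverse_normal(meth.iloc[:, j].to_numpy())
                          for j in range(meth.shape[1])])
    y, method = adjusted_outcome(case, covs)
    model = pls_fit(Xt, y, a_max=a_max)
    press, sq = press_cv(Xt, y, a_max=min(a_max, model.a_max))
    selected, vdv_p = vdv_select(sq, p_threshold=p_threshold,
                                 n_randomizations=n_randomizations, seed=seed)
    model.press_by_factors = press
    model.selected_factors = selected
    model.vdv_p_by_factors = vdv_p
    model.vip = vip_scores(model, max(selected, 1))
    vp = v_plot(model, Xt, y, vip_threshold=vip_threshold, a=max(selected, 1))
    return PLSDAResult(model=model, y_adjusted=y, adjustment_method=method,
                       press=press, selected_factors=selected, vdv_p=vdv_p,
                       vplot=vp, correlations=correlation_matrix(Xt),
                       n_subjects=len(y), n_excluded_missing=n_excluded)
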