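"""Resampling defenses around the family-clustered proportional-hazards fit.

Two procedures guard the carrier association against type-1 error:

* a carrier-label permutation null — carrier status is randomly reassigned
  to a fixed number of participants while outcomes and covariates stay
  untouched, and the fully adjusted clustered model is refitted each run;
* a case-exclusion bootstrap — k incident cases are removed at random,
  the model refitted, and the retention of significance and the spread of
  hazard-ratio estimates summarised.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from . import coxph
from .config import FULL_ADJUSTMENT


@dataclass
class PermutationResult:
    n_runs: int
    alpha: float
    n_below_alpha: int
    permutation_p: float
    per_run_p: np.ndarray
    n_failed: int
    seed: int | None


@dataclass
class CaseExclusionResult:
    alpha_keep: float
    per_k: dict[int, dict] = field(default_factory=dict)
    mean_hr: float = float("nan")
    mean_hr_ci: tuple[float, float] = (float("nan"), float("nan"))
    n_failed: int = 0
    seed: int | None = None


def _model_terms(adjust: Sequence[str] | None) -> list[str]:
    extra = FULL_ADJUSTMENT if adjust is None else list(adjust)
    return ["carrier", *extra]


def permutation_null(cohort: pd.DataFrame, n_carriers: int,
                     n_runs: int = 1000, alpha: float = 0.013,
                     seed: int | None = None,
                     adjust: Sequence[str] | None = None,
                     cluster_by: str = "pedigree_id") -> PermutationResult:
    """Carrier-label randomisation test conditional on everything else.

    Each run assigns pseudo-carrier status to a uniformly random subset of
    ``n_carriers`` participants, refits the fully adjusted clustered model,
    and records the carrier Wald p-value.  Returns the count below
    ``alpha`` and the smoothed permutation p-value
    ``(count + 1) / (runs + 1)``.
    """
    n = len(cohort)
    if not (0 < n_carriers < n):
        raise ValueError("n_carriers must be in (0, n)")
    rng = np.random.default_rng(seed)
    terms = _model_terms(adjust)
    work = cohort.copy()
    per_run = np.full(n_runs, np.nan)
    failed = 0
    for run in range(n_runs):
        idx = rng.choice(n, size=n_carriers, replace=False)
        pseudo = np.zeros(n, dtype=int)
        pseudo[idx] = 1
        work["carrier"] = pseudo
        try:
            fit = coxph.fit_cox(work, terms, cluster_by=cluster_by)
            if fit.converged:
                per_run[run] = fit.p[0]
            else:
                failed += 1
        except (coxph.RankDeficiencyError, np.linalg.LinAlgError):
            failed += 1
    ok = ~np.isnan(per_run)
    if failed > 0.01 * n_runs:
        warnings.warn(f"{failed} of {n_runs} permutation refits failed",
                      RuntimeWarning)
    n_ok = int(ok.sum())
    n_below = int((per_run[ok] < alpha).sum())
    return PermutationResult(
        n_runs=n_ok, alpha=alpha, n_below_alpha=n_below,
        permutation_p=(n_below + 1) / (n_ok + 1),
        per_run_p=per_run[ok], n_failed=failed, seed=seed,
    )


def case_exclusion_bootstrap(cohort: pd.DataFrame,
                             k_range: Sequence[int] = range(2, 10),
                             n_runs_per_k: int = 1000,
                             alpha_keep: float = 0.05,
                             seed: int | None = None,
                             adjust: Sequence[str] | None = None,
                             cluster_by: str = "pedigree_id",
                             ) -> CaseExclusionResult:
    """Refit the primary model after randomly deleting k incident cases.

    For each k, each run removes k uniformly chosen event subjects
    (non-cases are never touched) and records the carrier hazard ratio and
    Wald p.  Retention is the fraction of runs keeping ``p < alpha_keep``;
    the overall mean hazard ratio and its normal-theory 95% CI pool every
    run of every k.
    """
    k_range = list(k_range)
    event_idx = np.flatnonzero(cohort["event"].to_numpy() == 1)
    if k_range and max(k_range) >= len(event_idx):
        raise ValueError("k exceeds the number of events")
    rng = np.random.default_rng(seed)
    terms = _model_terms(adjust)
    result = CaseExclusionResult(alpha_keep=alpha_keep, seed=seed)
    all_hr: list[float] = []
    failed = 0
    for k in k_range:
        hrs = np.full(n_runs_per_k, np.nan)
        ps = np.full(n_runs_per_k, np.nan)
        for run in range(n_runs_per_k):
            if k == 0:
                sub = cohort
            else:
                drop = rng.choice(event_idx, size=k, replace=False)
                sub = cohort.drop(cohort.index[drop])
            try:
                fit = coxph.fit_cox(sub, terms, cluster_by=cluster_by)
            except (coxph.RankDeficiencyError, ValueError,
                    np.linalg.LinAlgError):
                failed += 1
                continue
            if not fit.converged:
                failed += 1
                continue
            hrs[run] = fit.hr[0]
            ps[run] = fit.p[0]
        ok = ~np.isnan(hrs)
        n_ok = int(ok.sum())
        result.per_k[k] = {
            "n_runs": n_ok,
            "retention": float((ps[ok] < alpha_keep).mean()) if n_ok else float("nan"),
            "hr": hrs[ok],
            "mean_hr": float(hrs[ok].mean()) if n_ok else float("nan"),
        }
        all_hr.extend(hrs[ok].tolist())
    if failed > 0.01 * max(1, len(k_range) * n_runs_per_k):
        warnings.warn(f"{failed} case-exclusion refits failed", RuntimeWarning)
    result.n_failed = failed
    if all_hr:
        arr = np.asarray(all_hr)
        m = float(arr.mean())
        sem = float(arr.std(ddof=1) / np.sqrt(len(arr))) if len(arr) > 1 else 0.0
        z = norm.ppf(0.975)
        result.mean_hr = m
        result.mean_hr_ci = (m - z * sem, m + z * sem)
    return result
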