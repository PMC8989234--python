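"""Genotype counting, allele frequencies, exact Hardy-Weinberg testing,
and the minor-homozygote / heterozygote pooling decision."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from . import coxph


@dataclass(frozen=True)
class GenotypeCounts:
    n_minor_hom: int  # TT
    n_het: int        # TG
    n_major_hom: int  # GG

    def __post_init__(self) -> None:
        if min(self.n_minor_hom, self.n_het, self.n_major_hom) < 0:
            raise ValueError("genotype counts must be non-negative")

    @property
    def total(self) -> int:
        return self.n_minor_hom + self.n_het + self.n_major_hom

    @classmethod
    def from_genotypes(cls, genotypes: Sequence[str]) -> "GenotypeCounts":
        s = pd.Series(genotypes)
        return cls(int((s == "TT").sum()), int((s == "TG").sum()),
                   int((s == "GG").sum()))


@dataclass(frozen=True)
class AlleleFrequencies:
    maf: float
    major_freq: float
    carrier_count: int
    carrier_fraction: float


def allele_frequencies(counts: GenotypeCounts) -> AlleleFrequencies:
    """Minor/major allele frequencies and the pooled carrier count."""
    n = counts.total
    if n == 0:
        raise ValueError("no genotyped subjects")
    maf = (2 * counts.n_minor_hom + counts.n_het) / (2 * n)
    carriers = counts.n_minor_hom + counts.n_het
    return AlleleFrequencies(maf=maf, major_freq=1.0 - maf,
                             carrier_count=carriers,
                             carrier_fraction=carriers / n)


def _log_het_prob(n: int, n_minor: int, n_het: int) -> float:
    """log P(heterozygote count | allele counts) under HWE random mating."""
    n_aa = (n_minor - n_het) // 2
    n_bb = n - n_aa - n_het
    return (gammaln(n + 1) - gammaln(n_aa + 1) - gammaln(n_het + 1)
            - gammaln(n_bb + 1) + n_het * np.log(2.0)
            - (gammaln(2 * n + 1) - gammaln(n_minor + 1)
               - gammaln(2 * n - n_minor + 1)))


def hwe_exact_test(counts: GenotypeCounts) -> float:
    """Two-sided exact Hardy-Weinberg test.

    Conditional on the observed allele counts, the p-value sums the
    probabilities of every heterozygote count whose conditional probability
    does not exceed that of the observed configuration.
    """
    n = counts.total
    if n == 0:
        raise ValueError("no genotyped subjects")
    n_minor = 2 * counts.n_minor_hom + counts.n_het
    if n_minor == 0 or n_minor == 2 * n:
        return 1.0  # monomorphic
    hets = np.arange(n_minor % 2, min(n_minor, 2 * n - n_minor) + 1, 2)
    logp = np.array([_log_het_prob(n, n_minor, int(h)) for h in hets])
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    obs = probs[np.flatnonzero(hets == counts.n_het)[0]]
    p = float(probs[probs <= obs * (1.0 + 1e-12)].sum())
    return min(p, 1.0)


@dataclass
class PoolingCheck:
    p_unadjusted: float | None
    p_adjusted: float | None
    pooled: bool
    forced: bool
    alpha: float
    note: str = ""


def pooling_check(cohort: pd.DataFrame, adjust: Sequence[str] = ("sex", "age_y"),
                  alpha: float = 0.05) -> PoolingCheck:
    """Decide whether minor-allele homozygotes and heterozygotes may be pooled.

    Fits the family-clustered proportional-hazards model on carriers only
    with a TT-vs-TG indicator, unadjusted and adjusted; pooling is declared
    when the smaller of the two Wald p-values is at least ``alpha``.  When
    the contrast is not estimable (a genotype class absent, or no events
    among carriers) pooling is forced and flagged.
    """
    carriers = cohort[cohort["genotype"].isin(["TT", "TG"])].copy()
    n_tt = int((carriers["genotype"] == "TT").sum())
    n_tg = int((carriers["genotype"] == "TG").sum())
    n_ev = int(carriers["event"].sum())
    if n_tt == 0 or n_tg == 0 or n_ev == 0:
        return PoolingCheck(None, None, pooled=True, forced=True, alpha=alpha,
                            note="TT-vs-TG contrast not estimable; pooling forced")
    carriers["tt"] = (carriers["genotype"] == "TT").astype(int)
    pvals = {}
    for key, terms in (("unadjusted", ["tt"]),
                       ("adjusted", ["tt", *adjust])):
        try:
            fit = coxph.fit_cox(carriers, terms)
            pvals[key] = float(fit.p[0]) if fit.converged else None
        except (coxph.RankDeficiencyError, ValueError):
            pvals[key] = None
    observed = [v for v in pvals.values() if v is not None]
    if not observed:
        return PoolingCheck(None, None, pooled=True, forced=True, alpha=alpha,
                            note="no TT-vs-TG fit converged; pooling forced")
    pooled = min(observed) >= alpha
    return PoolingCheck(pvals.get("unadjusted"), pvals.get("adjusted"),
                        pooled=pooled, forced=False, alpha=alpha)


def genotype_summary(cohort: pd.DataFrame, founders_only: bool = False) -> dict:
    """Counts, frequencies, HWE p-value and pooling decision for a cohort."""
    sub = cohort
    if founders_only:
        if "founder" not in cohort.columns:
            raise ValueError("cohort table has no founder column")
        sub = cohort[cohort["founder"] == 1]
    counts = GenotypeCounts.from_genotypes(sub["genotype"])
    freqs = allele_frequencies(counts)
    out = {
        "founders_only": founders_only,
        "n": counts.total,
        "counts": {"TT": counts.n_minor_hom, "TG": counts.n_het,
                   "GG": counts.n_major_hom},
        "maf": freqs.maf,
        "major_freq": freqs.major_freq,
        "carrier_count": freqs.carrier_count,
        "carrier_fraction": freqs.carrier_fraction,
        "hwe_p": hwe_exact_test(counts),
    }
    if {"event", "time_y"} <= set(cohort.columns):
        check = pooling_check(cohort)
        out["pooling"] = {
            "p_unadjusted": check.p_unadjusted,
            "p_adjusted": check.p_adjusted,
            "pooled": check.pooled,
            "forced": check.forced,
        }
    return out
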