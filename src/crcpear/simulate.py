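"""Synthetic family-structured cohort generator.

Produces cohorts that statistically emulate the study population every
downstream stage was designed for: pedigrees of realistic size, genotypes
drawn under Hardy-Weinberg equilibrium in founders and transmitted
Mendelian-fashion to descendants, baseline covariates with within-family
correlation, exponential event times calibrated to a target event count
under administrative censoring, and a 16-site promoter-methylation panel
generated from a two-latent-factor model with planted case effects.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .config import ConfigurationError, GeneratorConfig

GENOTYPE_LABELS = {0: "GG", 1: "TG", 2: "TT"}

COHORT_COLUMNS = [
    "id",
    "pedigree_id",
    "sex",
    "age_y",
    "bmi",
    "chol_total_mmol_l",
    "chol_hdl_mmol_l",
    "chol_ratio",
    "creat_umol_l",
    "gluc_mmol_l",
    "smoker",
    "drinker",
    "antiplatelet",
    "genotype",
    "event",
    "time_y",
    "founder",
]


@dataclass
class SimulatedCohort:
    """A generated cohort plus the ground truth that produced it."""

    cohort_table: pd.DataFrame
    methylation: pd.DataFrame  # proportions in [0, 1], index = participant id
    meth_meta: pd.DataFrame  # id, case, time_interval_y
    truth: dict


# ----------------------------------------------------------------------
# Pedigrees
# ----------------------------------------------------------------------

def _family_sizes(rng: np.random.Generator, n_families: int, total: int,
                  law: dict) -> np.ndarray:
    """Draw family sizes summing exactly to ``total`` (each >= min_size)."""
    if n_families == 0:
        if total:
            raise ConfigurationError("family members but no families")
        return np.zeros(0, dtype=int)
    min_size = int(law.get("min_size", 2))
    max_size = int(law.get("max_size", 30))
    mean = total / n_families
    if not (min_size <= mean <= max_size):
        raise ConfigurationError("family_size_law incompatible with totals")
    # truncated geometric: size = (min_size - 1) + Geom(p), capped at max_size
    p = min(1.0, 1.0 / max(mean - (min_size - 1), 1.0))
    sizes = (min_size - 1) + rng.geometric(p, size=n_families)
    sizes = np.clip(sizes, min_size, max_size)
    # deterministic fix-up to hit the exact total
    diff = total - int(sizes.sum())
    while diff != 0:
        i = int(rng.integers(n_families))
        if diff > 0 and sizes[i] < max_size:
            sizes[i] += 1
            diff -= 1
        elif diff < 0 and sizes[i] > min_size:
            sizes[i] -= 1
            diff += 1
    return sizes


def _build_family(rng: np.random.Generator, pedigree_id: int, size: int,
                  multi_generation: bool, next_id: int,
                  spouse_prob: float = 0.12) -> tuple[list[dict], int]:
    """Construct one family's member records.

    Single-generation families are sibships: the two parents exist only as
    latent genotype sources (``in_cohort`` False).  Multi-generation
    families start from an enrolled founder couple; children may marry in a
    founder spouse and have children of their own.
    """
    members: list[dict] = []

    def add(father: int, mother: int, founder: bool, in_cohort: bool, depth: int) -> int:
        nonlocal next_id
        rec = {
            "member_id": next_id,
            "pedigree_id": pedigree_id,
            "father_id": father,
            "mother_id": mother,
            "founder": founder,
            "in_cohort": in_cohort,
            "depth": depth,
        }
        members.append(rec)
        next_id += 1
        return rec["member_id"]

    if not multi_generation:
        pa = add(-1, -1, True, False, 0)
        ma = add(-1, -1, True, False, 0)
        for _ in range(size):
            add(pa, ma, False, True, 1)
        return members, next_id

    f1 = add(-1, -1, True, True, 0)
    f2 = add(-1, -1, True, True, 0)
    remaining = size - 2
    couples: list[tuple[int, int, int]] = [(f1, f2, 0)]  # father, mother, depth
    queue = [0]
    while remaining > 0:
        idx = queue.pop(0) if queue else int(rng.integers(len(couples)))
        pa, ma, depth = couples[idx]
        n_children = int(min(remaining, 1 + rng.poisson(1.2)))
        for _ in range(n_children):
            if remaining <= 0:
                break
            child = add(pa, ma, False, True, depth + 1)
            remaining -= 1
            if remaining >= 2 and rng.random() < spouse_prob:
                spouse = add(-1, -1, True, True, depth + 1)
                remaining -= 1
                couples.append((child, spouse, depth + 1))
                queue.append(len(couples) - 1)
    return members, next_id


def simulate_pedigrees(config: GeneratorConfig,
                       rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Assign every participant to a pedigree.

    Returns a table of members (including latent sibship parents, flagged
    ``in_cohort = False``) with parent links, founder flags, and the
    generation depth used to vectorise genotype transmission.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    total_family_members = config.n_participants - config.n_singletons
    sizes = _family_sizes(rng, config.n_families, total_family_members,
                          config.family_size_law)
    records: list[dict] = []
    next_id = 0
    # singletons first: pedigree ids 0 .. n_singletons-1
    for ped in range(config.n_singletons):
        records.append({
            "member_id": next_id, "pedigree_id": ped, "father_id": -1,
            "mother_id": -1, "founder": True, "in_cohort": True, "depth": 0,
        })
        next_id += 1
    n_single_gen = config.n_single_generation_families
    for j, size in enumerate(sizes):
        ped = config.n_singletons + j
        multi = j >= n_single_gen
        fam, next_id = _build_family(rng, ped, int(size), multi, next_id)
        records.extend(fam)
    df = pd.DataFrame.from_records(records)
    assert int(df["in_cohort"].sum()) == config.n_participants
    return df


# ----------------------------------------------------------------------
# Genotypes
# ----------------------------------------------------------------------

def simulate_genotypes(pedigrees: pd.DataFrame, maf: float,
                       rng: np.random.Generator | int | None = None) -> np.ndarray:
    """Minor-allele counts (0/1/2) for every member of the pedigree table.

    Founders are drawn from Hardy-Weinberg proportions at ``maf``;
    non-founders receive one allele from each parent.  Transmission is
    vectorised by generation depth (parents always have smaller depth).
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    n = len(pedigrees)
    geno = np.full(n, -1, dtype=int)
    member_pos = pd.Series(np.arange(n), index=pedigrees["member_id"].to_numpy())
    founder = pedigrees["founder"].to_numpy()
    geno[founder] = rng.binomial(2, maf, size=int(founder.sum()))
    depth = pedigrees["depth"].to_numpy()
    for d in range(1, int(depth.max()) + 1 if n else 0):
        mask = (depth == d) & ~founder
        if not mask.any():
            continue
        fa = member_pos[pedigrees.loc[mask, "father_id"].to_numpy()].to_numpy()
        mo = member_pos[pedigrees.loc[mask, "mother_id"].to_numpy()].to_numpy()
        if (geno[fa] < 0).any() or (geno[mo] < 0).any():
            raise ValueError("malformed pedigree: parent genotype not yet drawn")
        from_fa = rng.binomial(1, geno[fa] / 2.0)
        from_mo = rng.binomial(1, geno[mo] / 2.0)
        geno[mask] = from_fa + from_mo
    if (geno < 0).any():
        raise ValueError("malformed pedigree: unreachable members")
    return geno


# ----------------------------------------------------------------------
# Covariates
# ----------------------------------------------------------------------

def _correlated_normal(rng: np.random.Generator, fam_codes: np.ndarray,
                       n_fams: int, icc: float,
                       indiv: np.ndarray | None = None) -> np.ndarray:
    """Standard normal with intraclass correlation ``icc`` within families."""
    z_fam = rng.standard_normal(n_fams)[fam_codes]
    z_ind = rng.standard_normal(len(fam_codes)) if indiv is None else indiv
    return math.sqrt(icc) * z_fam + math.sqrt(1.0 - icc) * z_ind


def simulate_covariates(pedigrees: pd.DataFrame, config: GeneratorConfig,
                        rng: np.random.Generator | int | None = None) -> pd.DataFrame:
    """Baseline covariate panel for the in-cohort members.

    Continuous covariates are normal with the configured mean/SD, clipped
    at physiologic bounds; binary covariates follow a probit latent with
    the same family effect.  Total and HDL cholesterol share part of their
    individual variation so the total-to-HDL ratio behaves realistically.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    cohort = pedigrees[pedigrees["in_cohort"]]
    fam_codes, fams = pd.factorize(cohort["pedigree_id"])
    n = len(cohort)
    icc = config.family_icc
    out = pd.DataFrame(index=np.arange(n))

    # correlated cholesterol pair
    r = config.chol_total_hdl_corr
    z_hdl_ind = rng.standard_normal(n)
    z_tot_ind = r * z_hdl_ind + math.sqrt(1.0 - r * r) * rng.standard_normal(n)
    special_ind = {"chol_hdl_mmol_l": z_hdl_ind, "chol_total_mmol_l": z_tot_ind}

    for name, (mean, sd, lo, hi) in config.continuous_moments.items():
        z = _correlated_normal(rng, fam_codes, len(fams), icc,
                               indiv=special_ind.get(name))
        out[name] = np.clip(mean + sd * z, lo, hi)
    out["chol_ratio"] = out["chol_total_mmol_l"] / out["chol_hdl_mmol_l"]

    from scipy.stats import norm
    for name, prev in config.binary_prevalence.items():
        icc_b = 0.0 if name == "sex" else icc
        z = _correlated_normal(rng, fam_codes, len(fams), icc_b)
        out[name] = (z < norm.ppf(prev)).astype(int) if 0 < prev < 1 else np.full(n, int(prev >= 1))
    out.index = cohort["member_id"].to_numpy()
    return out


# ----------------------------------------------------------------------
# Survival
# ----------------------------------------------------------------------

def expected_events(baseline_rate: float, rel_hazard: np.ndarray,
                    censor_time: np.ndarray) -> float:
    """Expected number of observed events under exponential event times."""
    return float(np.sum(-np.expm1(-baseline_rate * rel_hazard * censor_time)))


def calibrate_baseline_rate(rel_hazard: np.ndarray, censor_time: np.ndarray,
                            target: float, tol: float = 1e-10) -> float:
    """Bisection for the baseline hazard giving ``target`` expected events."""
    if target > len(rel_hazard):
        raise ConfigurationError("target event count exceeds cohort size")
    lo, hi = 1e-12, 1.0
    while expected_events(hi, rel_hazard, censor_time) < target:
        hi *= 10.0
        if hi > 1e6:
            raise ConfigurationError("cannot reach target event count")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if expected_events(mid, rel_hazard, censor_time) < target:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol * hi:
            break
    return 0.5 * (lo + hi)


def simulate_survival(carrier: np.ndarray, covariates: pd.DataFrame,
                      config: GeneratorConfig,
                      rng: np.random.Generator | int | None = None,
                      ) -> tuple[np.ndarray, np.ndarray, float]:
    """Event indicator and follow-up time per participant.

    Event times are exponential with subject-specific rate
    ``baseline * exp(beta_carrier * carrier + covariate effects)``; the
    baseline is calibrated by bisection so the expected observed event
    count equals ``config.target_events`` given the drawn censoring times.
    Returns ``(event, time, baseline_rate)``.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    n = len(carrier)
    lp = config.true_log_hr_carrier * np.asarray(carrier, dtype=float)
    for name, beta in config.covariate_log_hr.items():
        if beta == 0.0 or name not in covariates:
            continue
        x = covariates[name].to_numpy(dtype=float)
        if name in config.continuous_moments:
            x = x - config.continuous_moments[name][0]
        elif name in config.binary_prevalence:
            x = x - config.binary_prevalence[name]
        lp = lp + beta * x
    rel_hazard = np.exp(lp)
    lo_c, hi_c = config.followup_range_y
    censor = rng.uniform(lo_c, hi_c, size=n)
    lam0 = calibrate_baseline_rate(rel_hazard, censor, config.target_events)
    event_time = rng.exponential(1.0, size=n) / (lam0 * rel_hazard)
    event = (event_time <= censor).astype(int)
    time = np.minimum(event_time, censor)
    time = np.maximum(time, 1e-6)
    return event, time, lam0


# ----------------------------------------------------------------------
# Methylation
# ----------------------------------------------------------------------

def _asymmetric_laplace(rng: np.random.Generator, n: int,
                        quartiles: tuple[float, float, float]) -> np.ndarray:
    """Samples with the given (Q1, median, Q3); each side is exponential."""
    q1, med, q3 = quartiles
    b_lo = (med - q1) / math.log(2.0)
    b_hi = (q3 - med) / math.log(2.0)
    upper = rng.random(n) < 0.5
    draw = np.where(upper,
                    rng.exponential(b_hi, size=n),
                    -rng.exponential(b_lo, size=n))
    return med + draw


def simulate_methylation(cohort: pd.DataFrame, config: GeneratorConfig,
                         rng: np.random.Generator | int | None = None,
                         ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """16-site methylation panel for a subset of the cohort.

    Latent two-factor model on the logit scale, mapped to proportions;
    case status (an observed event) shifts the planted sites by the signed
    effect times that site's total logit-scale SD.  Also draws the
    diagnosis/censoring-minus-measurement time interval per subject.
    Returns (methylation proportions indexed by id, meta table).
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    ids = cohort["id"].to_numpy()
    event = cohort["event"].to_numpy()
    case_ids = ids[event == 1]
    noncase_ids = ids[event == 0]
    n_cases = min(config.meth_case_n, len(case_ids))
    n_noncases = config.meth_subset_n - n_cases
    if n_noncases > len(noncase_ids):
        raise ConfigurationError("methylation subset larger than available non-cases")
    sel_cases = rng.choice(case_ids, size=n_cases, replace=False)
    sel_non = rng.choice(noncase_ids, size=n_noncases, replace=False)
    sel = np.concatenate([sel_cases, sel_non])
    sel.sort()
    case = pd.Series(0, index=ids).reindex(sel)
    case.loc[np.intersect1d(sel, sel_cases)] = 1
    case = case.to_numpy()

    m = len(sel)
    lam = config.meth_loadings
    sd_total = np.sqrt((lam ** 2).sum(axis=1) + config.meth_noise_sd ** 2)
    shift = np.zeros(16)
    for site, sign in config.planted_effects.items():
        shift[site - 1] = sign * config.planted_effect_sd * sd_total[site - 1]
    factors = rng.standard_normal((m, 2))
    noise = config.meth_noise_sd * rng.standard_normal((m, 16))
    logit = (config.meth_site_means[None, :] + factors @ lam.T + noise
             + np.outer(case, shift))
    meth = pd.DataFrame(expit(logit), index=sel,
                        columns=[f"cpg{j:02d}" for j in range(1, 17)])
    meth.index.name = "id"

    interval = np.empty(m)
    is_case = case == 1
    interval[is_case] = _asymmetric_laplace(rng, int(is_case.sum()),
                                            config.case_interval_quartiles)
    interval[~is_case] = _asymmetric_laplace(rng, int((~is_case).sum()),
                                             config.noncase_interval_quartiles)
    meta = pd.DataFrame({"id": sel, "case": case, "time_interval_y": interval})
    return meth, meta


# ----------------------------------------------------------------------
# Top-level
# ----------------------------------------------------------------------

def simulate_cohort(config: GeneratorConfig | None = None,
                    seed: int | None = None) -> SimulatedCohort:
    """Generate a complete cohort (pedigrees, genotypes, covariates,
    survival outcomes, methylation subset) from one seed."""
    if config is None:
        config = GeneratorConfig()
    if seed is not None:
        config = GeneratorConfig.from_dict({**config.to_dict(), "seed": seed})
    ss = np.random.SeedSequence(config.seed)
    r_ped, r_gen, r_cov, r_surv, r_meth = (np.random.default_rng(s)
                                           for s in ss.spawn(5))
    pedigrees = simulate_pedigrees(config, r_ped)
    geno_all = simulate_genotypes(pedigrees, config.maf, r_gen)
    in_cohort = pedigrees["in_cohort"].to_numpy()
    covs = simulate_covariates(pedigrees, config, r_cov)
    geno = geno_all[in_cohort]
    carrier = (geno >= 1).astype(int)
    event, time, lam0 = simulate_survival(carrier, covs, config, r_surv)

    cohort = pd.DataFrame({"id": pedigrees.loc[in_cohort, "member_id"].to_numpy()})
    cohort["pedigree_id"] = pedigrees.loc[in_cohort, "pedigree_id"].to_numpy()
    for col in covs.columns:
        cohort[col] = covs[col].to_numpy()
    cohort["genotype"] = [GENOTYPE_LABELS[g] for g in geno]
    cohort["event"] = event
    cohort["time_y"] = time
    cohort["founder"] = pedigrees.loc[in_cohort, "founder"].astype(int).to_numpy()
    cohort = cohort[COHORT_COLUMNS]

    meth, meta = simulate_methylation(cohort, config, r_meth)
    truth = {
        "true_log_hr_carrier": config.true_log_hr_carrier,
        "true_hr_carrier": math.exp(config.true_log_hr_carrier),
        "baseline_rate": lam0,
        "planted_sites_higher_risk": sorted(
            s for s, v in config.planted_effects.items() if v > 0),
        "planted_sites_lower_risk": sorted(
            s for s, v in config.planted_effects.items() if v < 0),
        "n_events": int(event.sum()),
        "seed": config.seed,
    }
    return SimulatedCohort(cohort_table=cohort, methylation=meth,
                           meth_meta=meta, truth=truth)


def add_carrier_column(cohort: pd.DataFrame) -> pd.DataFrame:
    """Derive the 0/1 minor-allele carrier indicator from the genotype."""
    cohort = cohort.copy()
    cohort["carrier"] = cohort["genotype"].isin(["TT", "TG"]).astype(int)
    return cohort


def write_simulation(sim: SimulatedCohort, prefix: str) -> None:
    """Write cohort.tsv, methylation.tsv (percent, 2 dp) and truth.json."""
    import os

    os.makedirs(prefix, exist_ok=True)
    sim.cohort_table.to_csv(os.path.join(prefix, "cohort.tsv"), sep="\t",
                            index=False, float_format="%.6g")
    meth_pct = (sim.methylation * 100.0).round(2).reset_index()
    meth_pct.to_csv(os.path.join(prefix, "methylation.tsv"), sep="\t", index=False)
    sim.meth_meta.to_csv(os.path.join(prefix, "methylation_meta.tsv"), sep="\t",
                         index=False, float_format="%.6g")
    with open(os.path.join(prefix, "truth.json"), "w") as fh:
        json.dump(sim.truth, fh, indent=2)


def read_cohort(path: str) -> pd.DataFrame:
    """Read a cohort TSV and derive the carrier indicator."""
    cohort = pd.read_csv(path, sep="\t")
    return add_carrier_column(cohort)
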