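"""End-to-end pipeline: simulate (optional) -> genotype statistics ->
clustered proportional-hazards fit -> resampling defenses -> methylation
PLS-DA -> descriptive comparisons, with a single JSON report."""

from __future__ import annotations

import json
import os
from typing import Any

import numpy as np
import pandas as pd

from . import coxph, descriptives, genetics, plsda, resampling
from .config import FULL_ADJUSTMENT, METHYLATION_ADJUSTMENT, GeneratorConfig
from .experiments import PRIMARY_TERMS, derive_seed
from .simulate import add_carrier_column, simulate_cohort, write_simulation


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def run_pipeline(config: dict | None = None,
                 out_dir: str | None = None) -> dict:
    """Execute every stage and return (and optionally write) the report.

    ``config`` is a flat mapping with optional per-stage sections:
    ``simulate`` (generator overrides, or ``cohort``/``methylation`` file
    paths to skip simulation), ``permute``, ``drop_cases``, ``plsda``.
    Every seed used is logged in the report; a rerun with the same config
    is byte-identical.
    """
    config = config or {}
    report: dict[str, Any] = {"config": _jsonable(config), "stages": []}
    seed = int(config.get("seed", 1))

    # ---- simulate or load -------------------------------------------
    sim_cfg = dict(config.get("simulate", {}))
    meth = meta = None
    try:
        if "cohort" in sim_cfg:
            cohort = add_carrier_column(pd.read_csv(sim_cfg["cohort"], sep="\t"))
            if "methylation" in sim_cfg:
                meth = pd.read_csv(sim_cfg["methylation"], sep="\t").set_index("id")
                if meth.to_numpy().max() > 1.5:
                    meth = meth / 100.0
                meta_path = sim_cfg.get("methylation_meta")
                if meta_path:
                    meta = pd.read_csv(meta_path, sep="\t")
            report["stages"].append("load")
        else:
            sim_cfg.setdefault("seed", derive_seed(seed, 0))
            gen = GeneratorConfig.from_dict(sim_cfg)
            sim = simulate_cohort(gen)
            cohort = add_carrier_column(sim.cohort_table)
            meth, meta = sim.methylation, sim.meth_meta
            report["simulate"] = {"seed": gen.seed, "truth": _jsonable(sim.truth)}
            report["stages"].append("simulate")
            if out_dir:
                write_simulation(sim, os.path.join(out_dir, "sim"))
    except Exception as exc:  # noqa: BLE001 - stage-named diagnostics
        raise StageError("simulate", exc) from exc

    # ---- genotype statistics ----------------------------------------
    try:
        report["geno"] = _jsonable(genetics.genotype_summary(cohort))
        if "founder" in cohort.columns:
            report["geno_founders"] = _jsonable(
                genetics.genotype_summary(cohort, founders_only=True))
        report["stages"].append("geno")
    except Exception as exc:
        raise StageError("geno", exc) from exc

    # ---- primary proportional-hazards fit ---------------------------
    try:
        fit = coxph.fit_cox(cohort, PRIMARY_TERMS, cluster_by="pedigree_id")
        report["cox"] = {
            "terms": fit.terms,
            "carrier": coxph.carrier_hr_report(fit),
            "n": fit.n, "n_events": fit.n_events,
            "converged": fit.converged,
        }
        ph = coxph.supremum_ph_test(fit, seed=derive_seed(seed, 10))
        report["cox"]["ph_test_p"] = _jsonable(dict(zip(ph.terms, ph.p)))
        report["stages"].append("cox")
    except Exception as exc:
        raise StageError("cox", exc) from exc

    # ---- resampling defenses ----------------------------------------
    perm_cfg = dict(config.get("permute", {}))
    try:
        res = resampling.permutation_null(
            cohort,
            n_carriers=int(perm_cfg.get("n_carriers", cohort["carrier"].sum())),
            n_runs=int(perm_cfg.get("runs", 1000)),
            alpha=float(perm_cfg.get("alpha", 0.013)),
            seed=int(perm_cfg.get("seed", derive_seed(seed, 20))))
        report["permute"] = {
            "n_runs": res.n_runs, "alpha": res.alpha,
            "n_below_alpha": res.n_below_alpha,
            "permutation_p": res.permutation_p,
        }
        report["stages"].append("permute")
    except Exception as exc:
        raise StageError("permute", exc) from exc

    drop_cfg = dict(config.get("drop_cases", {}))
    try:
        k_min = int(drop_cfg.get("k_min", 2))
        k_max = int(drop_cfg.get("k_max", 9))
        res = resampling.case_exclusion_bootstrap(
            cohort, k_range=range(k_min, k_max + 1),
            n_runs_per_k=int(drop_cfg.get("runs", 200)),
            alpha_keep=float(drop_cfg.get("alpha_keep", 0.05)),
            seed=int(drop_cfg.get("seed", derive_seed(seed, 30))))
        report["drop_cases"] = {
            "mean_hr": res.mean_hr, "mean_hr_ci": list(res.mean_hr_ci),
            "retention_by_k": {k: v["retention"] for k, v in res.per_k.items()},
        }
        report["stages"].append("drop_cases")
    except Exception as exc:
        raise StageError("drop_cases", exc) from exc

    # ---- methylation PLS-DA -----------------------------------------
    if meth is not None and meta is not None:
        pls_cfg = dict(config.get("plsda", {}))
        try:
            meta_idx = meta.set_index("id")
            covs = cohort.set_index("id").loc[
                meta_idx.index,
                [c for c in METHYLATION_ADJUSTMENT if c != "time_interval_y"]].copy()
            covs["time_interval_y"] = meta_idx["time_interval_y"]
            result = plsda.run_plsda(
                meth, meta_idx["case"].to_numpy(), covs,
                vip_threshold=float(pls_cfg.get("vip_threshold", 1.1)),
                seed=int(pls_cfg.get("seed", derive_seed(seed, 40))))
            table = result.vplot.to_frame()
            report["plsda"] = {
                "n_subjects": result.n_subjects,
                "selected_factors": result.selected_factors,
                "x_variance_explained": _jsonable(result.model.x_variance_explained),
                "vdv_p": _jsonable(result.vdv_p),
                "vplot": _jsonable(table.to_dict(orient="list")),
                "higher_risk_sites": table.loc[table["quadrant"] == "higher-risk",
                                               "site"].tolist(),
                "lower_risk_sites": table.loc[table["quadrant"] == "lower-risk",
                                              "site"].tolist(),
            }
            report["stages"].append("plsda")
            if out_dir:
                table.to_csv(os.path.join(out_dir, "vplot.tsv"), sep="\t",
                             index=False)
        except Exception as exc:
            raise StageError("plsda", exc) from exc
    else:
        report["plsda"] = "skipped (no methylation input)"

    # ---- descriptives ------------------------------------------------
    try:
        variables = [c for c in FULL_ADJUSTMENT]
        comps = descriptives.compare_groups(cohort, "carrier", variables)
        report["descriptives"] = [
            {"variable": c.variable, "kind": c.kind, "test": c.test, "p": c.p}
            for c in comps
        ]
        report["stages"].append("descriptives")
    except Exception as exc:
        raise StageError("descriptives", exc) from exc

    if out_dir:
        os.makedirs(out_dir, exist_ok=True)
        with open(os.path.join(out_dir, "report.json"), "w") as fh:
            json.dump(_jsonable(report), fh, indent=2)
    return report
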