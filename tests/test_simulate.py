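"""Structural and calibration checks on the synthetic cohort generator."""

import json

import numpy as np
import pandas as pd
import pytest

from crcpear.config import GeneratorConfig
from crcpear.simulate import (COHORT_COLUMNS, add_carrier_column,
                              calibrate_baseline_rate, expected_events,
                              read_cohort, simulate_cohort, simulate_pedigrees,
                              write_simulation)


def test_cohort_shape_and_columns(sim):
    table = sim.cohort_table
    assert list(table.columns) == COHORT_COLUMNS
    assert len(table) == 2532
    assert table["id"].is_unique


def test_family_structure(sim):
    table = sim.cohort_table
    sizes = table.groupby("pedigree_id").size()
    n_singletons = int((sizes == 1).sum())
    n_families = int((sizes >= 2).sum())
    assert n_singletons == 439
    assert n_families == 278
    assert sizes.sum() == 2532
    # family members (non-singletons) complement the singleton count
    assert sizes[sizes >= 2].sum() == 2532 - 439


def test_pedigree_depths():
    cfg = GeneratorConfig(seed=7)
    peds = simulate_pedigrees(cfg, np.random.default_rng(7))
    in_cohort = peds[peds["in_cohort"] == 1]
    assert len(in_cohort) == cfg.n_participants
    # founder flag is binary and some non-founders exist
    assert set(peds["founder"].unique()) <= {0, 1}
    assert (in_cohort["founder"] == 0).any()


def test_genotypes_and_carrier(sim):
    table = add_carrier_column(sim.cohort_table)
    assert set(table["genotype"].unique()) <= {"TT", "TG", "GG"}
    maf = (2 * (table["genotype"] == "TT").sum()
           + (table["genotype"] == "TG").sum()) / (2 * len(table))
    assert 0.06 < maf < 0.14
    assert (table["carrier"] == table["genotype"].isin(["TT", "TG"])).all()


def test_covariate_moments(sim):
    table = sim.cohort_table
    assert 40 < table["age_y"].mean() < 50
    assert 23 < table["bmi"].mean() < 29
    assert table[["sex", "smoker", "drinker", "antiplatelet"]].isin([0, 1]).all().all()
    assert (table["time_y"] > 0).all()
    # chol ratio is derived and positive
    assert (table["chol_ratio"] > 0).all()


def test_event_count_near_target(sim):
    n_events = int(sim.cohort_table["event"].sum())
    # target is 49; a single realisation should land within Poisson-ish range
    assert 25 <= n_events <= 80


def test_baseline_rate_calibration(rng):
    rel = np.exp(rng.normal(0, 0.3, size=500))
    censor = rng.uniform(8, 30, size=500)
    lam = calibrate_baseline_rate(rel, censor, target=40.0)
    assert expected_events(lam, rel, censor) == pytest.approx(40.0, abs=1e-6)


def test_methylation_panel(sim):
    meth, meta = sim.methylation, sim.meth_meta
    assert meth.shape == (929, 16)
    assert ((meth.to_numpy() > 0) & (meth.to_numpy() < 1)).all()
    assert len(meta) == 929
    assert int(meta["case"].sum()) == 16
    # diagnosis precedes measurement more often for cases than non-cases
    med_case = meta.loc[meta["case"] == 1, "time_interval_y"].median()
    med_non = meta.loc[meta["case"] == 0, "time_interval_y"].median()
    assert med_case < med_non


def test_truth_record(sim):
    truth = sim.truth
    assert truth["true_hr_carrier"] == pytest.approx(2.17)
    assert truth["planted_sites_higher_risk"] == [11, 12]
    assert truth["planted_sites_lower_risk"] == [2, 13]


def test_determinism_and_seed_sensitivity():
    a = simulate_cohort(GeneratorConfig(seed=99))
    b = simulate_cohort(GeneratorConfig(seed=99))
    c = simulate_cohort(GeneratorConfig(seed=100))
    pd.testing.assert_frame_equal(a.cohort_table, b.cohort_table)
    pd.testing.assert_frame_equal(a.methylation, b.methylation)
    assert not a.cohort_table.equals(c.cohort_table)


def test_write_read_round_trip(sim, tmp_path):
    prefix = tmp_path / "sim"
    write_simulation(sim, str(prefix))
    back = read_cohort(str(prefix / "cohort.tsv"))
    assert len(back) == len(sim.cohort_table)
    assert "carrier" in back.columns
    meth = pd.read_csv(prefix / "methylation.tsv", sep="\t")
    assert meth.shape[0] == 929
    with open(prefix / "truth.json") as fh:
        truth = json.load(fh)
    assert truth["seed"] == sim.truth["seed"]
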