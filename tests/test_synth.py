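import dataclasses
import filecmp

import numpy as np
import pandas as pd
import pytest

from cbrel.enrichment import write_gmt
from cbrel.io import read_brainspan, select_specimens
from cbrel.relative import drop_never_expressed, relative_z
from cbrel.synth import (
    InfeasibleCalibrationError,
    PlantedEffects,
    SimulationConfig,
    cerebellar_log_effect,
    calibrate_module_loading,
    module_profile_correlation,
    simulate,
    simulate_gmt,
    target_z_trajectory,
    write_simulation,
)

SMALL = SimulationConfig(
    n_donors=12,
    n_null_genes=60,
    n_positive_module=5,
    n_negative_module=5,
    n_sparse_donors=2,
    fraction_never_expressed=0.05,
    seed=3,
)
NO_EFFECTS = PlantedEffects(0.5, -0.5)


def test_identical_config_reproduces_files_byte_for_byte(tmp_path):
    for sub in ("a", "b"):
        ds, gt = simulate(SMALL, NO_EFFECTS)
        write_simulation(ds, gt, tmp_path / sub)
    for name in (
        "expression_matrix.csv",
        "rows_metadata.csv",
        "columns_metadata.csv",
        "ground_truth.txt",
    ):
        assert filecmp.cmp(tmp_path / "a" / name, tmp_path / "b" / name, shallow=False)


def test_different_seed_changes_values():
    ds1, _ = simulate(SMALL, NO_EFFECTS)
    ds2, _ = simulate(dataclasses.replace(SMALL, seed=4), NO_EFFECTS)
    assert not np.array_equal(ds1.values.to_numpy(), ds2.values.to_numpy())


def test_generated_values_are_non_negative_and_parse_back(tmp_path):
    ds, gt = simulate(SMALL, NO_EFFECTS)
    assert (ds.values.to_numpy() >= 0).all()
    paths = write_simulation(ds, gt, tmp_path)
    back = read_brainspan(paths["matrix"], paths["rows"], paths["columns"])
    pd.testing.assert_frame_equal(back.values, ds.values)


def test_never_expressed_bookkeeping_is_exactly_recovered():
    cfg = dataclasses.replace(SMALL, n_null_genes=500, fraction_never_expressed=0.04)
    ds, gt = simulate(cfg, NO_EFFECTS)
    _, dropped = drop_never_expressed(ds)
    assert sorted(dropped) == list(gt.never_expressed)
    assert len(gt.never_expressed) >= round(0.04 * 500)


def test_cohort_structure_matches_config():
    ds, gt = simulate(SMALL, NO_EFFECTS)
    assert len(ds.specimens) == SMALL.n_donors
    days = [sp.age.days_post_conception for sp in ds.specimens]
    assert all(40 <= d <= 15000 for d in days)
    assert days == sorted(days)  # donors ordered by age
    # one cerebellar structure at most, whole cerebellum for the youngest
    cb_labels = {
        sp.cerebellar_structure.acronym
        for sp in ds.specimens
        if sp.cerebellar_structure is not None
    }
    assert cb_labels <= {"CB", "CBC"}
    assert len(gt.sparse_donors) == SMALL.n_sparse_donors


def test_sparse_donors_usually_fail_inclusion():
    cfg = dataclasses.replace(SMALL, n_donors=30, n_sparse_donors=10, sparse_dropout=0.9)
    ds, gt = simulate(cfg, NO_EFFECTS)
    _, excluded = select_specimens(ds)
    assert {e.donor_id for e in excluded} >= set(gt.sparse_donors[:1])


def test_planted_z_floor_is_enforced():
    with pytest.raises(InfeasibleCalibrationError, match="floor"):
        cerebellar_log_effect(np.array([-50.0]), 0.25, 0.05)


def test_unreachable_trajectory_correlation_raises():
    # the z-estimation noise puts a ceiling on the age-z correlation no
    # slope can exceed
    from cbrel.synth import calibrate_phase1_slope

    noisy = dataclasses.replace(SMALL, region_noise_sd=0.6, noise_sd=0.5)
    with pytest.raises(InfeasibleCalibrationError, match="unreachable"):
        calibrate_phase1_slope(noisy, 0.999, n_mc=3000)


def test_module_loading_calibration_hits_requested_correlation():
    cfg = dataclasses.replace(SMALL, n_sparse_donors=0)
    a = calibrate_module_loading(cfg, 0.7, n_mc=8000)
    assert 0 < a < 1
    achieved = module_profile_correlation(a, cfg, n_mc=8000, seed=424242)
    assert achieved == pytest.approx(0.7, abs=0.05)


def test_trajectory_rises_then_falls():
    cfg = SMALL
    ages = np.array([56.0, 300.0, cfg.peak_age_days, 5000.0, 14890.0])
    z = target_z_trajectory(ages, cfg)
    assert z[0] == pytest.approx(cfg.z_start)
    assert np.all(np.diff(z[:3]) > 0)
    assert np.all(np.diff(z[2:]) < 0)


def test_planted_gmt_overlap_matches_fold_arithmetic(tmp_path):
    universe = [f"g{i}" for i in range(5000)]
    query = universe[:200]
    ann, tid = simulate_gmt(universe, query, 3.0, seed=9, term_size=50)
    members = ann.terms[tid][1]
    assert len(members) == 50
    assert len(members & set(query)) == round(3.0 * 50 * 200 / 5000)  # = 6
    out1, out2 = tmp_path / "a.gmt", tmp_path / "b.gmt"
    write_gmt(ann, out1)
    write_gmt(simulate_gmt(universe, query, 3.0, seed=9, term_size=50)[0], out2)
    assert filecmp.cmp(out1, out2, shallow=False)


def test_infeasible_gmt_fold_raises():
    universe = [f"g{i}" for i in range(100)]
    with pytest.raises(InfeasibleCalibrationError):
        simulate_gmt(universe, universe[:90], 10.0, seed=1, term_size=50)


def test_invalid_configs_rejected():
    with pytest.raises(ValueError):
        SimulationConfig(n_donors=0)
    with pytest.raises(ValueError):
        SimulationConfig(region_dropout=1.5)
    with pytest.raises(ValueError):
        SimulationConfig(r_mod=1.0)
    with pytest.raises(ValueError):
        SimulationConfig(cerebellar_region="XXX")


def test_planted_trajectory_visible_in_target_z():
    cfg = dataclasses.replace(
        SMALL, n_donors=30, n_sparse_donors=0, region_dropout=0.0, seed=11
    )
    ds, gt = simulate(cfg, NO_EFFECTS)
    included, _ = select_specimens(ds)
    zm = relative_z(included)
    z = zm.z.loc["ATM"]
    zeta = pd.Series(gt.target_zeta).loc[z.index]
    # realized z tracks the planted population trajectory
    assert z.corr(zeta) > 0.8
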