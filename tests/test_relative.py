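import numpy as np
import pandas as pd
import pytest

from cbrel.relative import (
    centile_benchmark,
    drop_never_expressed,
    midrank_centile,
    relative_z,
)
from conftest import build_dataset


def one_specimen_dataset(genes, cb_values, other_matrix, age="20 pcw"):
    """One donor with a cerebellum and one column per other-region value."""
    other_matrix = np.asarray(other_matrix, dtype=float)
    columns = [("D1", "CBC")] + [("D1", f"R{j}") for j in range(other_matrix.shape[1])]
    values = np.column_stack([np.asarray(cb_values, dtype=float), other_matrix])
    return build_dataset(genes, columns, values, {"D1": age})


def naive_z(cb, others):
    """Definition-level oracle: sample-SD z-score or None if degenerate."""
    others = [v for v in others if not np.isnan(v)]
    if np.isnan(cb) or len(others) < 2:
        return None
    m = sum(others) / len(others)
    sd = (sum((v - m) ** 2 for v in others) / (len(others) - 1)) ** 0.5
    if sd == 0:
        return None
    return (cb - m) / sd


def test_z_is_cerebellar_minus_mean_over_sample_sd():
    ds = one_specimen_dataset(["ATM"], [5.0], [[1.0, 2.0, 3.0]])
    zm = relative_z(ds)
    assert zm.z.loc["ATM", "D1"] == pytest.approx(3.0)
    assert zm.n_other_regions.loc["ATM", "D1"] == 3


def test_zero_spread_and_short_denominators_are_missing():
    ds = one_specimen_dataset(["FLAT", "OK"], [2.0, 5.0], [[2, 2, 2, 2], [1, 2, 3, 4]])
    zm = relative_z(ds)
    assert np.isnan(zm.z.loc["FLAT", "D1"])
    assert zm.n_other_regions.loc["FLAT", "D1"] == 0
    assert zm.n_degenerate == 1
    ds2 = one_specimen_dataset(["G"], [2.0], [[1.0, np.nan, np.nan]])
    assert np.isnan(relative_z(ds2).z.loc["G", "D1"])


def test_vectorised_z_matches_naive_oracle_on_100_gene_instance():
    rng = np.random.default_rng(11)
    n_genes, donors = 100, ["D1", "D2", "D3"]
    columns = [(d, s) for d in donors for s in ("CBC", "R0", "R1", "R2", "R3", "R4")]
    values = rng.lognormal(0, 1, (n_genes, len(columns)))
    values[rng.random(values.shape) < 0.1] = np.nan
    genes = [f"G{i}" for i in range(n_genes)]
    ds = build_dataset(
        genes, columns, values, {"D1": "10 pcw", "D2": "6 mos", "D3": "30 yrs"}
    )
    zm = relative_z(ds)
    for gi, g in enumerate(genes):
        for di, d in enumerate(donors):
            cols = values[gi, di * 6 : (di + 1) * 6]
            expect = naive_z(cols[0], cols[1:])
            got = zm.z.loc[g, d]
            if expect is None:
                assert np.isnan(got)
            else:
                assert got == pytest.approx(expect, rel=1e-12)


def test_z_invariant_to_specimen_scaling_and_region_order():
    rng = np.random.default_rng(5)
    values = rng.lognormal(0, 1, (20, 6))
    ds = one_specimen_dataset([f"G{i}" for i in range(20)], values[:, 0], values[:, 1:])
    base = relative_z(ds).z["D1"]
    scaled = one_specimen_dataset(
        [f"G{i}" for i in range(20)], 7.3 * values[:, 0], 7.3 * values[:, 1:]
    )
    pd.testing.assert_series_equal(relative_z(scaled).z["D1"], base)
    perm = rng.permutation(5)
    shuffled = one_specimen_dataset(
        [f"G{i}" for i in range(20)], values[:, 0], values[:, 1:][:, perm]
    )
    pd.testing.assert_series_equal(relative_z(shuffled).z["D1"], base)


def test_null_genes_have_near_zero_mean_z():
    # background genes i.i.d. across regions from one distribution at the
    # cohort's scale (15 regions, mild log-normal noise): the cerebellar
    # z is exchangeable, so its mean over many genes is close to 0
    rng = np.random.default_rng(42)
    n = 10_000
    values = rng.lognormal(0, 0.25, (n, 15))
    ds = one_specimen_dataset([f"G{i}" for i in range(n)], values[:, 0], values[:, 1:])
    assert abs(relative_z(ds).z["D1"].mean()) < 0.05


def test_drop_never_expressed_boundaries():
    ds = one_specimen_dataset(
        ["ZERO", "TINY", "MISSING_AND_ZERO"],
        [0.0, 0.0, np.nan],
        [[0, 0, 0], [0.001, 0, 0], [0, np.nan, 0]],
    )
    kept, dropped = drop_never_expressed(ds)
    assert kept.genes == ["TINY"]
    assert sorted(dropped) == ["MISSING_AND_ZERO", "ZERO"]


def test_midrank_centile_examples():
    assert midrank_centile(np.arange(99), 1000.0) == pytest.approx(100 * 99.0 / 99)
    assert midrank_centile(np.full(50, 2.0), 2.0) == pytest.approx(50.0)
    # 99 background genes below the target: midrank centile 99.5
    assert midrank_centile(np.arange(100), 99.0) == pytest.approx(99.5)


def sort_oracle_centile(background, value):
    """Independent midrank oracle via an explicit sorted scan."""
    s = sorted(background)
    below = sum(1 for v in s if v < value)
    ties = sum(1 for v in s if v == value)
    return 100.0 * (below + 0.5 * ties) / len(s)


def test_centile_benchmark_matches_sort_oracle():
    rng = np.random.default_rng(3)
    n = 500
    values = rng.lognormal(0, 1, (n, 7))
    values[rng.random(values.shape) < 0.05] = np.nan
    genes = ["ATM"] + [f"G{i}" for i in range(n - 1)]
    ds = one_specimen_dataset(genes, values[:, 0], values[:, 1:])
    zm = relative_z(ds)
    rep = centile_benchmark(zm, "ATM")
    bg = zm.z.drop(index="ATM")["D1"].dropna().to_numpy()
    t = zm.z.loc["ATM", "D1"]
    assert rep.loc[0, "centile"] == pytest.approx(sort_oracle_centile(bg, t))
    assert rep.loc[0, "n_background"] == bg.size
    assert rep.loc[0, "p95"] == pytest.approx(np.percentile(bg, 95))


def test_centile_consistent_with_background_quantiles():
    rng = np.random.default_rng(9)
    values = rng.lognormal(0, 1, (400, 8))
    genes = ["ATM"] + [f"G{i}" for i in range(399)]
    ds = one_specimen_dataset(genes, values[:, 0], values[:, 1:])
    rep = centile_benchmark(relative_z(ds), "ATM").iloc[0]
    assert (rep.centile > 95) == (rep.target_z > rep.p95)
    assert (rep.centile < 5) == (rep.target_z < rep.p5)


def test_missing_target_gene_raises(four_region_dataset):
    zm = relative_z(four_region_dataset)
    with pytest.raises(KeyError):
        centile_benchmark(zm, "NOT_A_GENE")
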