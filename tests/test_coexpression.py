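import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cbrel.ages import parse_age
from cbrel.coexpression import build_sets, correlate_all, filter_genes
from cbrel.relative import RelativeZMatrix, relative_z
from conftest import build_dataset


def zm_from_matrix(z, genes, donors, age="5 yrs"):
    z = pd.DataFrame(
        np.asarray(z, dtype=float), index=pd.Index(genes, name="gene"), columns=donors
    )
    n = z.notna().astype(int) * 5
    return RelativeZMatrix(z, n, {d: parse_age(age) for d in donors})


def uniform_age_dataset(genes, values, n_regions):
    columns = [("D1", "CBC")] + [("D1", f"R{j}") for j in range(n_regions)]
    return build_dataset(genes, columns, values, {"D1": "5 yrs"})


def test_quartile_threshold_drops_lowest_quarter_of_mean_expression():
    # 8 genes with means 1..8: linear-interpolation 25th percentile = 2.75
    values = np.tile(np.arange(1.0, 9.0)[:, None], (1, 5))
    ds = uniform_age_dataset([f"G{i}" for i in range(8)], values, 4)
    zm = relative_z(ds)
    retained, report = filter_genes(ds, zm, max_missing_z=5)
    assert report.quartile_threshold == pytest.approx(np.percentile(np.arange(1, 9), 25))
    assert report.n_low_expression_dropped == 2
    assert set(retained) == {f"G{i}" for i in range(2, 8)}


def test_gene_at_threshold_is_kept_strictly_below_dropped():
    means = [1.0, 2.0, 3.0, 4.0]  # 25th percentile = 1.75
    values = np.tile(np.array(means)[:, None], (1, 5))
    ds = uniform_age_dataset(["A", "B", "C", "D"], values, 4)
    retained, report = filter_genes(ds, relative_z(ds), max_missing_z=5)
    assert "A" not in retained and "B" in retained
    values2 = np.tile(np.array([1.75, 1.75, 1.75, 4.0])[:, None], (1, 5))
    ds2 = uniform_age_dataset(["A", "B", "C", "D"], values2, 4)
    retained2, _ = filter_genes(ds2, relative_z(ds2), max_missing_z=5)
    assert set(retained2) == {"A", "B", "C", "D"}  # equal to threshold: kept


def test_missingness_filter_boundary_at_five_of_thirty():
    donors = [f"D{i}" for i in range(30)]
    z = np.zeros((3, 30))
    z[1, :6] = np.nan  # 6 missing: dropped
    z[2, :5] = np.nan  # 5 missing: kept
    zm = zm_from_matrix(z, ["FULL", "SIX", "FIVE"], donors)
    columns = [(d, s) for d in donors for s in ("CBC", "R0")]
    ds = build_dataset(
        ["FULL", "SIX", "FIVE"], columns, np.ones((3, 60)), {d: "5 yrs" for d in donors}
    )
    retained, report = filter_genes(ds, zm, max_missing_z=5, apply_quartile_filter=False)
    assert set(retained) == {"FULL", "FIVE"}
    assert report.n_missingness_dropped == 1
    assert report.n_low_expression_dropped == 0


def test_filter_report_partitions_input():
    rng = np.random.default_rng(4)
    n = 200
    donors = [f"D{i}" for i in range(10)]
    values = rng.lognormal(0, 2, (n, 10 * 3))
    columns = [(d, s) for d in donors for s in ("CBC", "R0", "R1")]
    ds = build_dataset(
        [f"G{i}" for i in range(n)], columns, values, {d: "5 yrs" for d in donors}
    )
    zm = relative_z(ds)
    zm.z.iloc[:40, :7] = np.nan
    retained, rep = filter_genes(ds, zm, max_missing_z=5)
    assert rep.n_low_expression_dropped + rep.n_missingness_dropped + rep.n_retained == n
    assert rep.n_retained == len(retained)


def test_correlation_of_identical_and_negated_profiles():
    rng = np.random.default_rng(1)
    t = rng.normal(0, 1, 20)
    z = np.vstack([t, t, 2 * t.mean() - t])
    zm = zm_from_matrix(z, ["ATM", "SAME", "MIRROR"], [f"D{i}" for i in range(20)])
    ct = correlate_all(zm, "ATM", ["SAME", "MIRROR"])
    assert ct.loc["SAME", "r"] == pytest.approx(1.0)
    assert ct.loc["MIRROR", "r"] == pytest.approx(-1.0)
    assert "ATM" not in ct.index


def test_correlate_all_matches_naive_pairwise_loop():
    rng = np.random.default_rng(8)
    n_genes, n_donors = 100, 25
    z = rng.normal(0, 1, (n_genes + 1, n_donors))
    z[rng.random(z.shape) < 0.15] = np.nan
    genes = ["ATM"] + [f"G{i}" for i in range(n_genes)]
    zm = zm_from_matrix(z, genes, [f"D{i}" for i in range(n_donors)])
    ct = correlate_all(zm, "ATM", genes, min_pairs=3)
    t = z[0]
    for gi, g in enumerate(genes[1:], start=1):
        both = ~np.isnan(z[gi]) & ~np.isnan(t)
        n_pairs = int(both.sum())
        assert ct.loc[g, "n_pairs"] == n_pairs
        if n_pairs < 3:
            assert np.isnan(ct.loc[g, "r"])
        else:
            r, p = stats.pearsonr(z[gi][both], t[both])
            assert ct.loc[g, "r"] == pytest.approx(r, rel=1e-10, abs=1e-12)
            assert ct.loc[g, "p"] == pytest.approx(p, rel=1e-8, abs=1e-12)


def test_set_membership_is_strict_at_both_thresholds():
    ct = pd.DataFrame(
        {"n_pairs": [30] * 5, "r": [0.6, 0.61, -0.6, -0.61, np.nan],
         "p": [0.01] * 5},
        index=pd.Index(["AT", "IN_POS", "AT_NEG", "IN_NEG", "MISSING"], name="gene"),
    )
    sets = build_sets(ct)
    assert sets.positive == {"IN_POS"}
    assert sets.negative == {"IN_NEG"}


def test_raising_upper_threshold_never_grows_positive_set():
    rng = np.random.default_rng(12)
    ct = pd.DataFrame(
        {"n_pairs": 30, "r": rng.uniform(-1, 1, 500), "p": 0.5},
        index=pd.Index([f"G{i}" for i in range(500)], name="gene"),
    )
    sizes = [len(build_sets(ct, upper=u).positive) for u in (0.2, 0.4, 0.6, 0.8)]
    assert sizes == sorted(sizes, reverse=True)


def test_null_gene_tail_beyond_thresholds_matches_t_distribution():
    # population r = 0 at n pairs: P(|r| > 0.6) from the exact t transform
    rng = np.random.default_rng(99)
    n_genes, n_donors = 5000, 30
    z = rng.normal(0, 1, (n_genes + 1, n_donors))
    genes = ["ATM"] + [f"G{i}" for i in range(n_genes)]
    zm = zm_from_matrix(z, genes, [f"D{i}" for i in range(n_donors)])
    sets = build_sets(correlate_all(zm, "ATM", genes))
    df = n_donors - 2
    t_crit = 0.6 * np.sqrt(df / (1 - 0.36))
    p_tail = 2 * stats.t.sf(t_crit, df)  # two tails beyond +/-0.6
    observed = (len(sets.positive) + len(sets.negative)) / n_genes
    tol = 4 * np.sqrt(p_tail * (1 - p_tail) / n_genes)
    assert observed == pytest.approx(p_tail, abs=tol)
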