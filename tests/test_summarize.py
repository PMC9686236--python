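"""Lead selection, MAF/distance binning, Mood's test, concordance, null resampling."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from bloodeqtl.config import DataError
from bloodeqtl.summarize import (
    DISTANCE_BINS,
    directional_concordance,
    empirical_pvalue,
    jonckheere_trend_test,
    lncrna_adjacent_correlation,
    maf_bin_effect_table,
    mood_median_test,
    compare_r2_groups,
    partial_pearson,
    select_lead,
    select_leads,
    tss_distance_bins,
)

from conftest import make_expression


def _records(ps, betas=None, category="cis", gene="G1"):
    n = len(ps)
    betas = betas if betas is not None else np.ones(n)
    return pd.DataFrame({
        "variant_id": [f"v{i}" for i in range(n)],
        "gene_id": gene,
        "beta": betas,
        "se": 0.1,
        "t": 5.0,
        "p": ps,
        "log10_p": np.log10(ps),
        "r2": 0.1,
        "category": category,
        "tss_distance": 0.0,
        "eaf": 0.3,
    })


def test_select_lead_single_and_threshold():
    rec = _records([1e-9, 1e-3])
    lead = select_lead(rec, "cis", alpha=5e-8, seed=0)
    assert lead.record["variant_id"] == "v0"
    assert lead.n_tied == 1
    assert select_lead(_records([1e-3]), "cis", alpha=5e-8, seed=0) is None


def test_select_lead_tie_deterministic():
    rec = _records([1e-10, 1e-10, 1e-10])
    picks = {select_lead(rec, "cis", seed=7).record["variant_id"] for _ in range(5)}
    assert len(picks) == 1
    lead = select_lead(rec, "cis", seed=7)
    assert lead.n_tied == 3
    # order shuffling with the same tie set and seed gives the same variant id set size
    shuffled = rec.sample(frac=1.0, random_state=3).reset_index(drop=True)
    assert select_lead(shuffled, "cis", seed=7).n_tied == 3


def test_select_leads_one_row_per_gene():
    a = _records([1e-9, 1e-12], gene="G1")
    b = _records([1e-9], gene="G2")
    c = _records([1e-3], gene="G3")  # not significant
    leads = select_leads(pd.concat([a, b, c]), "cis", alpha=5e-8, seed=0)
    assert sorted(leads["gene_id"]) == ["G1", "G2"]
    assert leads.set_index("gene_id").loc["G1", "p"] == 1e-12


def test_maf_bins_quartiles_match_sort_oracle():
    rng = np.random.default_rng(0)
    n = 400
    leads = pd.DataFrame({
        "eaf": rng.uniform(0.004, 0.996, n),
        "beta": rng.normal(0, 2, n),
    })
    table, _ = maf_bin_effect_table(leads)
    maf = np.minimum(leads["eaf"], 1 - leads["eaf"])
    ab = np.abs(leads["beta"])
    from bloodeqtl.summarize import MAF_BINS

    for (label, lo, hi), row in zip(MAF_BINS, table.itertuples()):
        vals = np.sort(ab[(maf >= lo) & (maf < hi) & (maf > 0.003) & (maf < 0.5)])
        assert row.n == len(vals)
        if len(vals):
            assert row.median_abs_beta == pytest.approx(np.percentile(vals, 50))
            assert row.q1_abs_beta == pytest.approx(np.percentile(vals, 25))
            assert row.q3_abs_beta == pytest.approx(np.percentile(vals, 75))


def test_maf_bins_no_trend_when_flat():
    leads = pd.DataFrame({"eaf": np.linspace(0.005, 0.49, 200), "beta": 1.0})
    _, trend_p = maf_bin_effect_table(leads)
    assert trend_p >= 0.99


def test_maf_bins_detect_planted_rare_effect():
    """Monotone effect-size inflation toward rare bins is detected at n=500 leads."""
    rng = np.random.default_rng(1)
    n = 500
    # log-uniform MAF so every bin is populated
    maf = np.exp(rng.uniform(np.log(0.004), np.log(0.49), n))
    scale = np.select(
        [maf < 0.01, maf < 0.05, maf < 0.1], [4.0, 2.5, 1.5], default=1.0
    )
    leads = pd.DataFrame({"eaf": maf, "beta": np.abs(rng.normal(0, 1, n)) * scale})
    _, trend_p = maf_bin_effect_table(leads)
    assert trend_p < 0.001


def test_maf_bins_empty_bin_row():
    leads = pd.DataFrame({"eaf": [0.2, 0.3], "beta": [1.0, 2.0]})
    table, _ = maf_bin_effect_table(leads)
    rare = table[table["bin"] == "(0.003, 0.01)"].iloc[0]
    assert rare["n"] == 0 and np.isnan(rare["median_abs_beta"])


def test_mood_median_hand_example():
    stat, p = mood_median_test([1, 2, 3, 4], [10, 11, 12, 13])
    assert stat == pytest.approx(8.0)
    assert p == pytest.approx(0.00468, abs=5e-5)


def test_mood_median_identical_samples_and_degenerate():
    x = np.array([1.0, 2.0, 3.0, 4.0])
    _, p = mood_median_test(x, x)
    assert p == pytest.approx(1.0)
    _, p = mood_median_test(np.ones(5), np.ones(7))
    assert p == 1.0


def test_mood_median_monotone_invariance():
    rng = np.random.default_rng(2)
    x, y = rng.normal(0, 1, 30), rng.normal(0.8, 1, 40)
    s1, p1 = mood_median_test(x, y)
    s2, p2 = mood_median_test(np.exp(x), np.exp(y))
    assert s1 == pytest.approx(s2) and p1 == pytest.approx(p2)


def test_mood_median_matches_scipy():
    rng = np.random.default_rng(3)
    x, y = rng.normal(0, 1, 51), rng.normal(0.5, 1.2, 47)
    stat, p = mood_median_test(x, y)
    res = stats.median_test(x, y, ties="below", correction=False)
    assert stat == pytest.approx(res.statistic, rel=1e-10)
    assert p == pytest.approx(res.pvalue, rel=1e-10)


def test_tss_distance_bins_all_zero_and_edges():
    leads = pd.DataFrame({"tss_distance": [0.0, 0.0, 100_000.0, -100_000.0]})
    table = tss_distance_bins(leads)
    assert table["proportion"].sum() == pytest.approx(1.0, abs=1e-12)
    assert table.iloc[0]["n"] == 4  # 100kb edge falls in the first bin
    leads2 = pd.DataFrame({"tss_distance": [100_001.0]})
    assert tss_distance_bins(leads2).iloc[1]["n"] == 1


def test_tss_distance_bins_uniform_proportions():
    rng = np.random.default_rng(4)
    d = rng.uniform(0, 1_000_000, 5000)
    table = tss_distance_bins(pd.DataFrame({"tss_distance": d}))
    widths = np.array([hi - lo for _, lo, hi in DISTANCE_BINS]) / 1_000_000
    se = np.sqrt(widths * (1 - widths) / 5000)
    assert np.all(np.abs(table["proportion"].to_numpy() - widths) < 4 * se)


def test_tss_distance_bins_rejects_beyond_window():
    with pytest.raises(DataError, match="classification bug"):
        tss_distance_bins(pd.DataFrame({"tss_distance": [2_000_000.0]}))


def test_compare_r2_groups_shifted_distributions():
    rng = np.random.default_rng(5)
    n = 200
    leads = pd.DataFrame({
        "gene_id": [f"G{i}" for i in range(2 * n)],
        "category": ["cis"] * n + ["trans"] * n,
        "r2": np.concatenate([rng.beta(3, 20, n) + 0.05, rng.beta(3, 20, n)]),
    })
    ann = pd.DataFrame(
        {"biotype": ["protein_coding"] * 2 * n},
        index=pd.Index([f"G{i}" for i in range(2 * n)], name="gene_id"),
    )
    medians, contrasts = compare_r2_groups(leads, ann)
    row = contrasts.set_index("contrast").loc["cis_vs_trans"]
    assert row["p"] < 0.01
    # medians match a sort-based oracle
    cis_med = medians[(medians["category"] == "cis")]["median"].iloc[0]
    assert cis_med == pytest.approx(np.sort(leads[leads.category == "cis"]["r2"])[n // 2 - 1 : n // 2 + 1].mean())


def test_directional_concordance_self_negated_null():
    rng = np.random.default_rng(6)
    rec = pd.DataFrame({
        "variant_id": [f"v{i}" for i in range(300)],
        "gene_id": "G",
        "beta": rng.normal(0, 1, 300),
        "p": 1e-9,
    })
    n, same, prop = directional_concordance(rec, rec, 5e-8)
    assert (n, same, prop) == (300, 300, 1.0)
    neg = rec.assign(beta=-rec["beta"])
    assert directional_concordance(rec, neg, 5e-8)[2] == 0.0
    other = rec.assign(beta=rng.normal(0, 1, 300))
    prop_null = directional_concordance(rec, other, 5e-8)[2]
    assert abs(prop_null - 0.5) < 3 * np.sqrt(0.25 / 300)
    empty = rec.assign(p=1.0)
    assert np.isnan(directional_concordance(rec, empty, 5e-8)[2])


def test_partial_pearson_identical_and_plain():
    rng = np.random.default_rng(7)
    x = rng.normal(0, 1, 100)
    assert partial_pearson(x, x) == pytest.approx(1.0)
    y = rng.normal(0, 1, 100)
    r_plain = stats.pearsonr(x, y).statistic
    assert partial_pearson(x, y, design=None) == pytest.approx(r_plain, abs=1e-12)


def test_partial_pearson_removes_confounder():
    rng = np.random.default_rng(8)
    z = rng.normal(0, 1, 500)
    x = 2 * z + rng.normal(0, 0.5, 500)
    y = -3 * z + rng.normal(0, 0.5, 500)
    plain = partial_pearson(x, y)
    partial = partial_pearson(x, y, design=np.column_stack([np.ones(500), z]))
    assert abs(plain) > 0.8
    assert abs(partial) < 0.15  # null bound via Fisher z at n=500


def test_partial_pearson_zero_variance_raises():
    with pytest.raises(DataError, match="undefined"):
        partial_pearson(np.ones(10), np.arange(10.0))


def test_lncrna_adjacent_correlation_missing_gene():
    expr = make_expression(np.random.default_rng(0).standard_normal((30, 3)))
    with pytest.raises(DataError, match="GX"):
        lncrna_adjacent_correlation(expr, ("GX", "G0"))


def test_empirical_pvalue_smoothing_center_and_determinism():
    rng = np.random.default_rng(9)
    expr = make_expression(rng.standard_normal((80, 40)))
    p_big = empirical_pvalue(0.999, expr, n_genes_per_draw=20, n_iterations=50, seed=1)
    assert p_big == pytest.approx(1.0 / (50 * 10 + 1))
    p_null = empirical_pvalue(0.0, expr, n_genes_per_draw=20, n_iterations=50, seed=1)
    assert p_null > 0.9
    assert empirical_pvalue(0.2, expr, n_genes_per_draw=20, n_iterations=50, seed=2) == \
        empirical_pvalue(0.2, expr, n_genes_per_draw=20, n_iterations=50, seed=2)


def test_empirical_pvalue_bad_iterations():
    expr = make_expression(np.random.default_rng(0).standard_normal((20, 10)))
    from bloodeqtl.config import ConfigurationError

    with pytest.raises(ConfigurationError):
        empirical_pvalue(0.1, expr, n_iterations=0)


def test_jonckheere_needs_two_groups():
    with pytest.raises(DataError):
        jonckheere_trend_test([np.array([1.0, 2.0])])
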