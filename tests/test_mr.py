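"""Two-sample MR: instrument selection, harmonization, four estimators."""

import numpy as np
import pandas as pd
import pytest

from bloodeqtl.config import DataError
from bloodeqtl.mr import (
    InstrumentSet,
    harmonize,
    mr_egger,
    mr_for_genes,
    mr_ivw,
    mr_mode,
    mr_weighted_median,
    select_instruments,
    weighted_median,
)

from conftest import make_genotypes


def iv_set(gamma, Gamma, se_Gamma, se_gamma=None, gene="G"):
    gamma = np.asarray(gamma, dtype=float)
    se_gamma = np.full_like(gamma, 0.01) if se_gamma is None else np.asarray(se_gamma, float)
    return InstrumentSet(gene, pd.DataFrame({
        "variant_id": [f"v{i}" for i in range(len(gamma))],
        "gamma": gamma,
        "se_gamma": se_gamma,
        "Gamma": np.asarray(Gamma, dtype=float),
        "se_Gamma": np.asarray(se_Gamma, dtype=float),
        "effect_allele": "A", "other_allele": "G", "eaf": 0.3,
    }))


def test_ivw_single_iv_is_wald_ratio():
    est = mr_ivw(iv_set([0.5], [0.15], [0.05]))
    assert est.beta == pytest.approx(0.30)
    assert est.se == pytest.approx(0.10)
    assert est.n_snps == 1


def test_ivw_identical_ratios_zero_heterogeneity():
    est = mr_ivw(iv_set([0.5, 1.0, 0.2], [0.15, 0.30, 0.06], [0.05, 0.04, 0.03]))
    assert est.beta == pytest.approx(0.3)
    assert est.Q == pytest.approx(0.0, abs=1e-20)
    assert est.Q_p == pytest.approx(1.0)


def test_ivw_drops_zero_gamma():
    est = mr_ivw(iv_set([0.5, 0.0], [0.15, 0.4], [0.05, 0.05]))
    assert est.n_snps == 1
    assert est.beta == pytest.approx(0.30)


def test_egger_two_point_exact_line():
    est = mr_egger(iv_set([0.5, 1.0], [0.2, 0.3], [0.05, 0.05]), min_instruments=2)
    assert est.beta == pytest.approx(0.2)
    assert est.egger_intercept == pytest.approx(0.1)


def test_egger_reorients_negative_gamma():
    base = iv_set([0.5, 1.0, 0.8], [0.2, 0.3, 0.26], [0.05, 0.05, 0.05])
    flipped = iv_set([0.5, -1.0, 0.8], [0.2, -0.3, 0.26], [0.05, 0.05, 0.05])
    a, b = mr_egger(base), mr_egger(flipped)
    assert a.beta == pytest.approx(b.beta)
    assert a.egger_intercept == pytest.approx(b.egger_intercept)


def test_estimators_scale_equivariant():
    rng = np.random.default_rng(0)
    J = 12
    gamma = rng.uniform(0.2, 0.6, J)
    se_G = rng.uniform(0.02, 0.05, J)
    Gamma = 0.3 * gamma + rng.normal(0, se_G)
    s1 = iv_set(gamma, Gamma, se_G)
    c = 2.5
    s2 = iv_set(gamma, c * Gamma, c * se_G)
    for f in (mr_ivw, mr_egger):
        e1, e2 = f(s1), f(s2)
        assert e2.beta == pytest.approx(c * e1.beta, rel=1e-10)
        assert e2.se == pytest.approx(c * e1.se, rel=1e-10)
    wm1 = mr_weighted_median(s1, n_boot=200, seed=5)
    wm2 = mr_weighted_median(s2, n_boot=200, seed=5)
    assert wm2.beta == pytest.approx(c * wm1.beta, rel=1e-10)


def test_allele_flip_invariance():
    rng = np.random.default_rng(1)
    J = 10
    gamma = rng.uniform(0.2, 0.6, J)
    se_G = np.full(J, 0.04)
    Gamma = 0.3 * gamma + rng.normal(0, se_G)
    flip = np.ones(J)
    flip[::2] = -1.0
    s1 = iv_set(gamma, Gamma, se_G)
    s2 = iv_set(gamma * flip, Gamma * flip, se_G)
    assert mr_ivw(s2).beta == pytest.approx(mr_ivw(s1).beta, rel=1e-12)
    assert mr_egger(s2).beta == pytest.approx(mr_egger(s1).beta, rel=1e-12)


def test_weighted_median_equal_ratios_and_interpolation():
    est = mr_weighted_median(iv_set([0.5, 1.0, 0.2, 0.4], [0.15, 0.30, 0.06, 0.12],
                                    [0.05, 0.08, 0.02, 0.05]), n_boot=200, seed=0)
    assert est.beta == pytest.approx(0.3, abs=1e-12)
    # midpoint convention on two points with equal weight
    assert weighted_median(np.array([0.0, 1.0]), np.array([1.0, 1.0])) == pytest.approx(0.5)


def test_weighted_median_bootstrap_seeded():
    s = iv_set([0.5, 1.0, 0.2, 0.7], [0.2, 0.28, 0.05, 0.22], [0.05, 0.08, 0.02, 0.06])
    a = mr_weighted_median(s, n_boot=300, seed=3)
    b = mr_weighted_median(s, n_boot=300, seed=3)
    assert a.se == b.se


def test_mode_cluster_and_degenerate():
    est = mr_mode(iv_set([1.0, 1.0, 1.0, 1.0], [0.3, 0.3, 0.3, 0.9],
                         [0.05, 0.05, 0.05, 0.05]), n_boot=200, seed=0)
    assert abs(est.beta - 0.3) < 0.1  # density-maximization oracle tolerance
    deg = mr_mode(iv_set([0.5, 1.0, 2.0], [0.15, 0.3, 0.6], [0.05, 0.05, 0.05]),
                  n_boot=100, seed=0)
    assert deg.beta == pytest.approx(0.3)


def test_minimum_instrument_counts():
    s2 = iv_set([0.5, 1.0], [0.2, 0.3], [0.05, 0.05])
    with pytest.raises(DataError):
        mr_egger(s2)
    with pytest.raises(DataError):
        mr_weighted_median(s2)
    with pytest.raises(DataError):
        mr_mode(s2)


def test_harmonize_flip_palindrome_mismatch():
    exposure = pd.DataFrame({
        "variant_id": ["v1", "v2", "v3", "v4"],
        "beta": [0.5, 0.4, 0.3, 0.2], "se": [0.05] * 4,
        "effect_allele": ["A", "A", "A", "A"],
        "other_allele": ["G", "T", "C", "T"],
        "eaf": [0.3, 0.50, 0.3, 0.10],
    })
    outcome = pd.DataFrame({
        "variant": ["v1", "v2", "v3", "v4"],
        "effect_allele": ["G", "A", "A", "A"],
        "other_allele": ["A", "T", "G", "T"],
        "beta": [0.2, 0.1, 0.1, 0.15], "se": [0.05] * 4,
    })
    s = harmonize("G", exposure, outcome)
    t = s.table.set_index("variant_id")
    assert t.loc["v1", "Gamma"] == pytest.approx(-0.2)  # flipped
    assert "v2" not in t.index  # palindromic, eaf 0.50
    assert "v3" not in t.index  # A/C vs A/G mismatch
    assert t.loc["v4", "Gamma"] == pytest.approx(0.15)  # palindromic but eaf 0.10
    assert set(s.dropped["variant_id"]) == {"v2", "v3"}


def _pruning_cohort():
    """Variants A, B, C with r2(A,B) ~ 0.5+, r2(A,C) and r2(B,C) small."""
    rng = np.random.default_rng(7)
    n = 400
    a = rng.binomial(2, 0.4, n).astype(float)
    b = a.copy()
    flip = rng.random(n) < 0.25
    b[flip] = rng.binomial(2, 0.4, flip.sum())
    c = rng.binomial(2, 0.4, n).astype(float)
    g = make_genotypes(np.column_stack([a, b, c]))
    r2ab = np.corrcoef(a, b)[0, 1] ** 2
    r2ac = np.corrcoef(a, c)[0, 1] ** 2
    r2bc = np.corrcoef(b, c)[0, 1] ** 2
    assert r2ab > 0.3 and r2ac < 0.1 and r2bc < 0.1
    return g


def test_greedy_pruning_keeps_best_of_correlated_pair():
    g = _pruning_cohort()
    records = pd.DataFrame({
        "variant_id": ["v0", "v1", "v2"],
        "gene_id": "G",
        "p": [1e-12, 1e-10, 1e-9],
        "log10_p": [-12.0, -10.0, -9.0],
        "beta": [0.5, 0.45, 0.2], "se": [0.05] * 3, "eaf": 0.4,
        "category": "cis",
    })
    outcome = pd.DataFrame({"variant": ["v0", "v1", "v2"]})
    kept = select_instruments(records, g, outcome, r2_threshold=0.1)
    assert sorted(kept["variant_id"]) == ["v0", "v2"]


def test_pruning_duplicates_keep_lower_p():
    rng = np.random.default_rng(8)
    a = rng.binomial(2, 0.3, 200).astype(float)
    g = make_genotypes(np.column_stack([a, a]))
    records = pd.DataFrame({
        "variant_id": ["v0", "v1"], "gene_id": "G",
        "p": [1e-8, 1e-15], "log10_p": [-8.0, -15.0],
        "beta": [0.3, 0.31], "se": [0.05] * 2, "eaf": 0.3, "category": "cis",
    })
    kept = select_instruments(records, g, pd.DataFrame({"variant": ["v0", "v1"]}), 0.1)
    assert list(kept["variant_id"]) == ["v1"]


def test_pruning_all_below_threshold_kept():
    rng = np.random.default_rng(9)
    g = make_genotypes(rng.binomial(2, 0.4, size=(500, 4)).astype(float))
    records = pd.DataFrame({
        "variant_id": [f"v{i}" for i in range(4)], "gene_id": "G",
        "p": [1e-9] * 4, "log10_p": [-9.0] * 4,
        "beta": 0.3, "se": 0.05, "eaf": 0.4, "category": "cis",
    })
    kept = select_instruments(records, g, pd.DataFrame({"variant": [f"v{i}" for i in range(4)]}), 0.1)
    assert len(kept) == 4


def test_weighted_median_robust_to_contamination():
    """30% invalid IVs with large pleiotropy: median stays near truth, IVW drifts."""
    rng = np.random.default_rng(10)
    J = 30
    gamma = rng.uniform(0.3, 0.6, J)
    se_G = np.full(J, 0.03)
    alpha = np.zeros(J)
    alpha[:9] = 0.4  # 30% invalid
    Gamma = 0.3 * gamma + alpha + rng.normal(0, se_G)
    s = iv_set(gamma, Gamma, se_G)
    wm = mr_weighted_median(s, n_boot=500, seed=1)
    ivw = mr_ivw(s)
    assert abs(wm.beta - 0.3) < 3 * wm.se
    assert abs(ivw.beta - 0.3) > abs(wm.beta - 0.3)


from hypothesis import given, settings
from hypothesis import strategies as st


@settings(derandomize=True, max_examples=50)
@given(
    st.lists(st.floats(min_value=-10, max_value=10), min_size=1, max_size=20),
    st.integers(min_value=0, max_value=2**31 - 1),
)
def test_weighted_median_bounded_by_extremes(values, wseed):
    """The weighted median always lies within [min, max] of the ratios."""
    v = np.asarray(values)
    w = np.random.default_rng(wseed).uniform(0.1, 5.0, len(v))
    m = weighted_median(v, w)
    assert v.min() - 1e-12 <= m <= v.max() + 1e-12


def test_mr_for_genes_threshold_arithmetic_and_empty():
    rng = np.random.default_rng(11)
    n = 300
    g_dos = rng.binomial(2, 0.4, size=(n, 6)).astype(float)
    g = make_genotypes(g_dos)
    records = pd.DataFrame({
        "variant_id": [f"v{i}" for i in range(6)],
        "gene_id": ["A"] * 3 + ["B"] * 3,
        "p": [1e-10] * 6, "log10_p": [-10.0] * 6,
        "beta": [0.5, 0.4, 0.45, 0.3, 0.35, 0.32], "se": [0.05] * 6,
        "eaf": 0.4, "category": "cis",
    })
    meta = pd.DataFrame({
        "variant_id": [f"v{i}" for i in range(6)],
        "effect_allele": "G", "other_allele": "A", "eaf": 0.4,
    })
    outcome = pd.DataFrame({
        "variant": [f"v{i}" for i in range(6)],
        "effect_allele": "G", "other_allele": "A",
        "beta": [0.15, 0.12, 0.14, 0.09, 0.11, 0.10], "se": [0.03] * 6,
    })
    table = mr_for_genes(["A", "B"], records, meta, g, outcome, seed=0, n_boot=100)
    assert set(table.loc[table["method"] == "IVW", "gene_id"]) == {"A", "B"}
    assert (table["n_genes_tested"] == 2).all()
    ivw_rows = table[table["method"] == "IVW"]
    for _, r in ivw_rows.iterrows():
        assert r["significant"] == (r["p"] < 0.05 / 2)
    # empty outcome overlap: empty table, no error
    empty = mr_for_genes(["A"], records, meta, g,
                         pd.DataFrame({"variant": ["zz"], "effect_allele": "G",
                                       "other_allele": "A", "beta": [0.1], "se": [0.1]}))
    assert len(empty) == 0
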