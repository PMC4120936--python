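"""ANOVA, Tukey, proportion tests and Spearman concordance."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from ethnoindices.core_data import ValidationError
from ethnoindices.datasets import published_index_totals
from ethnoindices.group_comparison import (arcsine_sqrt,
                                           category_proportion_test,
                                           index_anova_by_species,
                                           one_way_anova, significance_stars,
                                           spearman, tukey_hsd)


def test_arcsine_sqrt_values():
    assert arcsine_sqrt(0.0) == 0.0
    assert arcsine_sqrt(1.0) == pytest.approx(math.pi / 2)
    assert arcsine_sqrt(0.25) == pytest.approx(math.pi / 6)  # asin(1/2)
    assert round(arcsine_sqrt(0.25), 4) == 0.5236
    with pytest.raises(ValidationError):
        arcsine_sqrt(1.5)
    with pytest.raises(ValidationError):
        arcsine_sqrt(-0.1)


def test_anova_hand_decomposition():
    """Three shifted groups: SSB = 6, SSW = 6, F = (6/2)/(6/6) = 3."""
    y = [1, 2, 3, 2, 3, 4, 3, 4, 5]
    g = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
    res = one_way_anova(y, g)
    assert res.f_statistic == pytest.approx(3.0)
    assert (res.df_num, res.df_den) == (2, 6)
    assert res.p_value == pytest.approx(stats.f.sf(3.0, 2, 6))


def test_anova_design_dfs():
    rng = np.random.default_rng(0)
    y = rng.normal(size=40)
    g = ["f"] * 20 + ["m"] * 20
    res = one_way_anova(y, g)
    assert (res.df_num, res.df_den) == (1, 38)
    res4 = one_way_anova(y, ["a", "b", "c", "d"] * 10)
    assert (res4.df_num, res4.df_den) == (3, 36)


def test_anova_degenerate_cases():
    res = one_way_anova([1, 1, 2, 2], ["a", "a", "b", "b"])
    assert res.f_statistic == math.inf and res.p_value == 0.0
    flat = one_way_anova([2, 2, 2, 2], ["a", "a", "b", "b"])
    assert flat.degenerate and flat.p_value == 1.0
    same_means = one_way_anova([1, 3, 1, 3], ["a", "a", "b", "b"])
    assert same_means.f_statistic == 0.0
    with pytest.raises(ValidationError):
        one_way_anova([1, 2], ["a", "a"])


@given(st.integers(0, 2 ** 31 - 1), st.integers(2, 5))
@settings(max_examples=50, deadline=None)
def test_anova_matches_scipy_oracle(seed, k):
    """F agrees with scipy.stats.f_oneway to 1e-10 on random fixtures."""
    rng = np.random.default_rng(seed)
    sizes = rng.integers(2, 8, size=k)
    groups = [rng.normal(i * 0.3, 1.0, size=n) for i, n in enumerate(sizes)]
    y = np.concatenate(groups)
    g = np.repeat([f"g{i}" for i in range(k)], sizes)
    res = one_way_anova(y, g)
    f_ref, p_ref = stats.f_oneway(*groups)
    assert res.f_statistic == pytest.approx(f_ref, abs=1e-10, rel=1e-10)
    assert res.p_value == pytest.approx(p_ref, abs=1e-10)


def test_anova_type_I_error_rate():
    """Null type-I error at alpha = .05 within +-0.02 over 2000 sims."""
    rng = np.random.default_rng(7)
    n_sim, k, n = 2000, 4, 10
    rejections = 0
    crit = stats.f.isf(0.05, k - 1, k * n - k)
    for _ in range(n_sim):
        y = rng.normal(size=(k, n))
        grand = y.mean()
        ssb = n * ((y.mean(axis=1) - grand) ** 2).sum()
        ssw = ((y - y.mean(axis=1, keepdims=True)) ** 2).sum()
        f = (ssb / (k - 1)) / (ssw / (k * n - k))
        rejections += f > crit
    # sanity: the closed-form loop above is the same F our function computes
    res = one_way_anova(y.ravel(), np.repeat(list("abcd"), n))
    assert res.f_statistic == pytest.approx(f)
    assert abs(rejections / n_sim - 0.05) < 0.02


def test_tukey_two_groups_equals_t():
    """With two groups, Tukey's q = sqrt(2)|t| and p matches the range dist."""
    rng = np.random.default_rng(3)
    a, b = rng.normal(0, 1, 12), rng.normal(0.8, 1, 12)
    tuk = tukey_hsd(np.concatenate([a, b]),
                    ["a"] * 12 + ["b"] * 12)
    t, _ = stats.ttest_ind(a, b)
    q = math.sqrt(2) * abs(t)
    p_ref = stats.studentized_range.sf(q, 2, 22)
    assert tuk["p_adj"].iloc[0] == pytest.approx(p_ref, abs=1e-6)


def test_tukey_against_statsmodels_unbalanced():
    """Tukey-Kramer p-values match statsmodels on unbalanced groups."""
    rng = np.random.default_rng(11)
    sizes = {"no_young": 8, "no_old": 20, "temp": 6, "perm": 6}
    y, g = [], []
    for i, (lv, n) in enumerate(sizes.items()):
        y.extend(rng.normal(0.2 * i, 1.0, n))
        g.extend([lv] * n)
    ours = tukey_hsd(y, g).set_index(["group1", "group2"])
    ref = pairwise_tukeyhsd(np.array(y), np.array(g))
    for (g1, g2), p_ref in zip(ref._results_table.data[1:] and
                               [(r[0], r[1]) for r in
                                ref._results_table.data[1:]],
                               ref.pvalues):
        key = (g1, g2) if (g1, g2) in ours.index else (g2, g1)
        assert ours.loc[key, "p_adj"] == pytest.approx(p_ref, abs=1e-4)


def test_tukey_conservative_vs_pairwise_t(default_dataset):
    rng = np.random.default_rng(5)
    y = rng.normal(size=30)
    g = np.repeat(["a", "b", "c"], 10)
    tuk = tukey_hsd(y, g)
    for row in tuk.itertuples():
        a, b = y[g == row.group1], y[g == row.group2]
        _, p_t = stats.ttest_ind(a, b)
        assert row.p_adj >= p_t - 1e-12


@pytest.mark.parametrize("x1,n1,x2,n2,expected", [
    (10, 20, 5, 20, 2.667),   # pooled p = .375: (.5-.25)^2 scaled
    (20, 20, 0, 20, 40.0),    # all-or-nothing: n (p1-p2)^2 / (pbar qbar)
])
def test_proportion_chi2_hand_values(x1, n1, x2, n2, expected):
    res = category_proportion_test(x1, n1, x2, n2)
    assert res.statistic == pytest.approx(expected, abs=5e-4)
    assert res.df == 1
    assert res.p_value == pytest.approx(stats.chi2.sf(res.statistic, 1))


def test_proportion_test_properties():
    equal = category_proportion_test(6, 12, 3, 6)
    assert equal.statistic == 0.0 and equal.p_value == 1.0
    a = category_proportion_test(10, 20, 5, 20)
    b = category_proportion_test(5, 20, 10, 20)   # symmetric in group order
    assert a.statistic == pytest.approx(b.statistic)
    # relabelling successes/failures leaves chi-square unchanged
    c = category_proportion_test(10, 20, 15, 20)
    assert c.statistic == pytest.approx(a.statistic)
    with pytest.raises(ValidationError):
        category_proportion_test(5, 4, 1, 10)
    with pytest.raises(ValidationError):
        category_proportion_test(0, 0, 1, 10)


def test_proportion_exact_binomial_option():
    res = category_proportion_test(10, 20, 5, 20, exact=True)
    assert res.method == "exact_binomial"
    assert res.p_value == pytest.approx(
        stats.binomtest(10, 20, 0.25).pvalue)
    assert math.isnan(res.statistic)


def test_spearman_basics():
    x = [1.0, 2.0, 3.0, 4.0]
    assert spearman(x, x)[0] == pytest.approx(1.0)
    assert spearman(x, x[::-1])[0] == pytest.approx(-1.0)
    with pytest.raises(ValidationError):
        spearman([1, 2], [2, 1])
    with pytest.raises(ValidationError):
        spearman([1, 1, 1], [1, 2, 3])


@given(st.integers(0, 2 ** 31 - 1))
@settings(max_examples=30, deadline=None)
def test_spearman_monotone_invariance(seed):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=12)
    y = rng.normal(size=12)
    rho, _ = spearman(x, y)
    rho2, _ = spearman(np.exp(x), y ** 3 + 5 * y)
    assert rho2 == pytest.approx(rho, abs=1e-12)


def test_published_totals_concordance():
    """The two published index totals agree strongly in rank (rho ~ .81)."""
    tab = published_index_totals()
    rho, p = spearman(tab["composite_s"], tab["ci"])
    assert rho == pytest.approx(0.811, abs=0.005)
    assert p < 0.001


def test_stars():
    assert significance_stars(0.0005) == "***"
    assert significance_stars(0.005) == "**"
    assert significance_stars(0.03) == "*"
    assert significance_stars(0.3) == "ns"


def test_index_anova_driver(default_dataset):
    for index in ("salience", "ci"):
        results = index_anova_by_species(default_dataset, index, "sex")
        assert len(results) == 14
        for res in results:
            if not res.degenerate:
                assert res.df_num == 1
                assert 0 <= res.p_value <= 1
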