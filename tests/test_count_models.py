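"""Poisson / quasi-Poisson GLMs, dispersion, and stepwise simplification."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ethnoindices.core_data import ValidationError
from ethnoindices.count_models import (MAXIMAL_TERMS, ModelSpec,
                                       build_design, canonical_term,
                                       dispersion_check, drop_term_test,
                                       fit_poisson_glm, stepwise_backward)


def make_covariates(n, rng=None, ages=None):
    rng = rng or np.random.default_rng(0)
    return pd.DataFrame({
        "age": ages if ages is not None else rng.uniform(16, 80, n),
        "sex": rng.integers(0, 2, n).astype(float),
        "migrant": rng.integers(0, 2, n).astype(float),
    })


def test_intercept_only_is_log_mean():
    cov = make_covariates(3)
    res = fit_poisson_glm([1, 2, 3], cov, ModelSpec(terms=()))
    assert res.coef.loc["Intercept", "estimate"] == \
        pytest.approx(math.log(2.0), abs=1e-8)


def test_all_zero_counts_flagged_degenerate():
    cov = make_covariates(10)
    res = fit_poisson_glm([0] * 10, cov)
    assert res.degenerate and not res.converged
    assert res.coef["estimate"].isna().all()


def test_counts_validated():
    cov = make_covariates(4)
    with pytest.raises(ValidationError):
        fit_poisson_glm([1, 2, -1, 0], cov)
    with pytest.raises(ValidationError):
        fit_poisson_glm([1.5, 2, 1, 0], cov)


def test_design_matrix_and_marginality():
    cov = make_covariates(6)
    X, names = build_design(cov, MAXIMAL_TERMS)
    assert names[0] == "Intercept" and X.shape == (6, 7)
    np.testing.assert_allclose(X[:, 4],
                               cov["age"].to_numpy() * cov["sex"].to_numpy())
    assert canonical_term(("sex", "age")) == ("age", "sex")
    with pytest.raises(ValidationError):
        ModelSpec(terms=(("age", "sex"),))  # interaction without parents


def test_slope_recovery_single_fit():
    """A strong known age slope is recovered on one large simulation."""
    rng = np.random.default_rng(1)
    cov = make_covariates(2000, rng)
    eta = -1.0 + 0.02 * cov["age"].to_numpy()
    y = rng.poisson(np.exp(eta))
    res = fit_poisson_glm(y, cov, ModelSpec(terms=(("age",),)))
    assert res.coef.loc["age", "estimate"] == pytest.approx(0.02, abs=0.004)


def test_dispersion_simulations():
    """Equidispersed Poisson sits near 1; lognormal frailty blows it up."""
    rng = np.random.default_rng(2)
    n_rep, n = 100, 500
    spec = ModelSpec(terms=(("age",),))
    in_band = over = 0
    for _ in range(n_rep):
        cov = make_covariates(n, rng)
        lam = np.exp(1.5 + 0.005 * cov["age"].to_numpy())
        plain = fit_poisson_glm(rng.poisson(lam), cov, spec)
        in_band += 0.8 <= dispersion_check(plain)[0] <= 1.2
        frail = fit_poisson_glm(
            rng.poisson(lam * np.exp(rng.normal(0, 1, n))), cov, spec)
        disp, refit = dispersion_check(frail)
        over += refit and disp > 1.5
    assert in_band >= 0.9 * n_rep
    assert over >= 0.9 * n_rep


def test_saturated_model_rejected():
    cov = make_covariates(1)
    with pytest.raises(ValidationError):
        fit_poisson_glm([2], cov, ModelSpec(terms=()))  # 1 param, 1 obs


def test_quasi_scales_standard_errors():
    rng = np.random.default_rng(3)
    cov = make_covariates(120, rng)
    y = rng.poisson(np.exp(rng.normal(0.5, 1.0, 120)))  # overdispersed
    spec = ModelSpec(terms=(("age",), ("sex",)))
    plain = fit_poisson_glm(y, cov, spec)
    quasi = fit_poisson_glm(y, cov, ModelSpec(spec.terms, "quasipoisson"))
    ratio = quasi.coef["se"] / plain.coef["se"]
    np.testing.assert_allclose(ratio, math.sqrt(plain.dispersion), rtol=1e-9)
    np.testing.assert_allclose(quasi.coef["estimate"], plain.coef["estimate"])


def test_drop_term_test_basics():
    rng = np.random.default_rng(4)
    cov = make_covariates(80, rng)
    y = rng.poisson(1.5, 80)
    full = fit_poisson_glm(y, cov)
    assert drop_term_test(full, full) == (0.0, 0, 1.0)
    reduced = fit_poisson_glm(y, cov, ModelSpec(terms=(
        ("age",), ("sex",), ("migrant",))))
    stat, df, p = drop_term_test(full, reduced)
    assert df == 3  # three interaction dummies dropped
    assert stat >= 0
    with pytest.raises(ValidationError):
        drop_term_test(reduced, full)


def test_deviance_monotone_in_nesting():
    """Adding terms never increases the deviance."""
    rng = np.random.default_rng(5)
    cov = make_covariates(60, rng)
    y = rng.poisson(2.0, 60)
    ladders = [(), (("age",),), (("age",), ("sex",)),
               (("age",), ("sex",), ("age", "sex")), MAXIMAL_TERMS]
    devs = [fit_poisson_glm(y, cov, ModelSpec(terms=t)).deviance
            for t in ladders]
    assert all(a >= b - 1e-9 for a, b in zip(devs, devs[1:]))


def test_lrt_null_distribution_uniform():
    """Under the null the one-extra-parameter LRT p is uniform (KS)."""
    rng = np.random.default_rng(6)
    pvals = []
    for _ in range(1000):
        cov = make_covariates(50, rng)
        y = rng.poisson(2.0, 50)
        full = fit_poisson_glm(y, cov, ModelSpec(terms=(("age",),)))
        reduced = fit_poisson_glm(y, cov, ModelSpec(terms=()))
        pvals.append(drop_term_test(full, reduced)[2])
    assert stats.kstest(pvals, "uniform").pvalue > 0.01


def test_stepwise_marginality_and_log():
    """Interactions forced strong keep their parents in the final model."""
    rng = np.random.default_rng(7)
    cov = make_covariates(400, rng)
    eta = (-0.5 + 0.8 * cov["sex"].to_numpy() * cov["migrant"].to_numpy())
    y = rng.poisson(np.exp(eta))
    res = stepwise_backward(y, cov)
    if ("sex", "migrant") in res.terms:
        assert ("sex",) in res.terms and ("migrant",) in res.terms
    for entry in res.dropped:
        assert entry["p"] > 0.05


def test_stepwise_retains_strong_migration_effect():
    """A -1.0 migrant deficit always survives; spurious extras appear at
    roughly the per-term type-I rate, so migrant-only dominates."""
    rng = np.random.default_rng(8)
    only = kept = 0
    n_rep = 200
    for _ in range(n_rep):
        cov = make_covariates(200, rng)
        eta = 0.5 - 1.0 * cov["migrant"].to_numpy()
        y = rng.poisson(np.exp(eta))
        res = stepwise_backward(y, cov)
        kept += ("migrant",) in res.terms
        only += res.terms == (("migrant",),)
    assert kept >= 0.9 * n_rep
    # five other droppable terms at ~5% each: all-dropped ~ 0.95^5 = 0.77
    assert 0.65 * n_rep <= only <= 0.9 * n_rep


def test_stepwise_invariant_to_term_order():
    rng = np.random.default_rng(9)
    cov = make_covariates(120, rng)
    y = rng.poisson(np.exp(0.2 + 0.4 * cov["sex"].to_numpy()))
    base = stepwise_backward(y, cov)
    for perm in itertools.permutations(MAXIMAL_TERMS[:3]):
        spec = ModelSpec(terms=tuple(perm) + MAXIMAL_TERMS[3:])
        assert stepwise_backward(y, cov, spec).terms == base.terms


def test_stepwise_degenerate_passthrough():
    cov = make_covariates(20)
    res = stepwise_backward([0] * 20, cov)
    assert res.degenerate


def test_term_table_shape():
    rng = np.random.default_rng(10)
    cov = make_covariates(100, rng)
    y = rng.poisson(2.0, 100)
    res = stepwise_backward(y, cov)
    tab = res.term_table()
    assert list(tab["term"]) == ["Intercept", "age", "sex(men)",
                                 "migration(yes)", "age:sex(men)",
                                 "age:migration(yes)",
                                 "sex(men):migration(yes)"]
    dropped_labels = {e["term"] for e in res.dropped}
    for row in tab.itertuples():
        if row.term in dropped_labels:
            assert row.estimate == "ns"
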