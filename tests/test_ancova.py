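"""Partial-F ANCOVA against independent least-squares and anova oracles."""

import numpy as np
import pytest
import statsmodels.api as sm
from scipy import stats

import endoscan as es
from conftest import random_sample_table


def normal_equations_oracle(y, groups, covariates):
    """Partial F via explicit normal equations and residual sums."""
    cats = np.unique(groups)
    n = len(y)
    dummies = np.column_stack([(groups == c).astype(float) for c in cats[1:]])
    X_full = np.column_stack([np.ones(n), dummies, covariates])
    X_red = np.column_stack([np.ones(n), covariates])

    def sse(X):
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        r = y - X @ beta
        return r @ r

    df1 = len(cats) - 1
    df2 = n - X_full.shape[1]
    f = (sse(X_red) - sse(X_full)) / df1 / (sse(X_full) / df2)
    return f, stats.f.sf(f, df1, df2)


def test_identical_group_means_give_f_zero():
    groups = np.repeat([1, 2, 3], 4)
    st = es.SampleTable(
        np.array([f"s{i}" for i in range(12)], dtype=object), groups,
        np.zeros(12), np.zeros(12), np.zeros((12, 1)), n_pcs_expected=1,
    )
    y = np.tile([0.0, 1.0, 1.0, 2.0], 3)  # same values in every group
    res = es.DosageAncova(y, st, use_covariates=False).fit()
    assert res.F == pytest.approx(0.0, abs=1e-12)
    assert res.pvalue == pytest.approx(1.0)


def test_two_groups_reduce_to_pooled_t(rng):
    st = random_sample_table(rng, (15, 12))
    y = rng.binomial(2, 0.4, 27).astype(float)
    res = es.DosageAncova(y, st, use_covariates=False).fit()
    t = stats.ttest_ind(y[st.endophenotype == 1], y[st.endophenotype == 2])
    assert res.F == pytest.approx(t.statistic**2, rel=1e-12)
    assert res.pvalue == pytest.approx(t.pvalue, rel=1e-12)


def test_matches_normal_equations_on_random_designs(rng):
    """100 random small designs: partial F to relative error < 1e-10."""
    for _ in range(100):
        k = rng.integers(2, 6)
        sizes = rng.integers(4, 9, size=k)
        st = random_sample_table(rng, sizes, n_pcs=2)
        offs = rng.normal(0, 0.3, k)
        y = np.clip(
            rng.normal(0.8, 0.4, st.n_samples)
            + offs[st.endophenotype - 1]
            + 0.02 * st.age,
            0, 2,
        )
        res = es.DosageAncova(y, st).fit()
        f_ref, p_ref = normal_equations_oracle(y, st.endophenotype, st.covariates)
        assert res.F == pytest.approx(f_ref, rel=1e-10)
        assert res.pvalue == pytest.approx(p_ref, rel=1e-8)


def test_one_way_anova_closed_form(rng):
    """Without covariates the partial F is textbook SSB/SSW."""
    for _ in range(100):
        k = int(rng.integers(2, 6))
        sizes = rng.integers(3, 8, size=k)
        st = random_sample_table(rng, sizes, n_pcs=1)
        y = rng.normal(1.0, 0.5, st.n_samples)
        g = st.endophenotype
        gm = np.array([y[g == c].mean() for c in st.categories])
        ssb = sum(((y[g == c] * 0 + gm[i] - y.mean()) ** 2).sum()
                  for i, c in enumerate(st.categories))
        ssw = sum(((y[g == c] - gm[i]) ** 2).sum() for i, c in enumerate(st.categories))
        f_ref = (ssb / (k - 1)) / (ssw / (len(y) - k))
        res = es.DosageAncova(y, st, use_covariates=False).fit()
        assert res.F == pytest.approx(f_ref, rel=1e-10)
        np.testing.assert_allclose(res.adj_means, gm, rtol=1e-10)


def test_matches_statsmodels_with_covariates(rng):
    st = random_sample_table(rng, (20, 25, 18, 22, 30), n_pcs=4)
    y = np.clip(rng.normal(0.7, 0.4, st.n_samples) + 0.1 * (st.endophenotype == 4), 0, 2)
    res = es.DosageAncova(y, st).fit()
    dummies = np.column_stack([(st.endophenotype == c).astype(float)
                               for c in st.categories[1:]])
    X_full = sm.add_constant(np.column_stack([dummies, st.covariates]))
    X_red = sm.add_constant(st.covariates)
    fit_full = sm.OLS(y, X_full).fit()
    fref = fit_full.compare_f_test(sm.OLS(y, X_red).fit())
    assert res.F == pytest.approx(fref[0], rel=1e-9)
    assert res.pvalue == pytest.approx(fref[1], rel=1e-7)
    assert res.df2 == int(fit_full.df_resid)


def test_f_invariant_under_affine_dosage_transform(rng):
    st = random_sample_table(rng, (10, 12, 9))
    y = rng.normal(1.0, 0.3, st.n_samples)
    base = es.DosageAncova(y, st).fit()
    for a, b in [(2.0, -1.0), (-0.5, 3.0), (0.1, 0.0)]:
        res = es.DosageAncova(a * y + b, st).fit()
        assert res.F == pytest.approx(base.F, rel=1e-9)


def test_complete_case_drops_missing_and_reports_n(rng):
    st = random_sample_table(rng, (20, 20, 20))
    y = rng.normal(1.0, 0.3, 60)
    y[:5] = np.nan
    res = es.DosageAncova(y, st).fit()
    assert res.n_used == 55
    assert res.df2 == 55 - (3 + 5)  # K + intercept-absorbed covariate count


def test_errors_are_informative(rng):
    st = random_sample_table(rng, (10, 10))
    with pytest.raises(es.MonomorphicVariantError):
        es.DosageAncova(np.ones(20), st).fit()
    y = rng.normal(1, 0.2, 20)
    y[st.endophenotype == 2] = np.nan
    with pytest.raises(ValueError, match="2"):
        es.DosageAncova(y, st)
    # collinear covariate: sex constant duplicates the intercept
    st2 = es.SampleTable(
        np.array([f"s{i}" for i in range(20)], dtype=object),
        np.repeat([1, 2], 10), np.ones(20), np.ones(20),
        np.ones((20, 1)), n_pcs_expected=1,
    )
    with pytest.raises(ValueError, match="collinear"):
        es.DosageAncova(rng.normal(1, 0.2, 20), st2).fit()


def test_adjusted_means_shift_with_confounded_covariate(rng):
    """Age gradient across groups moves raw means; LS means correct for it."""
    st = random_sample_table(rng, (40, 40, 40))
    age_effect = 0.05
    y = np.clip(rng.normal(0.8, 0.2, 120) + age_effect * st.age, 0, 2)
    res = es.DosageAncova(y, st).fit()
    raw = res.raw_means
    # groups have the same dosage process given age, so adjusted means are closer
    assert np.ptp(res.adj_means) <= np.ptp(raw) + 0.05


def test_severity_trend_exact_and_null(rng):
    st = random_sample_table(rng, (10, 10, 10, 10, 10))
    y_exact = st.endophenotype.astype(float) / 3.0
    r = es.SeverityTrend(y_exact, st, use_covariates=False).fit()
    assert r.pvalue < 1e-200 and r.slope == pytest.approx(1 / 3, rel=1e-9)
    with pytest.raises(ValueError, match="constant"):
        es.SeverityTrend(y_exact, st, score=np.ones(st.n_samples))
    r2 = es.SeverityTrend(rng.normal(1, 0.3, st.n_samples), st).fit()
    assert 0.0 < r2.pvalue <= 1.0


def test_trend_matches_statsmodels(rng):
    st = random_sample_table(rng, (30, 30, 30), n_pcs=2)
    y = np.clip(rng.normal(0.8, 0.3, 90) + 0.05 * st.endophenotype, 0, 2)
    r = es.SeverityTrend(y, st).fit()
    X = sm.add_constant(np.column_stack([st.endophenotype.astype(float), st.covariates]))
    ref = sm.OLS(y, X).fit()
    assert r.slope == pytest.approx(ref.params[1], rel=1e-10)
    assert r.se == pytest.approx(ref.bse[1], rel=1e-10)
    assert r.pvalue == pytest.approx(ref.pvalues[1], rel=1e-8)
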