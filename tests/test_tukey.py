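"""Studentized-range tail and Tukey-Kramer contrasts.

The quadrature implementation is cross-checked against scipy's
studentized_range distribution (an independent implementation), the k=2
reduction to Student t, and published critical-value tables.
"""

import numpy as np
import pytest
from scipy import stats

import endoscan as es


def test_sf_at_zero_is_one():
    assert es.studentized_range_sf(0.0, 5, 60) == 1.0
    assert es.studentized_range_sf(-1.0, 3, 10) == 1.0


@pytest.mark.parametrize("df", [3, 10, 60, 500])
@pytest.mark.parametrize("q", [0.5, 1.5, 3.0, 5.0])
def test_sf_k2_reduces_to_two_sided_t(q, df):
    expected = 2.0 * stats.t.sf(q / np.sqrt(2.0), df)
    assert es.studentized_range_sf(q, 2, df) == pytest.approx(expected, abs=1e-6)


@pytest.mark.parametrize("k,df,q", [
    (3, 5, 2.0), (4, 12, 3.5), (5, 60, 3.977), (5, 816, 4.5),
    (6, 30, 5.0), (10, 20, 2.5), (2, 1, 8.0), (3, 2, 12.0),
])
def test_sf_matches_scipy_reference(k, df, q):
    assert es.studentized_range_sf(q, k, df) == pytest.approx(
        stats.studentized_range.sf(q, k, df), abs=1e-6
    )


def test_critical_value_matches_published_tables():
    # q_0.05(k=5, df=60) = 3.98 in standard studentized-range tables
    assert es.tukey_q_critical(0.05, 5, 60) == pytest.approx(3.98, abs=5e-3)
    # q_0.05(k=3, df=10) = 3.88
    assert es.tukey_q_critical(0.05, 3, 10) == pytest.approx(3.88, abs=5e-3)


def test_sf_rejects_bad_arguments():
    with pytest.raises(ValueError):
        es.studentized_range_sf(np.nan, 3, 10)
    with pytest.raises(ValueError):
        es.studentized_range_sf(1.0, 1, 10)


def test_identical_means_give_p_one():
    contrasts = es.tukey_hsd(np.zeros(4), 1.0, np.full(4, 10), 36)
    assert len(contrasts) == 6
    assert all(c.p_adj == pytest.approx(1.0) for c in contrasts)


def test_k2_contrast_equals_unadjusted_t_test():
    means = np.array([0.3, 0.7])
    sizes = np.array([12, 15])
    mse, df2 = 0.2, 25
    (c,) = es.tukey_hsd(means, mse, sizes, df2)
    t = abs(means[0] - means[1]) / np.sqrt(mse * (1 / 12 + 1 / 15))
    assert c.p_adj == pytest.approx(2 * stats.t.sf(t, df2), abs=1e-6)
    assert c.q == pytest.approx(t * np.sqrt(2), rel=1e-12)


def test_one_shifted_group_flags_exactly_its_contrasts():
    """K=5, one group 6 se away: its 4 contrasts significant, other 6 not."""
    k, n, df2 = 5, 50, 800
    mse = 0.4
    se = np.sqrt(mse * (2 / n) / 2)
    means = np.array([0.5, 0.5, 0.5, 0.5, 0.5 + 6 * se])
    contrasts = es.tukey_hsd(means, mse, np.full(k, n), df2)
    sig = {(c.group_a, c.group_b) for c in contrasts if c.p_adj < 0.05}
    assert sig == {(1, 5), (2, 5), (3, 5), (4, 5)}


def test_kramer_se_for_unequal_sizes():
    means = np.array([0.2, 0.5, 0.9])
    sizes = np.array([10, 20, 40])
    contrasts = es.tukey_hsd(means, 0.3, sizes, 67)
    for c in contrasts:
        na, nb = sizes[c.group_a - 1], sizes[c.group_b - 1]
        assert c.se == pytest.approx(np.sqrt(0.3 * (1 / na + 1 / nb) / 2), rel=1e-12)


def test_tukey_matches_scipy_equal_sized(rng):
    """Full pipeline contrast p-values vs scipy.stats.tukey_hsd on raw data."""
    groups = [rng.normal(m, 1.0, 30) for m in (0.0, 0.3, 0.8)]
    y = np.concatenate(groups)
    labels = np.repeat([1, 2, 3], 30)
    st = es.SampleTable(
        np.array([f"s{i}" for i in range(90)], dtype=object), labels,
        np.zeros(90), np.zeros(90), np.zeros((90, 1)), n_pcs_expected=1,
    )
    # plain ANOVA path (no covariates): adjusted means are raw means
    res = es.DosageAncova(np.clip((y - y.min()) / np.ptp(y) * 2, 0, 2), st,
                          use_covariates=False).fit()
    ours = {(c.group_a, c.group_b): c.p_adj for c in res.tukey()}
    yscaled = np.clip((y - y.min()) / np.ptp(y) * 2, 0, 2)
    ref = stats.tukey_hsd(*[yscaled[labels == g] for g in (1, 2, 3)])
    for (a, b), p in ours.items():
        assert p == pytest.approx(ref.pvalue[a - 1, b - 1], abs=1e-5)


def test_tukey_hsd_input_validation():
    with pytest.raises(ValueError, match="MSE"):
        es.tukey_hsd(np.zeros(3), 0.0, np.full(3, 5), 12)
    with pytest.raises(ValueError, match="n >= 2"):
        es.tukey_hsd(np.zeros(3), 1.0, np.array([5, 1, 5]), 12)


def test_adjusted_contrast_se_uses_design_covariance(rng):
    """With covariates, adjusted-mean contrast SEs equal the OLS contrast
    covariance (what emmeans/multcomp compute), not the Kramer shortcut."""
    import statsmodels.api as sm
    from conftest import random_sample_table

    st = random_sample_table(rng, (20, 25, 18, 22, 30), n_pcs=2)
    # age gradient across groups makes the dummy coefficients collinear with age
    age = st.age + 0.9 * st.endophenotype
    st = es.SampleTable(st.sample_id, st.endophenotype, age, st.sex, st.pcs)
    y = np.clip(rng.normal(0.8, 0.4, st.n_samples) + 0.03 * age, 0, 2)
    res = es.DosageAncova(y, st).fit()

    dummies = np.column_stack([(st.endophenotype == c).astype(float)
                               for c in st.categories[1:]])
    X = sm.add_constant(np.column_stack([dummies, st.covariates]))
    cov = sm.OLS(y, X).fit().cov_params()
    k = st.k
    for c in res.tukey(adjusted=True):
        vec = np.zeros(X.shape[1])
        if c.group_a > 1:
            vec[c.group_a - 1] = 1.0
        if c.group_b > 1:
            vec[c.group_b - 1] = -1.0
        se_t = np.sqrt(vec @ cov @ vec)
        assert c.se * np.sqrt(2) == pytest.approx(se_t, rel=1e-8)
        assert c.p_adj == pytest.approx(
            es.studentized_range_sf(np.sqrt(2) * abs(c.diff) / se_t, k, res.df2),
            abs=1e-10,
        )
    # Kramer understates the SE when age separates the groups
    kram = {(t.group_a, t.group_b): t.se for t in res.tukey(adjusted=False)}
    adj = {(t.group_a, t.group_b): t.se for t in res.tukey(adjusted=True)}
    assert np.mean([adj[p] > kram[p] for p in adj]) > 0.5


def test_sf_vectorized_matches_scalar():
    qs = np.array([0.0, 0.7, 2.2, 4.1, 9.0])
    vec = es.studentized_range_sf(qs, 5, 40)
    for q, v in zip(qs, vec):
        assert v == pytest.approx(es.studentized_range_sf(float(q), 5, 40), abs=1e-12)
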