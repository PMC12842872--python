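"""MAF, the Hardy-Weinberg exact test, and the ordered QC filters."""

from fractions import Fraction
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

import endoscan as es
from endoscan.cohort import GenotypeMatrix, SampleTable, Variant
from endoscan.qc import hard_calls


def hwe_enumeration_oracle(n_AA, n_Aa, n_aa):
    """Exact-arithmetic enumeration of heterozygote configurations."""
    n = n_AA + n_Aa + n_aa
    n_a = 2 * n_aa + n_Aa
    rare = min(n_a, 2 * n - n_a)
    weights = {}
    for h in range(rare % 2, rare + 1, 2):
        r = (rare - h) // 2
        c = n - h - r
        weights[h] = Fraction(
            comb(n, h) * comb(n - h, r) * 2**h
        )
    total = sum(weights.values())
    probs = {h: w / total for h, w in weights.items()}
    obs = probs[n_Aa]
    return float(sum(p for p in probs.values() if p <= obs))


@pytest.mark.parametrize(
    "dosages, expected",
    [
        ([0, 1, 2, 2], 0.375),
        ([2, 2, 2, 2], 0.0),
        ([0, 1, 1, 0, 2, 0, 1, 1], 0.375),  # 6/16 folded
    ],
)
def test_minor_allele_frequency_examples(dosages, expected):
    assert es.minor_allele_frequency(dosages) == pytest.approx(expected)


def test_maf_ignores_missing_and_rejects_all_missing():
    assert es.minor_allele_frequency([1.0, np.nan, 1.0]) == pytest.approx(0.5)
    with pytest.raises(ValueError, match="missing"):
        es.minor_allele_frequency([np.nan, np.nan])


@given(hst.lists(hst.floats(0, 2), min_size=1, max_size=30))
@settings(max_examples=100, derandomize=True)
def test_maf_invariant_to_allele_relabeling(d):
    d = np.asarray(d)
    assert es.minor_allele_frequency(d) == pytest.approx(
        es.minor_allele_frequency(2.0 - d), abs=1e-12
    )


@pytest.mark.parametrize(
    "counts",
    [(25, 50, 25), (50, 0, 50), (3, 1, 3), (0, 0, 7), (10, 5, 0), (1, 1, 1), (4, 8, 4)],
)
def test_hwe_matches_enumeration_oracle(counts):
    assert es.hwe_exact_test(*counts) == pytest.approx(
        hwe_enumeration_oracle(*counts), rel=1e-9
    )


def test_hwe_examples():
    assert es.hwe_exact_test(25, 50, 25) == pytest.approx(1.0)
    assert es.hwe_exact_test(50, 0, 50) < 1e-6  # maximal het deficit fails QC
    with pytest.raises(ValueError):
        es.hwe_exact_test(-1, 2, 3)


def test_hard_calls_excludes_ambiguous_dosages():
    hc = hard_calls(np.array([0.05, 1.0, 1.5, 1.95, np.nan]))
    np.testing.assert_array_equal(hc[:2], [0.0, 1.0])
    assert np.isnan(hc[2]) and hc[3] == 2.0 and np.isnan(hc[4])


def _toy_cohort(dosage):
    m, n = dosage.shape
    variants = [Variant(f"v{i}", "1", 100 * (i + 1)) for i in range(m)]
    samples = [f"s{j}" for j in range(n)]
    gm = GenotypeMatrix(variants, samples, dosage)
    st = SampleTable(
        np.array(samples, dtype=object),
        np.tile([1, 2], n // 2)[:n],
        np.full(n, 9.0),
        np.zeros(n),
        np.zeros((n, 2)),
        n_pcs_expected=2,
    )
    return gm, st


def test_qc_call_rate_gate():
    # v0 misses 6% of samples -> removed for call rate; with 40 variants the
    # affected samples stay under the 5% sample-missingness gate
    rng = np.random.default_rng(0)
    dosage = rng.binomial(2, 0.3, size=(40, 100)).astype(float)
    dosage[0, :6] = np.nan
    gm, st = _toy_cohort(dosage)
    gm2, _, report = es.apply_qc(gm, st)
    assert "v0" not in [v.id for v in gm2.variants]
    assert gm2.n_samples == 100
    row = report.to_frame().iloc[0]
    assert row["reason"] == "call_rate" and row["item"] == "v0"
    assert row["value"] == pytest.approx(0.94)


def test_qc_maf_and_hwe_gates():
    rng = np.random.default_rng(1)
    ok = rng.binomial(2, 0.4, 200).astype(float)
    rare = rng.binomial(2, 0.01, 200).astype(float)
    het_deficit = np.repeat([0.0, 2.0], 100)
    gm, st = _toy_cohort(np.vstack([ok, rare, het_deficit]))
    gm2, _, report = es.apply_qc(gm, st)
    assert [v.id for v in gm2.variants] == ["v0"]
    reasons = dict(zip(report.to_frame()["item"], report.to_frame()["reason"]))
    assert reasons == {"v1": "maf", "v2": "hwe"}


def test_qc_sample_removal_precedes_variant_filters():
    # one sample with 60% missing; dropping it lifts a variant above the MAF gate
    dosage = np.array([
        [1, 1, 1, 1, 1, 1, 1, 1, 1, np.nan],   # fine either way
        [0, 0, 0, 0, 0, 1, 1, 0, 0, np.nan],   # MAF 0.10 without s9, ~0.09 pooled
        [1, 0, 1, 0, 1, 0, 1, 0, 1, np.nan],
        [0, 1, 0, 1, 0, 1, 0, 1, 0, np.nan],
        [1, 1, 0, 0, 1, 1, 0, 0, 1, 0.0],
    ], dtype=float)
    gm, st = _toy_cohort(dosage)
    thr = es.QcThresholds(variant_call_rate_min=0.95, maf_min=0.1,
                          hwe_p_min=1e-6, sample_missing_max=0.5)
    gm2, st2, report = es.apply_qc(gm, st, thr)
    df = report.to_frame()
    assert df.iloc[0]["type"] == "sample" and df.iloc[0]["item"] == "s9"
    assert "v1" in [v.id for v in gm2.variants]  # survives once s9 is gone
    assert st2.n_samples == 9


def test_qc_is_idempotent(small_cohort):
    gm, st, _ = small_cohort
    d = gm.dosage.copy()
    d[0, :50] = np.nan
    gm = GenotypeMatrix(gm.variants, gm.samples, d)
    once = es.apply_qc(gm, st)
    twice = es.apply_qc(once[0], once[1])
    assert [v.id for v in twice[0].variants] == [v.id for v in once[0].variants]
    np.testing.assert_array_equal(twice[0].dosage, once[0].dosage)
    assert len(twice[2].removals) == 0


def test_qc_error_when_nothing_survives():
    # every variant fails the MAF gate
    dosage = np.zeros((2, 10))
    gm, st = _toy_cohort(dosage)
    with pytest.raises(ValueError, match="survive QC"):
        es.apply_qc(gm, st)
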