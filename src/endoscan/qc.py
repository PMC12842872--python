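"""Cohort quality control: call rate, minor-allele frequency, and the
Hardy-Weinberg exact test.

Filter order is fixed: samples with excess missingness are dropped first,
then variant filters (call rate, MAF, HWE) are evaluated on the surviving
samples.  Every removal is recorded with its reason so the QC is auditable
and idempotent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .cohort import GenotypeMatrix, SampleTable

__all__ = [
    "QcThresholds",
    "QcReport",
    "minor_allele_frequency",
    "hwe_exact_test",
    "hard_calls",
    "apply_qc",
]


@dataclass(frozen=True)
class QcThresholds:
    """Variant/sample filter thresholds.

    Defaults: variant call rate >= 95%, MAF >= 5%, HWE exact p >= 1e-6,
    sample missingness <= 5%.
    """

    variant_call_rate_min: float = 0.95
    maf_min: float = 0.05
    hwe_p_min: float = 1e-6
    sample_missing_max: float = 0.05

    def __post_init__(self) -> None:
        for name in ("variant_call_rate_min", "maf_min", "hwe_p_min", "sample_missing_max"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must lie in (0,1), got {v}")


@dataclass
class QcReport:
    """Ledger of QC removals: one row per removed item, plus the sex coding."""

    removals: list = field(default_factory=list)
    sex_coding: str = "0/1 as provided"

    def add(self, item: str, item_type: str, reason: str, value: float, threshold: float) -> None:
        self.removals.append(
            {"item": item, "type": item_type, "reason": reason,
             "value": value, "threshold": threshold}
        )

    def to_frame(self) -> pd.DataFrame:
        cols = ["item", "type", "reason", "value", "threshold"]
        return pd.DataFrame(self.removals, columns=cols)

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def minor_allele_frequency(dosages: np.ndarray) -> float:
    """Folded allele frequency min(f, 1-f), f = mean(dosage)/2 over non-missing.

    Raises if every dosage is missing.
    """
    d = np.asarray(dosages, dtype=float)
    d = d[np.isfinite(d)]
    if d.size == 0:
        raise ValueError("MAF undefined: all dosages missing")
    f = d.mean() / 2.0
    return float(min(f, 1.0 - f))


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact two-sided Hardy-Weinberg test on genotype counts.

    Conditions on the allele counts and sums the probabilities of every
    heterozygote configuration whose conditional probability does not
    exceed that of the observed one.  Probabilities are computed in log
    space; a relative tolerance of 1e-12 guards the <= comparison against
    rounding.
    """
    if n_AA < 0 or n_Aa < 0 or n_aa < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise ValueError("need at least one genotyped sample")
    n_a = 2 * n_aa + n_Aa  # count of one allele; symmetry makes the choice immaterial
    rare = min(n_a, 2 * n - n_a)
    # heterozygote counts share the parity of the rare-allele count
    hets = np.arange(rare % 2, rare + 1, 2)
    n_homr = (rare - hets) // 2
    n_homc = n - hets - n_homr
    logp = (
        gammaln(n + 1.0) - gammaln(hets + 1.0) - gammaln(n_homr + 1.0)
        - gammaln(n_homc + 1.0) + hets * np.log(2.0)
    )
    logp -= logp.max()
    p = np.exp(logp)
    p /= p.sum()
    obs = np.nonzero(hets == n_Aa)[0][0]
    return float(min(1.0, p[p <= p[obs] * (1.0 + 1e-12)].sum()))


def hard_calls(dosages: np.ndarray, max_dev: float = 0.1) -> np.ndarray:
    """Round dosages to {0,1,2}; entries farther than ``max_dev`` from an
    integer (ambiguous imputed calls) become nan and are excluded from the
    HWE count only."""
    d = np.asarray(dosages, dtype=float)
    r = np.round(d)
    out = np.where(np.isfinite(d) & (np.abs(d - r) <= max_dev), r, np.nan)
    return out


def _variant_hwe_p(dosages: np.ndarray) -> float:
    hc = hard_calls(dosages)
    hc = hc[np.isfinite(hc)]
    if hc.size == 0:
        return 1.0
    counts = [int((hc == g).sum()) for g in (0, 1, 2)]
    return hwe_exact_test(counts[0], counts[1], counts[2])


def apply_qc(
    gm: GenotypeMatrix, st: SampleTable, thr: QcThresholds = QcThresholds()
) -> tuple[GenotypeMatrix, SampleTable, QcReport]:
    """Apply the fixed-order QC filters.

    (1) restrict to samples shared by genotypes and sample table;
    (2) drop samples with missingness > ``sample_missing_max``;
    (3) drop variants with call rate < ``variant_call_rate_min``,
        MAF < ``maf_min``, or HWE exact p < ``hwe_p_min`` on the
        remaining samples.
    """
    report = QcReport()
    shared = [s for s in gm.samples if s in set(st.sample_id)]
    if not shared:
        raise ValueError("no samples shared between genotypes and sample table")
    gm = gm.subset(sample_ids=shared)
    st = st.subset(shared)

    miss = np.mean(~np.isfinite(gm.dosage), axis=0) if gm.n_variants else np.zeros(gm.n_samples)
    keep_samples = []
    for j, s in enumerate(gm.samples):
        if miss[j] > thr.sample_missing_max:
            report.add(s, "sample", "missingness", float(miss[j]), thr.sample_missing_max)
        else:
            keep_samples.append(s)
    if not keep_samples:
        raise ValueError("no data survive QC: every sample removed")
    gm = gm.subset(sample_ids=keep_samples)
    st = st.subset(keep_samples)

    keep_variants = []
    for i, v in enumerate(gm.variants):
        d = gm.dosage[i]
        call_rate = float(np.mean(np.isfinite(d)))
        if call_rate < thr.variant_call_rate_min:
            report.add(v.id, "variant", "call_rate", call_rate, thr.variant_call_rate_min)
            continue
        maf = minor_allele_frequency(d)
        if maf < thr.maf_min:
            report.add(v.id, "variant", "maf", maf, thr.maf_min)
            continue
        hwe_p = _variant_hwe_p(d)
        if hwe_p < thr.hwe_p_min:
            report.add(v.id, "variant", "hwe", hwe_p, thr.hwe_p_min)
            continue
        keep_variants.append(v.id)
    if not keep_variants:
        raise ValueError("no data survive QC: every variant removed")
    gm = gm.subset(variant_ids=keep_variants)
    return gm, st, report
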