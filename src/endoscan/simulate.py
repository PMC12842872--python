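"""Synthetic two-cohort generator for categorical-endophenotype GWAS.

The generator emulates the statistical structure the scan assumes: K
ordinal endophenotype groups with fixed sizes, a monotone age gradient
across groups (age is then a genuine confounder of severity), ancestry
PCs, and per-variant binomial genotypes whose allele frequency may differ
by group ("planted" variants), depend on PCs ("confounded" variants), or
be shared across groups (null variants).  Defaults reproduce the
discovery-cohort design: group sizes 171/154/168/163/177 with group mean
ages rising from ~7 to ~11 years; the replication-cohort preset uses
sizes 207/205/204/207/207.

Genotypes are hard {0,1,2} binomial draws (HWE-consistent within group);
an optional truncated-Gaussian dosage-noise mode mimics imputation
uncertainty.  An optional AR(1)-latent block mode produces correlated
variants solely to exercise LD clumping — it is not a model of human LD.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import GenotypeMatrix, SampleTable, Variant

log = logging.getLogger(__name__)

__all__ = [
    "PlantedVariant",
    "LdBlockSpec",
    "SimConfig",
    "CAMP_GROUP_SIZES",
    "GACRS_GROUP_SIZES",
    "CAMP_AGE_MEANS",
    "GACRS_AGE_MEANS",
    "simulate_cohort",
    "simulate_cohort_pair",
]

CAMP_GROUP_SIZES = (171, 154, 168, 163, 177)
GACRS_GROUP_SIZES = (207, 205, 204, 207, 207)
CAMP_AGE_MEANS = (6.96, 7.87, 9.04, 9.87, 10.88)
GACRS_AGE_MEANS = (8.25, 8.66, 9.15, 9.82, 9.95)


@dataclass(frozen=True)
class PlantedVariant:
    """A variant with group-specific minor-allele frequencies."""

    group_mafs: tuple
    label: str = "planted"

    def __post_init__(self) -> None:
        for f in self.group_mafs:
            if not (0.0 < f < 1.0):
                raise ValueError(f"planted frequency {f} outside (0,1)")


@dataclass(frozen=True)
class LdBlockSpec:
    """Blocks of ``size`` null variants with AR(1) latent correlation ``rho``."""

    n_blocks: int = 0
    size: int = 5
    rho: float = 0.9


@dataclass(frozen=True)
class SimConfig:
    """Full generative description of a synthetic cohort.

    ``pc_confounding`` gives per-PC slopes on allele frequency for null
    variants flagged as confounded; with nonzero slopes, unadjusted scans
    inflate and PC adjustment removes the inflation — the reason ancestry
    PCs are covariates in the scan model.
    """

    group_sizes: tuple = CAMP_GROUP_SIZES
    n_null_variants: int = 100
    planted: tuple = ()
    age_means: tuple = CAMP_AGE_MEANS
    age_sd: float = 2.0
    sex_frac: float = 0.39
    n_pcs: int = 10
    pc_confounding: tuple = ()
    maf_null_range: tuple = (0.05, 0.5)
    dosage_noise_sd: float = 0.0
    ld_blocks: LdBlockSpec = field(default_factory=LdBlockSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 2 for n in self.group_sizes):
            raise ValueError("every group needs at least 2 samples")
        if len(self.age_means) != len(self.group_sizes):
            raise ValueError("age_means and group_sizes lengths differ")

    @property
    def k(self) -> int:
        return len(self.group_sizes)

    @property
    def n_samples(self) -> int:
        return int(sum(self.group_sizes))


def _sample_table(cfg: SimConfig, rng: np.random.Generator) -> SampleTable:
    groups = np.repeat(np.arange(1, cfg.k + 1), cfg.group_sizes)
    n = len(groups)
    age = rng.normal(np.repeat(cfg.age_means, cfg.group_sizes), cfg.age_sd)
    sex = (rng.random(n) < cfg.sex_frac).astype(float)
    pcs = rng.standard_normal((n, cfg.n_pcs))
    ids = np.array([f"S{i:05d}" for i in range(n)], dtype=object)
    return SampleTable(ids, groups, age, sex, pcs, n_pcs_expected=cfg.n_pcs)


def _freq_matrix(base_by_group: np.ndarray, groups: np.ndarray,
                 pcs: np.ndarray, slopes: np.ndarray, clamp_counter: list) -> np.ndarray:
    """Per-sample allele frequency: group base + PC confounding, clamped."""
    f = base_by_group[groups - 1]
    if slopes.size:
        f = f + pcs[:, : len(slopes)] @ slopes
    clamped = (f < 0.01) | (f > 0.99)
    clamp_counter.append(int(clamped.sum()))
    return np.clip(f, 0.01, 0.99)


def simulate_cohort(cfg: SimConfig) -> tuple[GenotypeMatrix, SampleTable, pd.DataFrame]:
    """Draw one cohort: genotypes, sample table, and the generative truth.

    The truth table records, per variant, its kind (null / confounded /
    planted / block member) and the generative per-group frequencies.
    Bit-identical for a fixed config (including seed).
    """
    rng = np.random.default_rng(cfg.seed)
    st = _sample_table(cfg, rng)
    groups = st.endophenotype
    n = st.n_samples
    slopes = np.asarray(cfg.pc_confounding, dtype=float)

    variants: list[Variant] = []
    rows: list[np.ndarray] = []
    truth_rows: list[dict] = []
    clamp_counter: list[int] = []
    pos = 0

    def add(vid: str, kind: str, base_by_group: np.ndarray, dosage: np.ndarray):
        nonlocal pos
        pos += 10_000
        variants.append(Variant(vid, "1", pos))
        rows.append(dosage)
        rec = {"variant": vid, "kind": kind}
        for g in range(cfg.k):
            rec[f"freq_{g + 1}"] = base_by_group[g]
        truth_rows.append(rec)

    # null (optionally PC-confounded) variants
    null_freqs = rng.uniform(*cfg.maf_null_range, size=cfg.n_null_variants)
    for i, f0 in enumerate(null_freqs):
        base = np.full(cfg.k, f0)
        f = _freq_matrix(base, groups, st.pcs, slopes, clamp_counter)
        dosage = rng.binomial(2, f).astype(float)
        kind = "confounded" if slopes.size else "null"
        add(f"null_{i:06d}", kind, base, dosage)

    # AR(1) latent blocks (for clumping exercises)
    lb = cfg.ld_blocks
    for b in range(lb.n_blocks):
        f0 = float(rng.uniform(0.2, 0.5))
        base = np.full(cfg.k, f0)
        thr = stats.norm.ppf(f0)
        # two haplotypes per sample, AR(1) latent chain across block variants
        z = np.empty((2, n, lb.size))
        z[:, :, 0] = rng.standard_normal((2, n))
        for j in range(1, lb.size):
            z[:, :, j] = lb.rho * z[:, :, j - 1] + np.sqrt(1 - lb.rho ** 2) * rng.standard_normal((2, n))
        alleles = (z < thr).astype(float)
        for j in range(lb.size):
            add(f"block{b:03d}_{j:02d}", "block", base, alleles[0, :, j] + alleles[1, :, j])

    # planted group-specific variants
    for pv in cfg.planted:
        if len(pv.group_mafs) != cfg.k:
            raise ValueError(f"planted variant {pv.label}: needs {cfg.k} group frequencies")
        base = np.asarray(pv.group_mafs, dtype=float)
        f = _freq_matrix(base, groups, st.pcs, slopes, clamp_counter)
        dosage = rng.binomial(2, f).astype(float)
        add(f"planted_{pv.label}", "planted", base, dosage)

    total_draws = max(1, n * (cfg.n_null_variants + len(cfg.planted)))
    if sum(clamp_counter) > 0.01 * total_draws:
        warnings.warn(
            f"allele-frequency clamping hit {sum(clamp_counter)} draws "
            f"(> 1% of {total_draws}); confounding slopes may be too large",
            stacklevel=2,
        )

    dosage = np.vstack(rows) if rows else np.empty((0, n))
    if cfg.dosage_noise_sd > 0:
        noise = rng.normal(0.0, cfg.dosage_noise_sd, size=dosage.shape)
        dosage = np.clip(dosage + noise, 0.0, 2.0)
    gm = GenotypeMatrix(variants, list(st.sample_id), dosage)
    truth = pd.DataFrame(truth_rows)
    return gm, st, truth


def simulate_cohort_pair(
    cfg_discovery: SimConfig,
    cfg_replication: SimConfig,
    shared_truth: bool = True,
    attenuation: float = 1.0,
) -> tuple[tuple, tuple]:
    """Draw a discovery/replication cohort pair over one variant list.

    With ``shared_truth``, the replication cohort reuses the discovery
    cohort's generative frequencies (null frequencies and planted group
    patterns), the planted group effects shrunk toward their mean by
    ``attenuation`` (1 = identical truth, 0 = replication behaves null).
    Returns ((gm_d, st_d, truth_d), (gm_r, st_r, truth_r)).
    """
    if cfg_discovery.n_null_variants != cfg_replication.n_null_variants or \
            len(cfg_discovery.planted) != len(cfg_replication.planted) or \
            cfg_discovery.ld_blocks != cfg_replication.ld_blocks:
        raise ValueError("cohort pair must share the same variant list")
    disc = simulate_cohort(cfg_discovery)
    if shared_truth:
        truth_d = disc[2]
        freq_cols = [c for c in truth_d.columns if c.startswith("freq_")]
        planted = []
        null_freqs = []
        for _, row in truth_d.iterrows():
            f = row[freq_cols].to_numpy(dtype=float)
            if row["kind"] == "planted":
                fbar = f.mean()
                f_att = fbar + attenuation * (f - fbar)
                label = row["variant"].removeprefix("planted_")
                planted.append(PlantedVariant(tuple(np.clip(f_att, 0.01, 0.99)), label))
            elif row["kind"] in ("null", "confounded"):
                null_freqs.append(f[0])
        cfg_replication = replace(cfg_replication, planted=tuple(planted))
        rep = _simulate_with_null_freqs(cfg_replication, np.asarray(null_freqs))
    else:
        rep = simulate_cohort(cfg_replication)
    if [v.id for v in disc[0].variants] != [v.id for v in rep[0].variants]:
        raise ValueError("cohort pair produced mismatched variant lists")
    return disc, rep


def _simulate_with_null_freqs(cfg: SimConfig, null_freqs: np.ndarray):
    """Like simulate_cohort but with fixed (shared) null frequencies."""
    if len(null_freqs) != cfg.n_null_variants:
        raise ValueError("null frequency list does not match n_null_variants")
    # re-draw via the standard path, then overwrite null rows deterministically
    rng = np.random.default_rng(cfg.seed)
    st = _sample_table(cfg, rng)
    groups = st.endophenotype
    slopes = np.asarray(cfg.pc_confounding, dtype=float)
    clamp_counter: list[int] = []

    variants, rows, truth_rows = [], [], []
    pos = 0

    def add(vid, kind, base, dosage):
        nonlocal pos
        pos += 10_000
        variants.append(Variant(vid, "1", pos))
        rows.append(dosage)
        rec = {"variant": vid, "kind": kind}
        for g in range(cfg.k):
            rec[f"freq_{g + 1}"] = base[g]
        truth_rows.append(rec)

    for i, f0 in enumerate(null_freqs):
        base = np.full(cfg.k, float(f0))
        f = _freq_matrix(base, groups, st.pcs, slopes, clamp_counter)
        add(f"null_{i:06d}", "confounded" if slopes.size else "null",
            base, rng.binomial(2, f).astype(float))
    if cfg.ld_blocks.n_blocks:
        raise ValueError("shared-truth pairs do not support LD blocks")
    for pv in cfg.planted:
        base = np.asarray(pv.group_mafs, dtype=float)
        f = _freq_matrix(base, groups, st.pcs, slopes, clamp_counter)
        add(f"planted_{pv.label}", "planted", base, rng.binomial(2, f).astype(float))

    dosage = np.vstack(rows) if rows else np.empty((0, st.n_samples))
    if cfg.dosage_noise_sd > 0:
        noise = rng.normal(0.0, cfg.dosage_noise_sd, size=dosage.shape)
        dosage = np.clip(dosage + noise, 0.0, 2.0)
    gm = GenotypeMatrix(variants, list(st.sample_id), dosage)
    return gm, st, pd.DataFrame(truth_rows)
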