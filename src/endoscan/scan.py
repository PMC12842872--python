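"""Genome-wide ANCOVA scan: one partial F-test per variant.

All variants share the same design matrix (factor dummies + covariates),
so the scan is vectorized: one QR factorization of the design serves every
variant without missing dosages, and residual sums of squares for all
variants come from two matrix products.  Variants with missing calls fall
back to a per-variant complete-case fit.  Per-variant failures (e.g.
monomorphic dosages) become NA rows with a reason; they never abort the
scan.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import qr, solve_triangular

from .ancova import (
    DosageAncova,
    MonomorphicVariantError,
    SeverityTrend,
    contrast_variance_factors,
)
from .cohort import GenotypeMatrix, SampleTable
from .tukey import tukey_hsd

log = logging.getLogger(__name__)

GENOME_WIDE_ALPHA = 5e-8

__all__ = ["genome_scan", "trend_scan", "GENOME_WIDE_ALPHA"]


def _shared_design(st: SampleTable, use_covariates: bool):
    cats = st.categories
    n = st.n_samples
    dummies = np.column_stack([(st.endophenotype == c).astype(float) for c in cats[1:]])
    cov = st.covariates if use_covariates else np.empty((n, 0))
    X_full = np.column_stack([np.ones(n), dummies, cov])
    X_red = np.column_stack([np.ones(n), cov])
    return X_full, X_red, cats


def genome_scan(
    gm: GenotypeMatrix,
    st: SampleTable,
    alpha_gw: float = GENOME_WIDE_ALPHA,
    contrasts: str = "flagged",
    use_covariates: bool = True,
    adjusted_contrast_means: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the per-variant ANCOVA over a QC'd cohort.

    Parameters
    ----------
    alpha_gw : float
        Genome-wide significance threshold for the ``gw_flag`` column.
    contrasts : {"flagged", "all", "none"}
        For which variants to compute Tukey-Kramer post-hoc contrasts.

    Returns
    -------
    (results, contrast_table)
        ``results`` has one row per input variant:
        ``variant chrom pos n F df1 df2 p gw_flag adj_mean_1..K reason``;
        ``contrast_table`` has one row per computed contrast:
        ``variant group_a group_b diff se q p_adj``.
    """
    if contrasts not in ("flagged", "all", "none"):
        raise ValueError(f"contrasts must be flagged|all|none, got {contrasts!r}")
    if list(gm.samples) != list(st.sample_id):
        gm = gm.subset(sample_ids=list(st.sample_id))

    X_full, X_red, cats = _shared_design(st, use_covariates)
    k = len(cats)
    n = st.n_samples
    p_full = X_full.shape[1]
    df1, df2 = k - 1, n - p_full
    Qf, Rf = qr(X_full, mode="economic")
    Qr, _ = qr(X_red, mode="economic")
    group_sizes = np.array([(st.endophenotype == c).sum() for c in cats])
    cov_mean = st.covariates.mean(axis=0) if use_covariates else np.empty(0)

    Y = gm.dosage
    m = gm.n_variants
    F = np.full(m, np.nan)
    pvals = np.full(m, np.nan)
    nums = np.full(m, n)
    adj = np.full((m, k), np.nan)
    mses = np.full(m, np.nan)
    sizes_per_variant: dict[int, np.ndarray] = {}
    df2s = np.full(m, df2)
    reasons = np.array([""] * m, dtype=object)

    complete = np.all(np.isfinite(Y), axis=1)
    mono = np.ptp(np.nan_to_num(Y, nan=0.0), axis=1) == 0
    # monomorphic check on the complete-case subset is exact for complete rows;
    # rows with missing are re-checked in the fallback path
    fast = complete & ~mono

    if fast.any():
        Yf = Y[fast]
        yss = np.einsum("ij,ij->i", Yf, Yf)
        proj_f = Yf @ Qf
        proj_r = Yf @ Qr
        sse_f = yss - np.einsum("ij,ij->i", proj_f, proj_f)
        sse_r = yss - np.einsum("ij,ij->i", proj_r, proj_r)
        sse_f = np.maximum(sse_f, 0.0)
        mse = sse_f / df2
        with np.errstate(divide="ignore", invalid="ignore"):
            Fv = np.maximum((sse_r - sse_f) / df1, 0.0) / mse
        Fv = np.where(mse <= 0, np.inf, Fv)
        pv = stats.f.sf(Fv, df1, df2)
        beta = solve_triangular(Rf, proj_f.T)  # p_full x m_fast
        base = beta[0] + (cov_mean @ beta[k:] if use_covariates else 0.0)
        adj_fast = np.vstack([base, base + beta[1:k]]).T
        idx = np.nonzero(fast)[0]
        F[idx], pvals[idx], adj[idx], mses[idx] = Fv, pv, adj_fast, mse

    for i in np.nonzero(~fast)[0]:
        if (i + 1) % 10_000 == 0:
            log.info("scan fallback at variant %d/%d", i + 1, m)
        try:
            res = DosageAncova(Y[i], st, use_covariates=use_covariates).fit()
        except MonomorphicVariantError:
            reasons[i] = "monomorphic"
            continue
        except ValueError as exc:
            reasons[i] = str(exc)
            continue
        F[i], pvals[i], adj[i] = res.F, res.pvalue, res.adj_means
        mses[i], nums[i], df2s[i] = res.mse, res.n_used, res.df2
        sizes_per_variant[i] = res.model.group_sizes

    gw = pvals <= alpha_gw
    results = pd.DataFrame({
        "variant": [v.id for v in gm.variants],
        "chrom": [v.chrom for v in gm.variants],
        "pos": [v.pos for v in gm.variants],
        "n": nums,
        "F": F,
        "df1": df1,
        "df2": df2s,
        "p": pvals,
        "gw_flag": np.where(np.isfinite(pvals), gw, False),
        "mse": mses,
        "reason": reasons,
    })
    for j, c in enumerate(cats):
        results[f"adj_mean_{c}"] = adj[:, j]

    contrast_rows = []
    if contrasts != "none":
        vf_shared = contrast_variance_factors(X_full, k) if adjusted_contrast_means else None
        which = np.nonzero(gw if contrasts == "flagged" else np.isfinite(pvals))[0]
        for i in which:
            if not np.isfinite(mses[i]) or mses[i] <= 0:
                continue
            if i in sizes_per_variant:  # complete-case subset: per-variant design
                res = DosageAncova(Y[i], st, use_covariates=use_covariates).fit()
                contr = res.tukey(adjusted=adjusted_contrast_means)
            else:
                means = adj[i]
                if not adjusted_contrast_means:
                    means = np.array([
                        np.nanmean(Y[i][st.endophenotype == c]) for c in cats
                    ])
                contr = tukey_hsd(means, mses[i], group_sizes, df2,
                                  groups=cats, var_factors=vf_shared)
            for c in contr:
                contrast_rows.append({
                    "variant": gm.variants[i].id, "group_a": c.group_a,
                    "group_b": c.group_b, "diff": c.diff, "se": c.se,
                    "q": c.q, "p_adj": c.p_adj,
                })
    contrast_table = pd.DataFrame(
        contrast_rows,
        columns=["variant", "group_a", "group_b", "diff", "se", "q", "p_adj"],
    )
    return results, contrast_table


def trend_scan(
    gm: GenotypeMatrix,
    st: SampleTable,
    score: np.ndarray | None = None,
    use_covariates: bool = True,
) -> pd.DataFrame:
    """Severity-trend test for every variant: dosage ~ score + covariates.

    Vectorized over variants without missing calls; returns
    ``variant slope se p``.
    """
    if score is None:
        score = st.endophenotype.astype(float)
    score = np.asarray(score, dtype=float)
    if np.unique(score).size < 2:
        raise ValueError("severity score is constant")
    n = st.n_samples
    cov = st.covariates if use_covariates else np.empty((n, 0))
    X = np.column_stack([np.ones(n), score, cov])
    df = n - X.shape[1]
    xtx_inv_11 = np.linalg.inv(X.T @ X)[1, 1]
    Q, R = qr(X, mode="economic")

    Y = gm.dosage
    m = gm.n_variants
    slope = np.full(m, np.nan)
    se = np.full(m, np.nan)
    pv = np.full(m, np.nan)

    complete = np.all(np.isfinite(Y), axis=1)
    if complete.any():
        Yc = Y[complete]
        proj = Yc @ Q
        beta = solve_triangular(R, proj.T)
        sse = np.maximum(np.einsum("ij,ij->i", Yc, Yc) - np.einsum("ij,ij->i", proj, proj), 0.0)
        sig2 = sse / df
        s = np.sqrt(np.maximum(sig2 * xtx_inv_11, 0.0))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(s > 0, beta[1] / s, np.where(beta[1] != 0, np.inf, 0.0))
        idx = np.nonzero(complete)[0]
        slope[idx], se[idx] = beta[1], s
        pv[idx] = 2.0 * stats.t.sf(np.abs(t), df)

    for i in np.nonzero(~complete)[0]:
        try:
            r = SeverityTrend(Y[i], st, score=score, use_covariates=use_covariates).fit()
        except ValueError:
            continue
        slope[i], se[i], pv[i] = r.slope, r.se, r.pvalue

    return pd.DataFrame({
        "variant": [v.id for v in gm.variants],
        "slope": slope, "se": se, "p": pv,
    })
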