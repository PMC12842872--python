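"""Per-variant ANCOVA of genotype dosage on a categorical endophenotype.

The model is a reverse regression: dosage is the response,

    dosage ~ endophenotype + age + sex + PC1..PC10,

and the endophenotype factor (K levels) is tested with a partial F
comparing the full linear model against the reduced model without the
factor.  Because the factor is the only term dropped, this coincides with
Type-II and Type-III tests.  Post-hoc localization uses Tukey-Kramer
contrasts on the covariate-adjusted (least-squares) group means; raw-mean
contrasts are available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .cohort import SampleTable
from .tukey import TukeyContrast, tukey_hsd

__all__ = [
    "DosageAncova",
    "DosageAncovaResults",
    "SeverityTrend",
    "TrendResults",
    "MonomorphicVariantError",
    "contrast_variance_factors",
]


class MonomorphicVariantError(ValueError):
    """Raised when the dosage vector is constant within the analysis subset."""


def _check_full_rank(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify columns that do not extend the span of their predecessors
        bad = []
        for j in range(1, X.shape[1]):
            if np.linalg.matrix_rank(X[:, : j + 1]) == np.linalg.matrix_rank(X[:, :j]):
                bad.append(names[j])
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")


def _lstsq_sse(X: np.ndarray, y: np.ndarray):
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return beta, float(resid @ resid)


def contrast_variance_factors(X_full: np.ndarray, k: int) -> np.ndarray:
    """Unit-variance factors Var(adj_mean_a - adj_mean_b) / sigma^2.

    Adjusted-mean differences equal group-dummy coefficient contrasts
    (the intercept and covariate terms cancel at shared covariate means),
    so the factor is the (a,b) contrast quadratic form in (X'X)^-1 over
    the dummy block, with the reference group contributing zero.  Without
    covariates this reduces to the Tukey-Kramer 1/n_a + 1/n_b.
    """
    xtx_inv = np.linalg.inv(X_full.T @ X_full)
    # dummy columns are 1..k-1; reference group maps to a zero row/column
    c = np.zeros((k, k))
    c[1:, 1:] = xtx_inv[1:k, 1:k]
    diag = np.diag(c)
    return diag[:, None] + diag[None, :] - 2.0 * c


class DosageAncova:
    """ANCOVA model for one variant's dosage vector.

    Parameters
    ----------
    y : array
        Dosage per sample, aligned with ``sample_table``; nan entries are
        dropped (per-variant complete-case analysis).
    sample_table : SampleTable
        Endophenotype factor and covariates.
    use_covariates : bool
        Include age, sex, and ancestry PCs; False gives plain one-way ANOVA.
    """

    def __init__(self, y: np.ndarray, sample_table: SampleTable, use_covariates: bool = True):
        y = np.asarray(y, dtype=float)
        if len(y) != sample_table.n_samples:
            raise ValueError("y length does not match sample table")
        keep = np.isfinite(y)
        self.y = y[keep]
        self.groups = sample_table.endophenotype[keep]
        self.categories = sample_table.categories
        self.k = len(self.categories)
        if use_covariates:
            self.covariates = sample_table.covariates[keep]
            self.cov_names = ["age", "sex"] + [f"pc{j+1}" for j in range(sample_table.pcs.shape[1])]
        else:
            self.covariates = np.empty((keep.sum(), 0))
            self.cov_names = []
        sizes = np.array([(self.groups == c).sum() for c in self.categories])
        empty = self.categories[sizes < 2]
        if empty.size:
            raise ValueError(
                f"groups with <2 non-missing samples after complete-case filtering: "
                f"{empty.tolist()}"
            )
        if np.ptp(self.y) == 0.0:
            raise MonomorphicVariantError("monomorphic")
        self.group_sizes = sizes
        self.n_used = int(keep.sum())

    def _design(self):
        n = self.n_used
        dummies = np.column_stack(
            [(self.groups == c).astype(float) for c in self.categories[1:]]
        )
        X_full = np.column_stack([np.ones(n), dummies, self.covariates])
        X_red = np.column_stack([np.ones(n), self.covariates])
        names = (
            ["intercept"]
            + [f"endo_{c}" for c in self.categories[1:]]
            + self.cov_names
        )
        return X_full, X_red, names

    def fit(self) -> "DosageAncovaResults":
        X_full, X_red, names = self._design()
        _check_full_rank(X_full, names)
        beta, sse_full = _lstsq_sse(X_full, self.y)
        _, sse_red = _lstsq_sse(X_red, self.y)
        df1 = self.k - 1
        df2 = self.n_used - X_full.shape[1]
        if df2 < 1:
            raise ValueError(f"no residual degrees of freedom (n={self.n_used})")
        mse = sse_full / df2
        if mse <= 0.0:  # factor + covariates fit y exactly
            fstat, pval = np.inf, 0.0
        else:
            fstat = max(0.0, (sse_red - sse_full) / df1 / mse)
            pval = float(stats.f.sf(fstat, df1, df2))
        # least-squares (adjusted) means: group prediction at sample-mean covariates
        cov_mean = self.covariates.mean(axis=0) if self.covariates.size else np.empty(0)
        base = beta[0] + (cov_mean @ beta[self.k:] if self.cov_names else 0.0)
        adj_means = np.concatenate([[base], base + beta[1:self.k]])
        raw_means = np.array([self.y[self.groups == c].mean() for c in self.categories])
        return DosageAncovaResults(
            model=self, params=beta, param_names=names, F=float(fstat), df1=df1,
            df2=df2, pvalue=pval, mse=float(mse), adj_means=adj_means,
            raw_means=raw_means,
            contrast_var_factors=contrast_variance_factors(X_full, self.k),
        )


@dataclass
class DosageAncovaResults:
    """Fitted ANCOVA: partial F for the endophenotype factor plus the
    adjusted group means needed for post-hoc contrasts."""

    model: DosageAncova
    params: np.ndarray
    param_names: list
    F: float
    df1: int
    df2: int
    pvalue: float
    mse: float
    adj_means: np.ndarray
    raw_means: np.ndarray
    contrast_var_factors: np.ndarray = None

    @property
    def n_used(self) -> int:
        return self.model.n_used

    def tukey(self, adjusted: bool = True) -> list[TukeyContrast]:
        """Tukey contrasts on adjusted (default) or raw group means.

        Adjusted-mean contrasts use the exact design-based contrast
        covariance (reduces to Tukey-Kramer without covariates); raw-mean
        contrasts use the Kramer standard error.
        """
        means = self.adj_means if adjusted else self.raw_means
        vf = self.contrast_var_factors if adjusted else None
        return tukey_hsd(means, self.mse, self.model.group_sizes, self.df2,
                         groups=self.model.categories, var_factors=vf)

    def summary(self) -> str:
        lines = [
            "Dosage ANCOVA (genotype ~ endophenotype + covariates)",
            f"  n = {self.n_used}, groups = {self.model.k}, "
            f"covariates = {len(self.model.cov_names)}",
            f"  F({self.df1}, {self.df2}) = {self.F:.4f}   p = {self.pvalue:.4g}",
            "  adjusted group means (dosage):",
        ]
        for c, m in zip(self.model.categories, self.adj_means):
            lines.append(f"    endophenotype {c}: {m:.4f}")
        return "\n".join(lines)


class SeverityTrend:
    """Linear dosage-on-severity-score regression with covariates.

    Tests for a monotone allele-dosage trend along a continuous severity
    axis: dosage ~ score + age + sex + PCs.  ``score`` defaults to the
    ordinal group index when no per-sample severity score is available.
    """

    def __init__(self, y, sample_table: SampleTable, score=None, use_covariates: bool = True):
        y = np.asarray(y, dtype=float)
        if score is None:
            score = sample_table.endophenotype.astype(float)
        score = np.asarray(score, dtype=float)
        keep = np.isfinite(y) & np.isfinite(score)
        self.y = y[keep]
        self.score = score[keep]
        if np.unique(self.score).size < 2:
            raise ValueError("severity score is constant; trend untestable")
        self.covariates = (
            sample_table.covariates[keep] if use_covariates
            else np.empty((keep.sum(), 0))
        )

    def fit(self) -> "TrendResults":
        n = len(self.y)
        X = np.column_stack([np.ones(n), self.score, self.covariates])
        beta, sse = _lstsq_sse(X, self.y)
        df = n - X.shape[1]
        if df < 1:
            raise ValueError("no residual degrees of freedom")
        sigma2 = sse / df
        xtx_inv = np.linalg.inv(X.T @ X)
        se = float(np.sqrt(max(sigma2 * xtx_inv[1, 1], 0.0)))
        slope = float(beta[1])
        if se == 0.0:
            p = 0.0 if slope != 0 else 1.0
            t = np.inf if slope != 0 else 0.0
        else:
            t = slope / se
            p = float(2.0 * stats.t.sf(abs(t), df))
        return TrendResults(slope=slope, se=se, tvalue=float(t), pvalue=p, df=df, n_used=n)


@dataclass
class TrendResults:
    slope: float
    se: float
    tvalue: float
    pvalue: float
    df: int
    n_used: int
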