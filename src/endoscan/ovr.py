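"""One-vs-rest logistic regression per endophenotype, with Wald inference
and explicit Bonferroni multiplicity accounting.

Each endophenotype k is recoded as a binary outcome (1 = k, 0 = others)
and fitted by maximum likelihood,

    endophenotype_k ~ genotype + age + sex + PC1..PC10,

via iteratively reweighted least squares (Newton scoring).  Convergence is
declared when the largest coefficient change falls below 1e-8 (at most 100
iterations); complete or quasi-complete separation is flagged
(``converged = False``, estimates NA) rather than penalized away.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import SampleTable

__all__ = [
    "OneVsRestLogit",
    "OvrResults",
    "fit_ovr",
    "ovr_scan",
    "multiplicity",
    "MultiplicityReport",
]

_MAX_ITER = 100
_TOL = 1e-8
_LINPRED_CAP = 30.0  # |X beta| beyond this on the fit path signals separation


def _irls(X: np.ndarray, y: np.ndarray):
    """Newton/IRLS logistic fit. Returns (beta, cov, converged, n_iter)."""
    n, p = X.shape
    beta = np.zeros(p)
    # start the intercept at the empirical logit for stability
    ybar = y.mean()
    beta[0] = np.log(ybar / (1.0 - ybar))
    converged = False
    for it in range(1, _MAX_ITER + 1):
        eta = X @ beta
        if np.max(np.abs(eta)) > _LINPRED_CAP:
            return beta, None, False, it
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        XtW = X.T * w
        H = XtW @ X
        g = X.T @ (y - mu)
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            return beta, None, False, it
        beta = beta + step
        if np.max(np.abs(step)) < _TOL:
            converged = True
            break
    if not converged:
        return beta, None, False, _MAX_ITER
    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = mu * (1.0 - mu)
    try:
        cov = np.linalg.inv((X.T * w) @ X)
    except np.linalg.LinAlgError:
        return beta, None, False, _MAX_ITER
    return beta, cov, True, it


class OneVsRestLogit:
    """Logistic model of one endophenotype-vs-rest on dosage plus covariates."""

    def __init__(
        self,
        endophenotype: int,
        x: np.ndarray | None,
        st: SampleTable,
        use_covariates: bool = True,
    ):
        if x is None:  # covariates-only reduced model (nested-model checks)
            keep = np.ones(st.n_samples, dtype=bool)
            x_col = np.empty((st.n_samples, 0))
        else:
            x = np.asarray(x, dtype=float)
            if len(x) != st.n_samples:
                raise ValueError("dosage length does not match sample table")
            keep = np.isfinite(x)
            x_col = x[keep, None]
        y = (st.endophenotype[keep] == endophenotype).astype(float)
        if y.min() == y.max():
            raise ValueError(
                f"endophenotype {endophenotype}: only one outcome class present"
            )
        cov = st.covariates[keep] if use_covariates else np.empty((int(keep.sum()), 0))
        self.endophenotype = endophenotype
        self.has_dosage = x is not None
        self.y = y
        self.X = np.column_stack([np.ones(len(y)), x_col, cov])
        self.n_case = int(y.sum())
        self.n_control = int(len(y) - y.sum())

    def fit(self) -> "OvrResults":
        beta, cov, converged, n_iter = _irls(self.X, self.y)
        if not converged or cov is None:
            return OvrResults(
                endophenotype=self.endophenotype, beta=np.nan, se=np.nan,
                OR=np.nan, pvalue=np.nan, converged=False,
                n_case=self.n_case, n_control=self.n_control, n_iter=n_iter,
                deviance=np.nan,
            )
        eta = self.X @ beta
        loglik = float(np.sum(self.y * eta - np.log1p(np.exp(eta))))
        deviance = -2.0 * loglik
        if not self.has_dosage:
            return OvrResults(
                endophenotype=self.endophenotype, beta=np.nan, se=np.nan,
                OR=np.nan, pvalue=np.nan, converged=True,
                n_case=self.n_case, n_control=self.n_control, n_iter=n_iter,
                deviance=deviance,
            )
        b = float(beta[1])
        se = float(np.sqrt(cov[1, 1]))
        z = b / se if se > 0 else np.inf
        p = float(max(2.0 * stats.norm.sf(abs(z)), np.nextafter(0, 1)))
        return OvrResults(
            endophenotype=self.endophenotype, beta=b, se=se, OR=float(np.exp(b)),
            pvalue=p, converged=True, n_case=self.n_case,
            n_control=self.n_control, n_iter=n_iter, deviance=deviance,
        )


@dataclass
class OvrResults:
    """Wald summary for one dosage coefficient in a one-vs-rest fit."""

    endophenotype: int
    beta: float
    se: float
    OR: float
    pvalue: float
    converged: bool
    n_case: int
    n_control: int
    n_iter: int
    deviance: float = float("nan")

    def summary(self) -> str:
        if not self.converged:
            return (f"OVR logit, endophenotype {self.endophenotype}: "
                    f"did not converge (separation suspected)")
        return (f"OVR logit, endophenotype {self.endophenotype}: "
                f"OR = {self.OR:.3f}, beta = {self.beta:.4f} (se {self.se:.4f}), "
                f"p = {self.pvalue:.4g} "
                f"[{self.n_case} vs {self.n_control}]")


def fit_ovr(endophenotype: int, x: np.ndarray, st: SampleTable,
            use_covariates: bool = True) -> OvrResults:
    """Convenience wrapper: build and fit a one-vs-rest logistic model."""
    return OneVsRestLogit(endophenotype, x, st, use_covariates=use_covariates).fit()


def ovr_scan(gm, st: SampleTable, variant_ids=None, use_covariates: bool = True) -> pd.DataFrame:
    """All K one-vs-rest fits for each requested variant.

    Returns ``variant endophenotype n_case n_control beta se OR p converged``.
    """
    ids = variant_ids if variant_ids is not None else [v.id for v in gm.variants]
    rows = []
    for vid in ids:
        x = gm.row(vid)
        for k in st.categories:
            try:
                r = fit_ovr(int(k), x, st, use_covariates=use_covariates)
            except ValueError:
                rows.append({"variant": vid, "endophenotype": int(k),
                             "n_case": np.nan, "n_control": np.nan, "beta": np.nan,
                             "se": np.nan, "OR": np.nan, "p": np.nan,
                             "converged": False})
                continue
            rows.append({"variant": vid, "endophenotype": r.endophenotype,
                         "n_case": r.n_case, "n_control": r.n_control,
                         "beta": r.beta, "se": r.se, "OR": r.OR, "p": r.pvalue,
                         "converged": r.converged})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class MultiplicityReport:
    """Bonferroni accounting over a family of m contrasts.

    ``alpha_adj`` is the exact per-test threshold alpha/m (printed values
    like 0.05/30 = 0.0016 are display rounding); ``n_nominal`` counts
    p < alpha, ``n_bonferroni`` counts p <= alpha_adj.
    """

    m: int
    alpha: float
    alpha_adj: float
    n_nominal: int
    n_bonferroni: int

    @property
    def nominal_fraction(self) -> float:
        return self.n_nominal / self.m

    @property
    def bonferroni_fraction(self) -> float:
        return self.n_bonferroni / self.m


def multiplicity(pvalues, alpha: float = 0.05) -> MultiplicityReport:
    """Count nominal and Bonferroni-significant tests in a p-value family."""
    p = np.asarray(pvalues, dtype=float)
    p = p[np.isfinite(p)]
    m = len(p)
    if m < 1:
        raise ValueError("need at least one p-value")
    alpha_adj = alpha / m
    return MultiplicityReport(
        m=m, alpha=alpha, alpha_adj=alpha_adj,
        n_nominal=int((p < alpha).sum()),
        n_bonferroni=int((p <= alpha_adj).sum()),
    )
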