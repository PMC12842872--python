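"""Studentized-range tail probabilities and Tukey-Kramer post-hoc contrasts.

The studentized range Q(k, df) is the range of k independent standard
normal means divided by an independent estimate of their standard error on
df degrees of freedom.  Its upper tail underlies Tukey's Honestly
Significant Difference: an all-pairs familywise-corrected comparison of
group means.  The tail is evaluated here by composite Gauss-Legendre
quadrature of the classical double-integral representation

    P(Q <= q) = E_s[ k * Int phi(z) (Phi(z) - Phi(z - q s))^(k-1) dz ]

where s = sqrt(chi2_df / df).  Node layouts are cached per (k, df); the
absolute accuracy target is 1e-6.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.optimize import brentq
from scipy.special import ndtr
from scipy.stats import chi

__all__ = ["studentized_range_sf", "tukey_q_critical", "tukey_hsd", "TukeyContrast"]

_INNER_PANELS = 24
_OUTER_PANELS = 32
_GL_NODES = 12
_Z_LO, _Z_HI = -9.0, 9.0


@lru_cache(maxsize=None)
def _gl(n: int):
    return np.polynomial.legendre.leggauss(n)


def _panel_nodes(edges: np.ndarray, n_nodes: int):
    """Gauss-Legendre nodes/weights on each panel defined by ``edges``."""
    x, w = _gl(n_nodes)
    half = np.diff(edges) / 2.0
    mid = (edges[:-1] + edges[1:]) / 2.0
    nodes = (mid[:, None] + half[:, None] * x[None, :]).ravel()
    weights = (half[:, None] * w[None, :]).ravel()
    return nodes, weights


@lru_cache(maxsize=None)
def _inner_grid():
    edges = np.linspace(_Z_LO, _Z_HI, _INNER_PANELS + 1)
    z, wz = _panel_nodes(edges, _GL_NODES)
    phi = np.exp(-0.5 * z * z) / np.sqrt(2.0 * np.pi)
    return z, wz * phi, ndtr(z)


@lru_cache(maxsize=None)
def _outer_grid(df: int):
    """Quadrature of the scale factor s = sqrt(chi2_df/df): panel edges at
    equiprobable quantiles so small df's heavy tail is resolved."""
    dist = chi(df, scale=1.0 / np.sqrt(df))
    probs = np.linspace(1e-10, 1.0 - 1e-10, _OUTER_PANELS + 1)
    edges = dist.ppf(probs)
    s, ws = _panel_nodes(edges, _GL_NODES)
    return s, ws * dist.pdf(s)


def _range_cdf_scaled(w: np.ndarray, k: int, chunk: int = 16384) -> np.ndarray:
    """P(range of k std normals <= w) for an array of widths w >= 0."""
    z, wphi, Phi = _inner_grid()
    out = np.empty_like(w)
    for lo in range(0, len(w), chunk):  # bound the (chunk x nodes) temporary
        wc = w[lo:lo + chunk]
        inner = (Phi[None, :] - ndtr(z[None, :] - wc[:, None])) ** (k - 1)
        out[lo:lo + chunk] = k * (inner @ wphi)
    return np.clip(out, 0.0, 1.0)


def studentized_range_sf(q, k: int, df: int):
    """Upper-tail probability P(Q(k, df) > q) of the studentized range.

    ``q`` may be a scalar or an array (one quadrature pass covers all
    values).  ``df`` may be ``np.inf`` (or any value > 1e6) for the
    limiting range of k standard normals.  Absolute accuracy ~1e-6 over
    the range used by HSD testing.
    """
    scalar = np.isscalar(q)
    qa = np.atleast_1d(np.asarray(q, dtype=float))
    if not np.all(np.isfinite(qa)):
        raise ValueError("q must be finite")
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    pos = qa > 0.0
    cdf = np.zeros_like(qa)
    if pos.any():
        qp = qa[pos]
        if not np.isfinite(df) or df > 1e6:
            cdf[pos] = _range_cdf_scaled(qp, k)
        else:
            df = int(df)
            if df < 1:
                raise ValueError(f"df must be >= 1, got {df}")
            s, ws = _outer_grid(df)
            # (nq x ns) widths evaluated in one inner-quadrature pass
            w = (qp[:, None] * s[None, :]).ravel()
            cdf[pos] = (_range_cdf_scaled(w, k).reshape(len(qp), len(s)) @ ws)
    sf = np.clip(1.0 - cdf, 0.0, 1.0)
    return float(sf[0]) if scalar else sf


@lru_cache(maxsize=None)
def tukey_q_critical(alpha: float, k: int, df: int) -> float:
    """Critical value q with studentized_range_sf(q, k, df) = alpha."""
    return float(brentq(lambda q: studentized_range_sf(q, k, df) - alpha, 1e-6, 60.0,
                        xtol=1e-10))


@dataclass(frozen=True)
class TukeyContrast:
    """One pairwise group contrast with its familywise-adjusted p-value.

    ``diff`` is the (adjusted) mean difference group_a - group_b in dosage
    units.  ``q`` = |diff| / se is on the studentized-range scale because
    the Kramer standard error se = sqrt(MSE * (1/n_a + 1/n_b) / 2) already
    carries the factor 1/sqrt(2); equivalently q = t * sqrt(2) for the
    pairwise pooled-t statistic.
    """

    group_a: int
    group_b: int
    diff: float
    se: float
    q: float
    p_adj: float


def tukey_hsd(
    means: np.ndarray,
    mse: float,
    group_sizes: np.ndarray,
    df2: int,
    groups: np.ndarray | None = None,
    var_factors: np.ndarray | None = None,
) -> list[TukeyContrast]:
    """All K(K-1)/2 Tukey contrasts between (adjusted) group means.

    By default unequal group sizes use the Tukey-Kramer standard error
    se_ab = sqrt(MSE * (1/n_a + 1/n_b) / 2), exact for one-way layouts.
    When the means are covariate-adjusted (least-squares) means, pass
    ``var_factors``: a k x k matrix with Var(mean_a - mean_b) / sigma^2,
    i.e. the design-based contrast variance (e_a - e_b)'(X'X)^-1(e_a - e_b).
    Without covariates that factor equals 1/n_a + 1/n_b, so Kramer is the
    special case.  Each contrast's familywise-adjusted p-value is the
    studentized-range tail at q = |diff| / se_ab with K groups and
    ``df2`` error degrees of freedom.
    """
    means = np.asarray(means, dtype=float)
    sizes = np.asarray(group_sizes)
    k = len(means)
    if k < 2:
        raise ValueError("need at least 2 groups")
    if mse <= 0:
        raise ValueError(f"MSE must be positive, got {mse}")
    if np.any(sizes < 2):
        raise ValueError("every group needs n >= 2")
    labels = np.arange(1, k + 1) if groups is None else np.asarray(groups)
    out = []
    for a in range(k):
        for b in range(a + 1, k):
            diff = means[a] - means[b]
            vf = (1.0 / sizes[a] + 1.0 / sizes[b]) if var_factors is None \
                else float(var_factors[a, b])
            se = float(np.sqrt(mse * vf / 2.0))
            q = abs(diff) / se
            p = studentized_range_sf(q, k, df2)
            out.append(TukeyContrast(int(labels[a]), int(labels[b]), float(diff), se, float(q), p))
    return out
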