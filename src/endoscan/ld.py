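"""Dosage-based linkage-disequilibrium and greedy clumping.

LD between two variants is the squared Pearson correlation of their
dosage vectors over pairwise-complete samples.  Clumping is greedy: the
best remaining p-value becomes an index variant and sweeps away every
remaining variant on the same chromosome that shares a sliding window
with it (windows of ``window`` variants advancing by ``step``) and has
r^2 >= ``r2_max`` with it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import GenotypeMatrix

log = logging.getLogger(__name__)

__all__ = ["ClumpParams", "dosage_r2", "clump"]


@dataclass(frozen=True)
class ClumpParams:
    """Window (variant count), step, and r^2 ceiling for clumping.

    Windows are variant-count based, not kilobase based; a kb mode is
    available through ``window_kb``.
    """

    window: int = 250
    step: int = 50
    r2_max: float = 0.5
    window_kb: float | None = None

    def __post_init__(self) -> None:
        if not (0 < self.step <= self.window):
            raise ValueError(f"need 0 < step <= window, got {self.step}, {self.window}")
        if not (0.0 < self.r2_max < 1.0):
            raise ValueError(f"r2_max must lie in (0,1), got {self.r2_max}")


def dosage_r2(d1: np.ndarray, d2: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors, pairwise-complete."""
    d1 = np.asarray(d1, dtype=float)
    d2 = np.asarray(d2, dtype=float)
    keep = np.isfinite(d1) & np.isfinite(d2)
    if keep.sum() < 3:
        raise ValueError("need at least 3 pairwise-complete samples")
    if keep.mean() < 0.8:
        log.warning("r2 computed on only %.0f%% of samples", 100 * keep.mean())
    a, b = d1[keep], d2[keep]
    va, vb = a.var(), b.var()
    if va == 0.0 or vb == 0.0:
        raise ValueError("r2 undefined for a constant dosage vector")
    cov = np.mean((a - a.mean()) * (b - b.mean()))
    return float(cov * cov / (va * vb))


def _shares_window(i: int, j: int, window: int, step: int) -> bool:
    """Whether sorted positions i and j fall inside a common sliding window
    [s, s + window) with s a multiple of step."""
    lo, hi = (i, j) if i <= j else (j, i)
    if hi - lo >= window:
        return False
    s_min = max(0, hi - window + 1)
    s_candidate = -(-s_min // step) * step  # smallest multiple of step >= s_min
    return s_candidate <= lo


def clump(
    results: pd.DataFrame,
    gm: GenotypeMatrix,
    params: ClumpParams = ClumpParams(),
) -> pd.DataFrame:
    """Greedy LD clumping of scan results.

    ``results`` needs columns ``variant``, ``chrom``, ``pos``, ``p``; all
    referenced variants must be in ``gm``.  Ties in p are broken by
    (chrom, pos, variant) so output is deterministic.  Variants whose r^2
    with an index cannot be computed are retained conservatively.

    Returns a table ``index_variant chrom pos p n_clumped members``.
    """
    if results.empty:
        return pd.DataFrame(columns=["index_variant", "chrom", "pos", "p", "n_clumped", "members"])
    df = results[["variant", "chrom", "pos", "p"]].copy()
    missing = [v for v in df["variant"] if v not in gm]
    if missing:
        raise ValueError(f"variants absent from genotype matrix: {missing[:5]}")
    df = df.sort_values(["p", "chrom", "pos", "variant"], kind="mergesort").reset_index(drop=True)

    # per-chromosome variant ranks in position order, for window arithmetic
    rank: dict[str, dict[str, int]] = {}
    for chrom in df["chrom"].unique():
        sub = df[df["chrom"] == chrom].sort_values(["pos", "variant"], kind="mergesort")
        rank[chrom] = {v: i for i, v in enumerate(sub["variant"])}

    alive = dict.fromkeys(df["variant"], True)
    rows = []
    for _, row in df.iterrows():
        vid = row["variant"]
        if not alive[vid]:
            continue
        alive[vid] = False
        members = []
        d_index = gm.row(vid)
        ri = rank[row["chrom"]][vid]
        same_chrom = df[(df["chrom"] == row["chrom"])]
        for _, other in same_chrom.iterrows():
            ov = other["variant"]
            if not alive[ov]:
                continue
            if params.window_kb is not None:
                in_window = abs(other["pos"] - row["pos"]) <= params.window_kb * 1000.0
            else:
                in_window = _shares_window(ri, rank[row["chrom"]][ov], params.window, params.step)
            if not in_window:
                continue
            try:
                r2 = dosage_r2(d_index, gm.row(ov))
            except ValueError as exc:
                log.warning("retaining %s: r2 vs %s failed (%s)", ov, vid, exc)
                continue
            if r2 >= params.r2_max:
                alive[ov] = False
                members.append(ov)
        rows.append({
            "index_variant": vid, "chrom": row["chrom"], "pos": row["pos"],
            "p": row["p"], "n_clumped": len(members), "members": ",".join(members),
        })
    return pd.DataFrame(rows)
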