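"""Minimal plots: Manhattan, per-group MAF bars, and one-vs-rest ROC."""

from __future__ import annotations

import numpy as np
import pandas as pd

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

__all__ = ["manhattan", "maf_bars", "roc_curves"]


def manhattan(results: pd.DataFrame, out_path, alpha_gw: float = 5e-8):
    """Manhattan plot from a scan table (columns chrom, pos, p)."""
    fig, ax = plt.subplots(figsize=(9, 3))
    offset = 0
    for i, (chrom, sub) in enumerate(results.groupby("chrom", sort=False)):
        sub = sub.sort_values("pos")
        x = offset + np.arange(len(sub))
        ax.scatter(x, -np.log10(sub["p"]), s=4, color=f"C{i % 2}")
        offset += len(sub)
    ax.axhline(-np.log10(alpha_gw), ls="--", color="grey")
    ax.set_xlabel("variant (ordered by chromosome, position)")
    ax.set_ylabel(r"$-\log_{10} p$")
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)


def maf_bars(maf_table: pd.DataFrame, out_path):
    """Bar chart of per-endophenotype MAF for each variant row."""
    maf_cols = [c for c in maf_table.columns if c.startswith("maf_")]
    k = len(maf_cols)
    n = len(maf_table)
    fig, ax = plt.subplots(figsize=(1.2 * n * k / 5 + 2, 3))
    width = 0.8 / k
    for j, col in enumerate(maf_cols):
        ax.bar(np.arange(n) + j * width, maf_table[col], width, label=col.replace("maf_", "endo "))
    ax.set_xticks(np.arange(n) + 0.4, maf_table["variant"], rotation=45, ha="right", fontsize=7)
    ax.set_ylabel("minor-allele frequency")
    ax.legend(fontsize=6, ncols=k)
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)


def roc_curves(roc_points: pd.DataFrame, out_path):
    """One-vs-rest ROC curves (columns endophenotype, fpr, tpr)."""
    fig, ax = plt.subplots(figsize=(4, 4))
    for k, sub in roc_points.groupby("endophenotype"):
        ax.plot(sub["fpr"], sub["tpr"], lw=1, label=f"endo {k}")
    ax.plot([0, 1], [0, 1], ls="--", color="grey", lw=0.8)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
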