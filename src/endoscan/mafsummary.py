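"""Per-endophenotype allele-frequency tables, delta-MAF, and cross-cohort
direction concordance.

Group frequencies are folded on the *pooled* sample: the minor allele is
chosen once per variant from the whole cohort and every group frequency is
reported for that same allele, so between-group differences are
comparable and allele relabeling leaves the table unchanged.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort import GenotypeMatrix, SampleTable

__all__ = ["group_maf", "maf_table", "direction_concordance"]


def group_maf(gm: GenotypeMatrix, st: SampleTable, variant_id: str) -> np.ndarray:
    """Per-group minor-allele frequency for one variant (pooled fold).

    Groups whose dosages are all missing get nan.
    """
    d = gm.row(variant_id).astype(float)
    finite = np.isfinite(d)
    if not finite.any():
        raise ValueError(f"variant {variant_id}: all dosages missing")
    if d[finite].mean() / 2.0 > 0.5:
        d = 2.0 - d  # fold once, on the pooled frequency
    out = np.full(st.k, np.nan)
    for j, c in enumerate(st.categories):
        mask = (st.endophenotype == c) & finite
        if mask.any():
            out[j] = d[mask].mean() / 2.0
    return out


def maf_table(gm: GenotypeMatrix, st: SampleTable, variant_ids=None,
              contrast_table: pd.DataFrame | None = None) -> pd.DataFrame:
    """Group-frequency table ``variant maf_1..K delta_max`` for the given
    variants, plus per-contrast deltas when a Tukey contrast table is
    supplied (columns ``variant group_a group_b``, typically the
    significant contrasts from a scan)."""
    ids = variant_ids if variant_ids is not None else [v.id for v in gm.variants]
    rows = []
    for vid in ids:
        freqs = group_maf(gm, st, vid)
        rec = {"variant": vid}
        for c, f in zip(st.categories, freqs):
            rec[f"maf_{c}"] = f
        rec["delta_max"] = float(np.nanmax(freqs) - np.nanmin(freqs))
        rows.append(rec)
    table = pd.DataFrame(rows)
    if contrast_table is not None and not contrast_table.empty:
        deltas = []
        for _, r in contrast_table.iterrows():
            row = table[table["variant"] == r["variant"]]
            if row.empty:
                continue
            deltas.append({
                "variant": r["variant"], "group_a": int(r["group_a"]),
                "group_b": int(r["group_b"]),
                "delta_maf": float(row[f"maf_{int(r['group_a'])}"].iloc[0]
                                   - row[f"maf_{int(r['group_b'])}"].iloc[0]),
            })
        table.attrs["contrast_deltas"] = pd.DataFrame(deltas)
    return table


def _severity_gradient(row: pd.Series, categories) -> float:
    """Mean MAF in the two most severe groups minus the two mildest."""
    cats = sorted(categories)
    mild = [row[f"maf_{c}"] for c in cats[:2]]
    severe = [row[f"maf_{c}"] for c in cats[-2:]]
    return float(np.nanmean(severe) - np.nanmean(mild))


def direction_concordance(
    summary_a: pd.DataFrame, summary_b: pd.DataFrame, variant_ids=None
) -> pd.DataFrame:
    """Cross-cohort direction agreement of the severity MAF gradient.

    A variant is concordant when the sign of (mean MAF in the two most
    severe groups minus mean MAF in the two mildest) agrees between the
    two summaries.  Returns ``variant gradient_a gradient_b concordant``
    with the totals in ``DataFrame.attrs["n_concordant"]`` /
    ``attrs["n_total"]``.
    """
    ids = variant_ids if variant_ids is not None else list(summary_a["variant"])
    a = summary_a.set_index("variant")
    b = summary_b.set_index("variant")
    maf_cols = [c for c in summary_a.columns if c.startswith("maf_")]
    cats = [int(c.split("_")[1]) for c in maf_cols]
    rows = []
    for vid in ids:
        if vid not in a.index or vid not in b.index:
            raise ValueError(f"variant {vid} absent from one summary")
        ga = _severity_gradient(a.loc[vid], cats)
        gb = _severity_gradient(b.loc[vid], cats)
        rows.append({"variant": vid, "gradient_a": ga, "gradient_b": gb,
                     "concordant": bool(np.sign(ga) == np.sign(gb))})
    out = pd.DataFrame(rows, columns=["variant", "gradient_a", "gradient_b", "concordant"])
    out.attrs["n_concordant"] = int(out["concordant"].sum()) if len(out) else 0
    out.attrs["n_total"] = len(out)
    return out
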