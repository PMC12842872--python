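"""Published summary statistics for the six replicated severity-endophenotype
loci in the CAMP (discovery) and GACRS (replication) childhood-asthma
cohorts.

These small tables are shipped so that the significance-accounting
machinery (Bonferroni bookkeeping over one-vs-rest contrasts, post-hoc
contrast counting) can be exercised on real published numbers without any
individual-level data.  They carry, per locus: the ANCOVA F statistic and
p-value in each cohort, the Tukey-corrected pairwise contrasts that
remained significant, and the one-vs-rest odds ratio and p-value for each
of the five endophenotypes.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "six_locus_ancova",
    "ovr_summary",
    "published_contrasts",
    "ovr_pvalues",
]

_LOCI = ["rs10964536", "rs28892326", "rs2823880", "rs10086065", "rs12448208", "rs2754324"]
_REGIONS = ["9p21.3", "7q33", "21q21.1", "8p23.1", "16q12.1", "9p22.2"]

_ANCOVA = {
    # snp: (F_camp, p_camp, contrasts_camp, F_gacrs, p_gacrs, contrasts_gacrs)
    "rs10964536": (12.03, 1.71e-9, ["4-1", "5-1", "4-3"], 3.23, 0.0121, ["5-1"]),
    "rs28892326": (11.92, 2.11e-9, ["4-1", "5-1"], 3.04, 0.0166, ["5-2"]),
    "rs2823880": (11.43, 5.09e-9, ["4-1", "5-1"], 5.12, 0.0004, ["4-1", "4-2", "4-3"]),
    "rs10086065": (11.42, 5.23e-9, ["4-1", "5-1"], 2.53, 0.0390, ["4-1"]),
    "rs12448208": (10.35, 3.59e-8, ["2-1", "4-1"], 2.81, 0.0246, ["5-1"]),
    "rs2754324": (10.29, 4.00e-8, ["4-1", "4-3"], 2.73, 0.0282, ["5-3"]),
}

# (OR, p) per endophenotype 1..5, cohorts CAMP then GACRS
_OVR = {
    "rs10964536": ([(1.97, 0.0010), (0.97, 0.841), (1.30, 0.129), (0.65, 0.0028), (0.78, 0.088)],
                   [(1.37, 0.749), (1.04, 0.273), (0.86, 0.029), (1.21, 0.168), (0.70, 0.0053)]),
    "rs28892326": ([(3.44, 0.0007), (1.00, 0.995), (1.05, 0.815), (0.75, 0.098), (0.68, 0.021)],
                   [(1.61, 0.0304), (1.86, 0.541), (0.87, 0.077), (0.81, 0.323), (0.62, 0.019)]),
    "rs2823880": ([(1.95, 0.0031), (1.01, 0.952), (1.10, 0.590), (0.75, 0.054), (0.77, 0.085)],
                  [(1.47, 0.149), (1.45, 0.100), (1.55, 0.136), (0.44, 4e-5), (0.93, 0.733)]),
    "rs10086065": ([(2.24, 0.0016), (0.90, 0.550), (1.10, 0.581), (0.70, 0.021), (0.86, 0.321)],
                   [(1.44, 0.374), (1.22, 0.818), (1.05, 0.117), (0.57, 0.0029), (1.07, 0.746)]),
    "rs12448208": ([(2.56, 0.0022), (0.66, 0.017), (1.37, 0.160), (0.63, 0.0083), (1.06, 0.755)],
                   [(0.60, 0.183), (1.35, 0.373), (1.22, 0.0068), (0.81, 0.279), (1.44, 0.111)]),
    "rs2754324": ([(1.56, 0.0288), (1.05, 0.798), (1.41, 0.077), (0.56, 0.0001), (0.96, 0.798)],
                  [(0.93, 0.558), (1.16, 0.0162), (2.05, 0.762), (0.98, 0.946), (0.58, 0.0088)]),
}


def six_locus_ancova() -> pd.DataFrame:
    """ANCOVA F, p, and significant Tukey contrasts per locus and cohort."""
    rows = []
    for snp, region in zip(_LOCI, _REGIONS):
        fc, pc, cc, fg, pg, cg = _ANCOVA[snp]
        rows.append({
            "variant": snp, "region": region,
            "F_camp": fc, "p_camp": pc, "posthoc_camp": ";".join(cc),
            "F_gacrs": fg, "p_gacrs": pg, "posthoc_gacrs": ";".join(cg),
        })
    return pd.DataFrame(rows)


def ovr_summary() -> pd.DataFrame:
    """One-vs-rest OR and p per locus, endophenotype, and cohort."""
    rows = []
    for snp in _LOCI:
        camp, gacrs = _OVR[snp]
        for cohort, vals in [("CAMP", camp), ("GACRS", gacrs)]:
            for k, (orat, p) in enumerate(vals, start=1):
                rows.append({"variant": snp, "cohort": cohort,
                             "endophenotype": k, "OR": orat, "p": p})
    return pd.DataFrame(rows)


def ovr_pvalues(cohort: str = "CAMP") -> list[float]:
    """The 30 one-vs-rest p-values (6 loci x 5 endophenotypes) for a cohort."""
    df = ovr_summary()
    return df.loc[df["cohort"] == cohort.upper(), "p"].tolist()


def published_contrasts(cohort: str = "CAMP") -> pd.DataFrame:
    """Tukey-corrected contrasts reported significant, as a contrast table
    (``variant group_a group_b significant``)."""
    col = 2 if cohort.upper() == "CAMP" else 5
    rows = []
    for snp in _LOCI:
        for c in _ANCOVA[snp][col]:
            a, b = c.split("-")
            rows.append({"variant": snp, "group_a": int(a), "group_b": int(b),
                         "significant": True})
    return pd.DataFrame(rows)
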