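"""VCF input/output for dosage matrices.

Reading goes through cyvcf2 and supports either imputed dosages (FORMAT/DS)
or hard genotype calls (FORMAT/GT, converted to alternate-allele counts).
Writing produces a minimal VCF 4.2 with both GT (rounded) and DS fields so
fixtures and simulated cohorts round-trip through the same reader.
"""

from __future__ import annotations

import logging

import numpy as np
from cyvcf2 import VCF

from .cohort import GenotypeMatrix, Variant

log = logging.getLogger(__name__)

__all__ = ["read_genotypes", "write_vcf"]


def read_genotypes(path, dosage_source: str = "GT") -> GenotypeMatrix:
    """Read a (optionally bgzipped) VCF into a GenotypeMatrix.

    Parameters
    ----------
    path : str
        VCF path; plain or bgzip-compressed.
    dosage_source : {"GT", "DS"}
        "DS" copies the per-sample dosage field; "GT" converts diploid
        calls to alt-allele counts (0/0 -> 0, 0/1 -> 1, 1/1 -> 2,
        ./. -> missing).

    Multi-allelic records are skipped with a warning; the scan targets
    biallelic common variants.
    """
    if dosage_source not in ("GT", "DS"):
        raise ValueError(f"dosage_source must be 'GT' or 'DS', got {dosage_source!r}")
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    variants: list[Variant] = []
    rows: list[np.ndarray] = []
    n_skipped = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            n_skipped += 1
            log.warning("skipping multi-allelic record %s:%s (%s)", rec.CHROM, rec.POS, rec.ID)
            continue
        vid = rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}:{rec.REF}:{rec.ALT[0]}"
        if dosage_source == "DS":
            try:
                ds = rec.format("DS")
            except KeyError:
                ds = None
            if ds is None:
                raise ValueError(f"variant {vid}: FORMAT/DS field absent")
            row = np.asarray(ds, dtype=float).reshape(-1)
            row = np.where((row < 0) | (row > 2), np.nan, row)
        else:
            gts = rec.genotypes  # [allele_a, allele_b, phased]
            row = np.empty(len(samples))
            for j, g in enumerate(gts):
                if len(g) != 3:
                    raise ValueError(
                        f"variant {vid}, sample {samples[j]}: non-diploid GT with "
                        f"{len(g) - 1} allele(s)"
                    )
                a, b = g[0], g[1]
                row[j] = np.nan if (a < 0 or b < 0) else float(a + b)
        variants.append(Variant(vid, str(rec.CHROM), int(rec.POS), rec.REF, rec.ALT[0]))
        rows.append(row)
    if n_skipped:
        log.warning("skipped %d multi-allelic records", n_skipped)
    dosage = np.vstack(rows) if rows else np.empty((0, len(samples)))
    return GenotypeMatrix(variants, samples, dosage)


def write_vcf(gm: GenotypeMatrix, path) -> None:
    """Write a GenotypeMatrix as uncompressed VCF 4.2 with GT and DS fields.

    Dosages are written to 3 decimals; GT is the nearest-integer hard call
    (./. for missing).  read_genotypes(write_vcf(gm), "DS") recovers the
    dosages to that precision.
    """
    chroms = []
    for v in gm.variants:
        if v.chrom not in chroms:
            chroms.append(v.chrom)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=endoscan\n")
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Alt allele dosage">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(gm.samples) + "\n")
        gt_codes = {0: "0/0", 1: "0/1", 2: "1/1"}
        for i, v in enumerate(gm.variants):
            fields = [v.chrom, str(v.pos), v.id, v.ref, v.alt, ".", "PASS", ".", "GT:DS"]
            for d in gm.dosage[i]:
                if np.isnan(d):
                    fields.append("./.:.")
                else:
                    fields.append(f"{gt_codes[int(round(d))]}:{d:.3f}")
            fh.write("\t".join(fields) + "\n")
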