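"""Core in-memory containers: variants, dosage matrices, and sample metadata.

The analysis is a *reverse regression*: genotype dosage is the response and
the categorical endophenotype (K ordinal severity classes, typically five)
is the factor of interest, with age, sex, and ancestry principal components
as covariates.  These containers carry exactly what that design needs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Variant",
    "GenotypeMatrix",
    "SampleTable",
    "read_sample_table",
    "write_sample_table",
]


@dataclass(frozen=True)
class Variant:
    """A biallelic variant keyed by rsID or ``chrom:pos:ref:alt``.

    Coordinates are 1-based (VCF convention); assembly labels such as
    GRCh38 pass through unvalidated.
    """

    id: str
    chrom: str
    pos: int
    ref: str = "A"
    alt: str = "G"

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"variant {self.id}: pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"variant {self.id}: ref and alt alleles are identical")


class GenotypeMatrix:
    """Variants x samples dosage matrix with variant metadata.

    Dosages are expected alternate-allele counts in [0, 2]; missing calls
    are ``nan``.  Rows follow ``variants`` order, columns follow ``samples``.
    """

    def __init__(self, variants: list[Variant], samples: list[str], dosage: np.ndarray):
        dosage = np.asarray(dosage, dtype=float)
        if dosage.shape != (len(variants), len(samples)):
            raise ValueError(
                f"dosage shape {dosage.shape} does not match "
                f"{len(variants)} variants x {len(samples)} samples"
            )
        finite = dosage[np.isfinite(dosage)]
        if finite.size and (finite.min() < 0 or finite.max() > 2):
            raise ValueError("dosages must lie in [0, 2]")
        ids = [v.id for v in variants]
        if len(set(ids)) != len(ids):
            raise ValueError("variant ids must be unique within a GenotypeMatrix")
        if len(set(samples)) != len(samples):
            raise ValueError("sample ids must be unique")
        self.variants = list(variants)
        self.samples = list(samples)
        self.dosage = dosage
        self._index = {vid: i for i, vid in enumerate(ids)}

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def row(self, variant_id: str) -> np.ndarray:
        """Dosage vector for one variant."""
        return self.dosage[self._index[variant_id]]

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self._index

    def subset(self, variant_ids=None, sample_ids=None) -> "GenotypeMatrix":
        """Return a new matrix restricted to the given variants/samples (order kept)."""
        if variant_ids is None:
            rows = np.arange(self.n_variants)
        else:
            rows = np.array([self._index[v] for v in variant_ids])
        if sample_ids is None:
            cols = np.arange(self.n_samples)
        else:
            pos = {s: j for j, s in enumerate(self.samples)}
            cols = np.array([pos[s] for s in sample_ids])
        return GenotypeMatrix(
            [self.variants[i] for i in rows],
            [self.samples[j] for j in cols],
            self.dosage[np.ix_(rows, cols)],
        )

    def __repr__(self) -> str:
        return f"GenotypeMatrix({self.n_variants} variants x {self.n_samples} samples)"


@dataclass
class SampleTable:
    """Per-sample design data: endophenotype category, age, sex, ancestry PCs.

    ``endophenotype`` holds integer category labels 1..K (K >= 2, every
    category present at least twice so the factor is testable); ``sex`` is
    a consistent binary code; ``pcs`` is samples x n_pcs.
    """

    sample_id: np.ndarray
    endophenotype: np.ndarray
    age: np.ndarray
    sex: np.ndarray
    pcs: np.ndarray
    n_pcs_expected: int = field(default=10, repr=False)

    def __post_init__(self) -> None:
        self.sample_id = np.asarray(self.sample_id, dtype=object)
        self.endophenotype = np.asarray(self.endophenotype, dtype=int)
        self.age = np.asarray(self.age, dtype=float)
        self.sex = np.asarray(self.sex, dtype=float)
        self.pcs = np.atleast_2d(np.asarray(self.pcs, dtype=float))
        n = len(self.sample_id)
        for name, arr in [("endophenotype", self.endophenotype), ("age", self.age), ("sex", self.sex)]:
            if len(arr) != n:
                raise ValueError(f"{name} length {len(arr)} != {n} samples")
        if self.pcs.shape[0] != n:
            raise ValueError(f"pcs have {self.pcs.shape[0]} rows, expected {n}")
        if len(set(self.sample_id)) != n:
            raise ValueError("sample ids must be unique")
        labels, counts = np.unique(self.endophenotype, return_counts=True)
        if len(labels) < 2:
            raise ValueError("need at least 2 endophenotype categories")
        thin = labels[counts < 2]
        if thin.size:
            raise ValueError(f"endophenotype categories with <2 samples: {thin.tolist()}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_id)

    @property
    def categories(self) -> np.ndarray:
        """Sorted distinct endophenotype labels."""
        return np.unique(self.endophenotype)

    @property
    def k(self) -> int:
        return len(self.categories)

    @property
    def covariates(self) -> np.ndarray:
        """Covariate block [age, sex, PC1..PCn], samples x (2 + n_pcs)."""
        return np.column_stack([self.age, self.sex, self.pcs])

    def subset(self, sample_ids) -> "SampleTable":
        pos = {s: j for j, s in enumerate(self.sample_id)}
        idx = np.array([pos[s] for s in sample_ids])
        return SampleTable(
            self.sample_id[idx], self.endophenotype[idx], self.age[idx],
            self.sex[idx], self.pcs[idx], self.n_pcs_expected,
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "sample_id": self.sample_id,
            "endophenotype": self.endophenotype,
            "age": self.age,
            "sex": self.sex.astype(int),
        })
        for j in range(self.pcs.shape[1]):
            df[f"pc{j + 1}"] = self.pcs[:, j]
        return df


def read_sample_table(path, n_pcs: int = 10) -> SampleTable:
    """Read a TSV with header ``sample_id endophenotype age sex pc1..pcN``."""
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "endophenotype", "age", "sex"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"sample table missing columns: {sorted(missing)}")
    pc_cols = [c for c in df.columns if c.startswith("pc") and c[2:].isdigit()]
    pc_cols.sort(key=lambda c: int(c[2:]))
    if len(pc_cols) != n_pcs:
        raise ValueError(f"expected {n_pcs} PC columns, found {len(pc_cols)}")
    return SampleTable(
        df["sample_id"].to_numpy(dtype=object),
        df["endophenotype"].to_numpy(),
        df["age"].to_numpy(),
        df["sex"].to_numpy(),
        df[pc_cols].to_numpy(),
        n_pcs_expected=n_pcs,
    )


def write_sample_table(st: SampleTable, path) -> None:
    st.to_frame().to_csv(path, sep="\t", index=False)
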