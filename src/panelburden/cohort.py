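"""In-memory cohort model: variant sites, genotype matrix, annotations, phenotypes.

The genotype matrix stores allele dosage (count of non-reference alleles per
diploid genotype) as a small integer array with ``MISSING`` (-1) marking
uncalled genotypes.  All downstream stages — site QC, ancestry PCA and the
carrier-collapsing burden test — operate on this container.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Sentinel dosage for a missing (uncalled or half-called) genotype.
MISSING: int = -1

_VALID_BASES = set("ACGTN")


@dataclass(frozen=True)
class VariantSite:
    """A called variant locus on the panel.

    ``site_id`` is the stable key ``chrom:pos:ref:alt`` (first ALT for
    multi-allelic records, which site QC removes anyway).
    """

    chrom: str
    pos: int
    ref: str
    alt_alleles: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        for allele in (self.ref, *self.alt_alleles):
            if not allele or set(allele.upper()) - _VALID_BASES:
                raise ValueError(f"invalid allele {allele!r} at {self.chrom}:{self.pos}")

    @property
    def n_alt_alleles(self) -> int:
        return len(self.alt_alleles)

    @property
    def site_id(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt_alleles[0]}"


@dataclass
class GenotypeMatrix:
    """samples x sites dosage matrix with values in {0, 1, 2, MISSING}."""

    samples: list[str]
    sites: list[VariantSite]
    dosage: np.ndarray  # int8, shape (n_samples, n_sites)

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.shape != (len(self.samples), len(self.sites)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} inconsistent with "
                f"{len(self.samples)} samples x {len(self.sites)} sites"
            )
        bad = ~np.isin(self.dosage, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError(f"dosage contains values outside {{0,1,2,{MISSING}}}")
        ids = self.site_ids
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate site_id in cohort")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def site_ids(self) -> list[str]:
        return [s.site_id for s in self.sites]

    def sample_index(self, names: list[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        missing = [n for n in names if n not in lookup]
        if missing:
            raise KeyError(f"samples absent from genotype matrix: {missing[:5]}")
        return np.array([lookup[n] for n in names], dtype=int)

    def subset_sites(self, keep: list[str]) -> "GenotypeMatrix":
        keep_set = set(keep)
        idx = [i for i, sid in enumerate(self.site_ids) if sid in keep_set]
        return GenotypeMatrix(
            samples=list(self.samples),
            sites=[self.sites[i] for i in idx],
            dosage=self.dosage[:, idx].copy(),
        )


@dataclass(frozen=True)
class AnnotatedVariant:
    """A variant site joined to its functional annotation and predictor scores.

    Unknown numeric scores / frequencies are ``None``.  ``mutation_taster`` is
    the categorical prediction symbol (D = disease-causing) or ``None``.
    """

    site_id: str
    gene: str
    func_region: str
    exonic_func: str
    exac_af: float | None
    polyphen2: float | None
    sift: float | None
    mutation_taster: str | None
    orphan: bool = False  # annotation row without a genotyped counterpart

    def __post_init__(self) -> None:
        for name in ("polyphen2", "sift"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} score {v} outside [0,1] for {self.site_id}")
        if self.exac_af is not None and not (0.0 <= self.exac_af <= 1.0):
            raise ValueError(f"exac_af {self.exac_af} outside [0,1] for {self.site_id}")


@dataclass
class PhenotypeTable:
    """Case/control labels plus case-only phenotype subgroups (e.g. ASD)."""

    table: pd.DataFrame = field(repr=False)  # index sample_id; columns: group, subgroups

    def __post_init__(self) -> None:
        t = self.table
        if t.index.has_duplicates:
            dup = t.index[t.index.duplicated()].tolist()
            raise ValueError(f"duplicate sample_id: {dup[:5]}")
        bad = set(t["group"]) - {"case", "control"}
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")
        for sid, row in t.iterrows():
            if row["group"] == "control" and row["subgroups"]:
                raise ValueError(f"control sample {sid} carries subgroup labels")

    @property
    def samples(self) -> list[str]:
        return list(self.table.index)

    @property
    def cases(self) -> list[str]:
        return list(self.table.index[self.table["group"] == "case"])

    @property
    def controls(self) -> list[str]:
        return list(self.table.index[self.table["group"] == "control"])

    def in_subgroup(self, label: str) -> list[str]:
        return [s for s, sg in self.table["subgroups"].items() if label in sg]

    def group_counts(self) -> tuple[int, int]:
        return len(self.cases), len(self.controls)
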