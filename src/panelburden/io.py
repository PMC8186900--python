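"""Readers for the three cohort inputs and the shared results writer.

Genotypes come from a VCF (plain or bgzipped, read with cyvcf2); the
annotation and phenotype tables are TSV.  Half-called genotypes count as
missing; phased separators are treated like unphased ones.  Unknown ExAC
frequency ('.') is kept as unknown here and interpreted as "absent from the
reference database, hence rare" by the damaging filter.
"""

from __future__ import annotations

import logging
import os
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .cohort import MISSING, AnnotatedVariant, GenotypeMatrix, PhenotypeTable, VariantSite

log = logging.getLogger(__name__)

_ANNOTATION_COLUMNS = ["Gene", "Func", "ExonicFunc", "ExAC_ALL", "Polyphen2", "SIFT", "MutationTaster"]


def read_genotypes(vcf_path: str | os.PathLike, sample_filter: list[str] | None = None) -> GenotypeMatrix:
    """Load a multi-sample VCF into a dosage matrix.

    One column per VCF record; multi-allelic records are retained (site QC
    excludes them by alt-allele count).  Dosage is the number of non-reference
    alleles in GT; any genotype containing a missing allele is missing.
    Sample order follows the VCF header restricted to ``sample_filter``.
    """
    vcf_path = Path(vcf_path)
    if not vcf_path.exists():
        raise FileNotFoundError(vcf_path)
    vcf = VCF(str(vcf_path), gts012=False)
    header_samples = list(vcf.samples)
    if sample_filter is not None:
        absent = [s for s in sample_filter if s not in header_samples]
        if absent:
            raise KeyError(f"sample_filter names absent from VCF header: {absent[:5]}")
        samples = [s for s in header_samples if s in set(sample_filter)]
    else:
        samples = header_samples
    col_idx = [header_samples.index(s) for s in samples]

    sites: list[VariantSite] = []
    columns: list[np.ndarray] = []
    saw_gt = False
    for rec in vcf:
        if "GT" in (rec.FORMAT or ""):
            saw_gt = True
        # rec.genotypes: [allele_a, allele_b, phased]; -1 marks a missing allele
        dos = np.empty(len(col_idx), dtype=np.int8)
        for out_i, vcf_i in enumerate(col_idx):
            g = rec.genotypes[vcf_i]
            alleles = g[:-1]
            if any(a < 0 for a in alleles):
                dos[out_i] = MISSING
            else:
                dos[out_i] = sum(1 for a in alleles if a > 0)
        sites.append(VariantSite(rec.CHROM, rec.POS, rec.REF, tuple(rec.ALT)))
        columns.append(dos)
    if sites and not saw_gt:
        raise ValueError(f"VCF {vcf_path} has no GT genotype field")
    dosage = (
        np.stack(columns, axis=1) if columns else np.empty((len(samples), 0), dtype=np.int8)
    )
    return GenotypeMatrix(samples=samples, sites=sites, dosage=dosage)


def _parse_score(raw: object) -> float | None:
    try:
        v = float(raw)  # type: ignore[arg-type]
    except (TypeError, ValueError):
        return None
    return None if np.isnan(v) else v


def read_annotations(
    table_path: str | os.PathLike, known_site_ids: set[str] | None = None
) -> list[AnnotatedVariant]:
    """Read the per-variant annotation TSV into :class:`AnnotatedVariant` rows.

    Accepts either a ``site_id`` column or the (chrom, pos, ref, alt) quartet.
    Unparseable numeric scores become unknown.  Rows whose site_id has no
    genotyped counterpart (per ``known_site_ids``) are retained but flagged
    orphan and counted to the log.
    """
    df = pd.read_csv(table_path, sep="\t", dtype=str, comment="#")
    return annotations_from_frame(df, known_site_ids)


def annotations_from_frame(
    df: pd.DataFrame, known_site_ids: set[str] | None = None
) -> list[AnnotatedVariant]:
    df = df.astype(str).replace("nan", ".")
    if "site_id" not in df.columns:
        quartet = ["chrom", "pos", "ref", "alt"]
        if not set(quartet) <= set(df.columns):
            raise ValueError("annotation table needs a site_id column or chrom,pos,ref,alt")
        df["site_id"] = df["chrom"] + ":" + df["pos"] + ":" + df["ref"] + ":" + df["alt"]
    missing_cols = [c for c in _ANNOTATION_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"annotation table missing required columns: {missing_cols}")
    if df["site_id"].duplicated().any():
        dup = df.loc[df["site_id"].duplicated(), "site_id"].tolist()
        raise ValueError(f"duplicated site_id in annotation table: {dup[:5]}")

    out: list[AnnotatedVariant] = []
    n_orphan = 0
    for _, row in df.iterrows():
        mt = row["MutationTaster"]
        orphan = known_site_ids is not None and row["site_id"] not in known_site_ids
        n_orphan += orphan
        out.append(
            AnnotatedVariant(
                site_id=row["site_id"],
                gene=row["Gene"] if pd.notna(row["Gene"]) else "",
                func_region=str(row["Func"]).lower(),
                exonic_func=str(row["ExonicFunc"]).lower() if pd.notna(row["ExonicFunc"]) else ".",
                exac_af=_parse_score(row["ExAC_ALL"]),
                polyphen2=_parse_score(row["Polyphen2"]),
                sift=_parse_score(row["SIFT"]),
                mutation_taster=mt if pd.notna(mt) and mt != "." else None,
                orphan=orphan,
            )
        )
    if n_orphan:
        log.info("annotation table: %d orphan rows without a genotyped site", n_orphan)
    return out


def read_phenotypes(table_path: str | os.PathLike) -> PhenotypeTable:
    """Read the sample phenotype TSV (sample_id, group, optional subgroup)."""
    df = pd.read_csv(table_path, sep="\t", dtype=str, comment="#")
    required = {"sample_id", "group"}
    if not required <= set(df.columns):
        raise ValueError(f"phenotype table missing columns: {sorted(required - set(df.columns))}")
    subgroups = []
    for _, row in df.iterrows():
        raw = row.get("subgroup")
        labels = frozenset() if pd.isna(raw) or raw in ("", ".") else frozenset(str(raw).split(","))
        subgroups.append(labels)
    table = pd.DataFrame(
        {"group": df["group"].values, "subgroups": subgroups},
        index=pd.Index(df["sample_id"], name="sample_id"),
    )
    phen = PhenotypeTable(table)
    n_case, n_control = phen.group_counts()
    log.info("phenotypes: %d cases, %d controls", n_case, n_control)
    return phen


def write_results(
    rows: pd.DataFrame, path: str | os.PathLike, provenance: dict[str, object] | None = None
) -> None:
    """Write a result table as TSV with an optional '# key: value' provenance block.

    Full numeric precision is preserved (repr round-trip); re-reading with
    :func:`read_results` reproduces the table.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for key, value in (provenance or {}).items():
            fh.write(f"# {key}: {value}\n")
        rows.to_csv(fh, sep="\t", index=False, float_format="%.17g")


def read_results(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
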