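import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from panelburden.cohort import PhenotypeTable
from panelburden.simulate import CohortSimConfig, PlantedGene, simulate_cohort

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
)


@pytest.fixture
def make_vcf(tmp_path):
    """Write a small VCF from (samples, records) where each record is
    (chrom, pos, ref, alt, [genotype strings])."""

    def _make(samples, records, name="test.vcf"):
        path = tmp_path / name
        with open(path, "w") as fh:
            fh.write(VCF_HEADER)
            chroms = {r[0] for r in records}
            for c in sorted(chroms):
                fh.write(f"##contig=<ID={c}>\n")
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
            for chrom, pos, ref, alt, gts in records:
                fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n")
        return path

    return _make


def make_phenotypes(n_cases, n_controls, subgroup=None, subgroup_cases=()):
    """In-memory phenotype table; subgroup_cases are case indices (0-based)."""
    samples = [f"CASE{i:04d}" for i in range(1, n_cases + 1)] + [
        f"CTRL{i:04d}" for i in range(1, n_controls + 1)
    ]
    member = set(subgroup_cases)
    subgroups = [
        frozenset({subgroup}) if (subgroup and i < n_cases and i in member) else frozenset()
        for i in range(len(samples))
    ]
    return PhenotypeTable(
        pd.DataFrame(
            {"group": ["case"] * n_cases + ["control"] * n_controls, "subgroups": subgroups},
            index=pd.Index(samples, name="sample_id"),
        )
    )


@pytest.fixture(scope="session")
def planted_cohort():
    """Small cohort with one enriched gene and planted QC violations."""
    cfg = CohortSimConfig(
        n_cases=120,
        n_controls=100,
        n_genes=20,
        variants_per_gene_mean=6,
        planted=(PlantedGene("GENE001", 0.20, 0.02),),
        n_low_call_sites=3,
        n_hwe_violating_sites=2,
        n_diff_missing_sites=2,
        n_multiallelic_sites=2,
        seed=11,
    )
    return simulate_cohort(cfg)


def null_burden_config(seed, n_genes=57):
    """The calibration world: 298/220 samples, all-testable rare damaging
    genes (3 exonic nonsynonymous damaging sites each), no planted effect."""
    return CohortSimConfig(
        n_cases=298,
        n_controls=220,
        n_genes=n_genes,
        variants_per_gene_mean=0.0,
        variants_per_gene_min=3,
        maf_beta=(2.0, 400.0),
        frac_exonic=1.0,
        frac_synonymous=0.0,
        frac_lof=0.0,
        frac_damaging_class=1.0,
        frac_af_unknown=0.0,
        seed=seed,
    )
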