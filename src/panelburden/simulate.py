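"""Synthetic targeted-panel cohort generator.

Emulates the statistical structure of a case–control targeted sequencing
panel at the scale of the motivating cohort (298 cases, 220 controls, 104
genes, ~1560 exonic variants): genotypes drawn under Hardy–Weinberg
equilibrium from a Beta minor-allele-frequency spectrum, baseline random
missingness, and optional planted features — low-call-rate sites,
HWE-violating sites (heterozygosity distortion), differentially missing
sites, multi-allelic records, a two-subpopulation Balding–Nichols structure,
and genes with case-enriched rare damaging carriers.  Every planted feature
is recorded in a truth table so downstream stages can be asserted against
ground truth.  Identical config + seed gives byte-identical outputs.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import MISSING, GenotypeMatrix, PhenotypeTable, VariantSite
from .permanova import ExpressionPanel

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class PlantedGene:
    """A gene with carriers of rare damaging variants planted at stated
    per-group rates (case rate >= control rate when simulating enrichment)."""

    gene: str
    case_carrier_rate: float
    control_carrier_rate: float
    n_sites: int = 4  # rare damaging sites the carriers are spread over

    def __post_init__(self) -> None:
        for r in (self.case_carrier_rate, self.control_carrier_rate):
            if not (0.0 <= r <= 1.0):
                raise ValueError(f"carrier rate {r} outside [0,1]")


@dataclass(frozen=True)
class SubpopConfig:
    """Two-subpopulation structure: each sample joins population B with
    probability ``fraction``; per-population allele frequencies diverge from
    the ancestral one by a Balding–Nichols model at the given Fst."""

    fraction: float = 0.5
    fst: float = 0.1
    align_with_group: bool = False  # population B == cases (worst-case stratification)


@dataclass(frozen=True)
class CohortSimConfig:
    n_cases: int = 298
    n_controls: int = 220
    n_genes: int = 104
    variants_per_gene_mean: float = 15.0  # Poisson; ~1560 sites over 104 genes
    variants_per_gene_min: int = 1
    maf_beta: tuple[float, float] = (0.2, 2.0)  # Beta spectrum scaled onto (0, 0.5]
    missing_rate: float = 0.02
    frac_exonic: float = 0.95
    frac_synonymous: float = 0.45  # of exonic sites
    frac_damaging_class: float = 0.5  # of nonsynonymous sites
    frac_lof: float = 0.03  # of nonsynonymous sites: stopgain/frameshift
    frac_af_unknown: float = 0.02  # annotation rows with '.' ExAC frequency
    planted: tuple[PlantedGene, ...] = ()
    n_low_call_sites: int = 0
    low_call_missing_rate: float = 0.25
    n_hwe_violating_sites: int = 0
    hwe_violation_f: float = -1.0  # inbreeding-style distortion; -1 = full het excess
    n_diff_missing_sites: int = 0
    diff_missing_delta: float = 0.40  # extra case missingness at planted sites
    n_multiallelic_sites: int = 0  # planted with 3 ALT alleles (fails the >2 rule)
    subgroup_label: str = "ASD"
    subgroup_frac_of_cases: float = 183 / 298  # atrial septal defect prevalence
    subpop: SubpopConfig | None = None
    seed: int = 0


@dataclass
class SimTruth:
    sites: pd.DataFrame  # site_id, gene, maf, planted flags, damaging class
    samples: pd.DataFrame  # sample_id, group, subpop
    genes: pd.DataFrame  # planted genes and their rates


@dataclass
class SimulatedCohort:
    genotypes: GenotypeMatrix
    annotations: pd.DataFrame  # annotation table as written to TSV
    phenotypes: PhenotypeTable
    truth: SimTruth
    config: CohortSimConfig


def _draw_site(rng: np.random.Generator, chrom: str, pos: int, n_alt: int = 1) -> VariantSite:
    ref, *alts = rng.choice(_BASES, size=1 + n_alt, replace=False)
    return VariantSite(chrom, pos, str(ref), tuple(str(a) for a in alts))


def simulate_cohort(cfg: CohortSimConfig) -> SimulatedCohort:
    """Generate the full in-memory cohort (use :func:`write_cohort` for files)."""
    rng = np.random.default_rng(cfg.seed)
    n_case, n_control = cfg.n_cases, cfg.n_controls
    n_total = n_case + n_control
    samples = [f"CASE{i:04d}" for i in range(1, n_case + 1)] + [
        f"CTRL{i:04d}" for i in range(1, n_control + 1)
    ]
    is_case = np.arange(n_total) < n_case
    genes = [f"GENE{i:03d}" for i in range(1, cfg.n_genes + 1)]
    planted_by_gene = {p.gene: p for p in cfg.planted}
    unknown = [p.gene for p in cfg.planted if p.gene not in set(genes)]
    if unknown:
        raise ValueError(f"planted genes not in cohort: {unknown}")

    # --- subpopulation assignment (Balding–Nichols allele-frequency divergence)
    if cfg.subpop is not None:
        if cfg.subpop.align_with_group:
            pop = is_case.astype(int)
        else:
            pop = (rng.random(n_total) < cfg.subpop.fraction).astype(int)
    else:
        pop = np.zeros(n_total, dtype=int)

    # --- per-gene site layout
    n_per_gene = np.maximum(
        cfg.variants_per_gene_min, rng.poisson(cfg.variants_per_gene_mean, size=cfg.n_genes)
    )
    for gi, gene in enumerate(genes):
        if gene in planted_by_gene:
            n_per_gene[gi] = max(n_per_gene[gi], planted_by_gene[gene].n_sites)

    site_rows = []
    sites: list[VariantSite] = []
    dosage_cols: list[np.ndarray] = []
    a_beta, b_beta = cfg.maf_beta

    for gi, gene in enumerate(genes):
        planted_gene = planted_by_gene.get(gene)
        planted_site_idx = set(range(planted_gene.n_sites)) if planted_gene else set()
        carrier_site_choice = None
        if planted_gene:
            # realise carrier status per sample, then attach each carrier to
            # one uniformly chosen planted site (heterozygous)
            rate = np.where(is_case, planted_gene.case_carrier_rate, planted_gene.control_carrier_rate)
            carrier = rng.random(n_total) < rate
            carrier_site_choice = np.where(
                carrier, rng.integers(0, planted_gene.n_sites, size=n_total), -1
            )
        for sj in range(n_per_gene[gi]):
            pos = 100_000 * (gi + 1) + 100 * (sj + 1)
            if sj in planted_site_idx and planted_gene is not None:
                maf = float(rng.uniform(0.0005, 0.002))  # rare by construction
                site = _draw_site(rng, "1", pos)
                dos = (carrier_site_choice == sj).astype(np.int8)
                klass = "damaging"
            else:
                maf = float(rng.beta(a_beta, b_beta) * 0.5)
                site = _draw_site(rng, "1", pos)
                p_by_pop = np.array([maf, maf])
                if cfg.subpop is not None:
                    f = cfg.subpop.fst
                    shape = (1.0 - f) / f
                    p_by_pop = rng.beta(maf * shape, (1.0 - maf) * shape, size=2)
                dos = rng.binomial(2, p_by_pop[pop]).astype(np.int8)
                klass = ""
            site_rows.append(
                dict(site_id=site.site_id, gene=gene, maf=maf,
                     planted_carrier_site=sj in planted_site_idx, forced_class=klass)
            )
            sites.append(site)
            dosage_cols.append(dos)

    dosage = np.stack(dosage_cols, axis=1)
    truth_sites = pd.DataFrame(site_rows)
    n_sites = len(sites)

    # --- planted QC violations on non-planted-gene sites
    eligible = np.flatnonzero(~truth_sites["planted_carrier_site"].to_numpy())
    n_special = cfg.n_low_call_sites + cfg.n_hwe_violating_sites + cfg.n_diff_missing_sites + cfg.n_multiallelic_sites
    if n_special > len(eligible):
        raise ValueError("not enough sites for the planted QC violations")
    special = rng.choice(eligible, size=n_special, replace=False)
    low_call = special[: cfg.n_low_call_sites]
    hwe_bad = special[cfg.n_low_call_sites : cfg.n_low_call_sites + cfg.n_hwe_violating_sites]
    dm_bad = special[
        cfg.n_low_call_sites + cfg.n_hwe_violating_sites :
        cfg.n_low_call_sites + cfg.n_hwe_violating_sites + cfg.n_diff_missing_sites
    ]
    multi = special[n_special - cfg.n_multiallelic_sites :]

    for j in hwe_bad:
        # genotype frequencies distorted by F: P(het) = 2p(1-p)(1-F)
        p, f = 0.5, cfg.hwe_violation_f
        probs = np.array([
            (1 - p) ** 2 + f * p * (1 - p),
            2 * p * (1 - p) * (1 - f),
            p**2 + f * p * (1 - p),
        ])
        probs = np.clip(probs, 0, None)
        probs /= probs.sum()
        dosage[:, j] = rng.choice([0, 1, 2], size=n_total, p=probs).astype(np.int8)

    # --- missingness: baseline everywhere, elevated at planted sites
    miss = rng.random((n_total, n_sites)) < cfg.missing_rate
    if len(low_call):
        miss[:, low_call] |= rng.random((n_total, len(low_call))) < cfg.low_call_missing_rate
    if len(dm_bad):
        extra = rng.random((n_case, len(dm_bad))) < cfg.diff_missing_delta
        miss[:n_case, dm_bad] |= extra
    dosage[miss] = MISSING

    for j in multi:
        old = sites[j]
        sites[j] = _draw_site(rng, old.chrom, old.pos, n_alt=3)
        truth_sites.loc[j, "site_id"] = sites[j].site_id

    truth_sites["planted_low_call"] = np.isin(np.arange(n_sites), low_call)
    truth_sites["planted_hwe_violation"] = np.isin(np.arange(n_sites), hwe_bad)
    truth_sites["planted_diff_missing"] = np.isin(np.arange(n_sites), dm_bad)
    truth_sites["planted_multiallelic"] = np.isin(np.arange(n_sites), multi)

    G = GenotypeMatrix(samples=samples, sites=sites, dosage=dosage)
    annotations = _simulate_annotations(rng, truth_sites, cfg)

    # --- phenotypes: case-only subgroup (e.g. atrial septal defect)
    n_sub = int(round(cfg.subgroup_frac_of_cases * n_case))
    sub_members = set(rng.choice(n_case, size=n_sub, replace=False))
    subgroups = [
        frozenset({cfg.subgroup_label}) if (i < n_case and i in sub_members) else frozenset()
        for i in range(n_total)
    ]
    phen = PhenotypeTable(
        pd.DataFrame(
            {"group": np.where(is_case, "case", "control"), "subgroups": subgroups},
            index=pd.Index(samples, name="sample_id"),
        )
    )

    truth = SimTruth(
        sites=truth_sites,
        samples=pd.DataFrame(
            {"sample_id": samples, "group": np.where(is_case, "case", "control"), "subpop": pop}
        ),
        genes=pd.DataFrame(
            [
                dict(gene=p.gene, case_carrier_rate=p.case_carrier_rate,
                     control_carrier_rate=p.control_carrier_rate, n_sites=p.n_sites)
                for p in cfg.planted
            ],
            columns=["gene", "case_carrier_rate", "control_carrier_rate", "n_sites"],
        ),
    )
    return SimulatedCohort(genotypes=G, annotations=annotations, phenotypes=phen, truth=truth, config=cfg)


def _simulate_annotations(
    rng: np.random.Generator, truth_sites: pd.DataFrame, cfg: CohortSimConfig
) -> pd.DataFrame:
    """Annotation table consistent with the planted damaging/benign classes."""
    rows = []
    classes = []
    for _, site in truth_sites.iterrows():
        forced_damaging = site["forced_class"] == "damaging"
        if forced_damaging or rng.random() < cfg.frac_exonic:
            func = "exonic"
            if not forced_damaging and rng.random() < cfg.frac_synonymous:
                exonic_func = "synonymous SNV"
                klass = "benign"
            elif not forced_damaging and rng.random() < cfg.frac_lof:
                exonic_func = rng.choice(["stopgain", "frameshift deletion"])
                klass = "lof"
            else:
                exonic_func = "nonsynonymous SNV"
                klass = "damaging" if forced_damaging or rng.random() < cfg.frac_damaging_class else "benign"
        else:
            func = str(rng.choice(["intronic", "UTR3", "UTR5"]))
            exonic_func = "."
            klass = "benign"

        if site["planted_carrier_site"]:
            exac = site["maf"]
        elif rng.random() < cfg.frac_af_unknown:
            exac = None
        else:
            exac = site["maf"]

        if klass in ("damaging",):
            pp2 = rng.uniform(0.95, 1.0)
            sift = rng.uniform(0.0, 0.05)
            mt = "D"
        elif klass == "lof":
            pp2, sift, mt = None, None, None  # predictors do not score truncating changes
        else:
            pp2 = rng.uniform(0.0, 0.90)
            sift = rng.uniform(0.10, 1.0)
            mt = str(rng.choice(["N", "P"]))
        classes.append(klass)
        rows.append(
            dict(
                site_id=site["site_id"],
                Gene=site["gene"],
                Func=func,
                ExonicFunc=exonic_func,
                ExAC_ALL="." if exac is None else f"{exac:.6g}",
                Polyphen2="." if pp2 is None else f"{pp2:.4f}",
                SIFT="." if sift is None else f"{sift:.4f}",
                MutationTaster="." if mt is None else mt,
            )
        )
    truth_sites["annotation_class"] = classes
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# file emission (formats exactly as cohort_io reads them)

_GT_CODE = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_cohort(sim: SimulatedCohort, outdir: str | os.PathLike) -> dict[str, Path]:
    """Write VCF + annotation/phenotype/truth TSVs; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": outdir / "cohort.vcf",
        "annotations": outdir / "annotations.tsv",
        "phenotypes": outdir / "phenotypes.tsv",
        "truth_sites": outdir / "truth_sites.tsv",
        "truth_samples": outdir / "truth_samples.tsv",
        "truth_genes": outdir / "truth_genes.tsv",
    }
    G = sim.genotypes
    with open(paths["vcf"], "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=panelburden-simulated-cohort\n")
        fh.write("##contig=<ID=1>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(G.samples) + "\n")
        for j, site in enumerate(G.sites):
            gts = "\t".join(_GT_CODE[int(d)] for d in G.dosage[:, j])
            fh.write(
                f"{site.chrom}\t{site.pos}\t.\t{site.ref}\t{','.join(site.alt_alleles)}"
                f"\t.\tPASS\t.\tGT\t{gts}\n"
            )
    sim.annotations.to_csv(paths["annotations"], sep="\t", index=False)
    phen_rows = pd.DataFrame(
        {
            "sample_id": sim.phenotypes.samples,
            "group": sim.phenotypes.table["group"].values,
            "subgroup": [",".join(sorted(s)) for s in sim.phenotypes.table["subgroups"]],
        }
    )
    phen_rows.to_csv(paths["phenotypes"], sep="\t", index=False)
    sim.truth.sites.to_csv(paths["truth_sites"], sep="\t", index=False)
    sim.truth.samples.to_csv(paths["truth_samples"], sep="\t", index=False)
    sim.truth.genes.to_csv(paths["truth_genes"], sep="\t", index=False)
    return paths


def simulate_cohort_files(cfg: CohortSimConfig, outdir: str | os.PathLike) -> dict[str, Path]:
    return write_cohort(simulate_cohort(cfg), outdir)


# ---------------------------------------------------------------------------
# expression simulators for the PERMANOVA and network modules


def simulate_expression_panel(
    n_per_group: tuple[int, int],
    effect_vector: np.ndarray | list[float],
    noise_sd: float = 1.0,
    seed: int | None = None,
    feature_names: list[str] | None = None,
) -> ExpressionPanel:
    """Two-group multivariate normal panel: group A ~ N(0, sd), group B ~
    N(effect_vector, sd) per feature.  Stand-in for a small qPCR target panel
    (e.g. Notch/Shh targets Hey1, Heyl, Ptch1, Gli1)."""
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    n_a, n_b = n_per_group
    if min(n_a, n_b) < 2:
        raise ValueError("need >= 2 samples per group")
    effect = np.asarray(effect_vector, dtype=float)
    rng = np.random.default_rng(seed)
    features = feature_names or [f"gene{i + 1}" for i in range(effect.size)]
    values = np.vstack(
        [
            rng.normal(0.0, noise_sd, size=(n_a, effect.size)),
            rng.normal(effect, noise_sd, size=(n_b, effect.size)),
        ]
    )
    return ExpressionPanel(
        samples=[f"A{i + 1}" for i in range(n_a)] + [f"B{i + 1}" for i in range(n_b)],
        groups=["A"] * n_a + ["B"] * n_b,
        features=features,
        values=values,
    )


def simulate_module_expression(
    n_modules: int = 3,
    genes_per_module: int = 10,
    within_r: float = 0.9,
    n_samples: int = 100,
    seed: int | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Genes x samples matrix with planted co-expression modules.

    Each gene loads on its module's latent factor with sqrt(within_r), so
    expected within-module pairwise correlation is within_r and across-module
    correlation is ~0.  Returns (matrix, true module labels per gene)."""
    if not (0.0 <= within_r < 1.0):
        raise ValueError("within_r must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    factors = rng.normal(size=(n_modules, n_samples))
    rows, labels = [], []
    for m in range(n_modules):
        noise = rng.normal(size=(genes_per_module, n_samples))
        rows.append(np.sqrt(within_r) * factors[m] + np.sqrt(1.0 - within_r) * noise)
        labels.extend([m] * genes_per_module)
    expr = pd.DataFrame(
        np.vstack(rows),
        index=[f"M{m + 1}G{g + 1}" for m in range(n_modules) for g in range(genes_per_module)],
        columns=[f"S{i + 1}" for i in range(n_samples)],
    )
    return expr, np.asarray(labels)
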