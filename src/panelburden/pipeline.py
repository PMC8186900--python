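"""Stage runners composing the library into the end-to-end analysis.

Each runner loads its inputs, executes one stage, and returns the result
table(s) as DataFrames; the CLI wraps these and writes them with provenance
headers.  Tests and the analysis scripts call them directly.
"""

from __future__ import annotations

import logging
from dataclasses import asdict

import numpy as np
import pandas as pd

from .burden import GeneBurdenResult, count_carriers, run_burden, subgroup_carrier_test
from .cohort import GenotypeMatrix, PhenotypeTable
from .config import PipelineConfig
from .damaging import adjudicate_all, summarize_filter
from .io import read_annotations, read_genotypes, read_phenotypes
from .network import build_correlation_graph, mcl_cluster
from .pca import ancestry_overlay, genotype_pca
from .permanova import ExpressionPanel, permanova
from .qc import passing_site_ids, run_site_qc

log = logging.getLogger(__name__)


def _load_cohort(cfg: PipelineConfig) -> tuple[GenotypeMatrix, list, PhenotypeTable]:
    for name in ("vcf", "annotations", "phenotypes"):
        if getattr(cfg, name) is None:
            raise ValueError(f"config is missing the {name!r} input path")
    G = read_genotypes(cfg.vcf)
    annotations = read_annotations(cfg.annotations, known_site_ids=set(G.site_ids))
    phen = read_phenotypes(cfg.phenotypes)
    return G, annotations, phen


def qc_table(cfg: PipelineConfig) -> pd.DataFrame:
    G, _, phen = _load_cohort(cfg)
    reports = run_site_qc(G, phen, cfg.qc)
    return pd.DataFrame(
        [
            dict(
                site_id=r.site_id,
                n_alt_alleles=r.n_alt_alleles,
                call_rate=r.call_rate,
                hwe_p_controls=r.hwe_p_controls,
                diff_missing_p=r.diff_missing_p,
                excluded=r.excluded,
                reasons=",".join(sorted(r.reasons)),
            )
            for r in reports
        ]
    )


def filter_table(cfg: PipelineConfig) -> tuple[pd.DataFrame, dict]:
    _, annotations, _ = _load_cohort(cfg)
    calls = adjudicate_all([a for a in annotations if not a.orphan], cfg.filter)
    funnel = summarize_filter(calls) if calls else None
    table = pd.DataFrame([asdict(c) for c in calls])
    return table, (asdict(funnel) if funnel else {})


def burden_tables(cfg: PipelineConfig) -> dict[str, pd.DataFrame]:
    """Full composition: QC -> rare-damaging filter -> collapsing burden test.

    Returns the QC report, damaging calls, burden results and the
    Manhattan-style plot data (gene, -log10 p, q flag).
    """
    G, annotations, phen = _load_cohort(cfg)
    reports = run_site_qc(G, phen, cfg.qc)
    passing = passing_site_ids(reports)
    log.info("site QC: %d of %d sites pass", len(passing), G.n_sites)
    G_pass = G.subset_sites(passing)
    calls = adjudicate_all([a for a in annotations if not a.orphan], cfg.filter)
    n_rd = sum(c.rare_damaging for c in calls)
    log.info("rare damaging variants: %d", n_rd)
    results = run_burden(
        G_pass, calls, phen,
        q_threshold=cfg.burden.q_threshold,
        min_variants=cfg.burden.min_variants,
    )
    burden_df = burden_frame(results, cfg.burden.q_threshold)
    tested = burden_df[burden_df["included"]]
    manhattan = pd.DataFrame(
        {
            "gene": tested["gene"],
            "neg_log10_p": -np.log10(tested["p_one_tailed"]),
            "q_significant": tested["q_bh"] < cfg.burden.q_threshold,
        }
    )
    qc_df = pd.DataFrame(
        [
            dict(site_id=r.site_id, n_alt_alleles=r.n_alt_alleles, call_rate=r.call_rate,
                 hwe_p_controls=r.hwe_p_controls, diff_missing_p=r.diff_missing_p,
                 excluded=r.excluded, reasons=",".join(sorted(r.reasons)))
            for r in reports
        ]
    )
    calls_df = pd.DataFrame([asdict(c) for c in calls])
    return {"qc": qc_df, "calls": calls_df, "burden": burden_df, "manhattan": manhattan}


def burden_frame(results: list[GeneBurdenResult], q_threshold: float = 0.20) -> pd.DataFrame:
    df = pd.DataFrame([asdict(r) for r in results])
    if not df.empty:
        df["significant"] = df["included"] & (df["q_bh"] < q_threshold)
    return df


def subgroup_table(cfg: PipelineConfig, gene: str, subgroup: str) -> pd.DataFrame:
    """Carrier-vs-subgroup Fisher test for one gene (e.g. the ASD subgroup)."""
    G, annotations, phen = _load_cohort(cfg)
    reports = run_site_qc(G, phen, cfg.qc)
    G_pass = G.subset_sites(passing_site_ids(reports))
    calls = adjudicate_all([a for a in annotations if not a.orphan], cfg.filter)
    per_gene = count_carriers(G_pass, calls)
    carriers = per_gene.get(gene, {"carriers": set()})["carriers"]
    res = subgroup_carrier_test(phen, carriers, subgroup, cfg.burden.subgroup_sidedness)
    return pd.DataFrame([asdict(res)])


def pca_tables(cfg: PipelineConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    G, _, phen = _load_cohort(cfg)
    res = genotype_pca(G, k=cfg.pca.k, maf_min=cfg.pca.maf_min)
    scores = pd.DataFrame(
        res.scores, columns=[f"PC{i + 1}" for i in range(res.k)],
        index=pd.Index(res.samples, name="sample_id"),
    ).reset_index()
    scores["group"] = phen.table.loc[res.samples, "group"].values
    match = ancestry_overlay(res, phen, n_permutations=cfg.pca.n_permutations, seed=cfg.seed)
    summary = pd.DataFrame(
        [dict(centroid_distance=match.centroid_distance, p_value=match.p_value,
              n_permutations=match.n_permutations,
              explained_var=";".join(f"{v:.4f}" for v in res.explained_var))]
    )
    return scores, summary


def permanova_table(cfg: PipelineConfig, panel: ExpressionPanel | None = None) -> pd.DataFrame:
    if panel is None:
        if cfg.expression_panel is None:
            raise ValueError("config is missing the expression_panel input path")
        df = pd.read_csv(cfg.expression_panel, sep="\t", comment="#", index_col=0)
        panel = ExpressionPanel.from_frame(df)
    res = permanova(
        panel, n_permutations=cfg.permanova.n_permutations,
        seed=cfg.seed, distance=cfg.permanova.distance,
    )
    return pd.DataFrame(
        [dict(pseudo_F=res.pseudo_F, p_value=res.p_value,
              n_permutations=res.n_permutations, exhaustive=res.exhaustive, seed=cfg.seed)]
    )


def network_tables(cfg: PipelineConfig, expr: pd.DataFrame | None = None) -> dict[str, pd.DataFrame]:
    if expr is None:
        if cfg.expression_matrix is None:
            raise ValueError("config is missing the expression_matrix input path")
        expr = pd.read_csv(cfg.expression_matrix, sep="\t", comment="#", index_col=0)
    cg = build_correlation_graph(expr, threshold=cfg.network.threshold, signed=cfg.network.signed)
    clustering = mcl_cluster(cg, inflation=cfg.network.inflation)
    edges = pd.DataFrame(
        [dict(gene1=u, gene2=v, r=d["r"]) for u, v, d in cg.graph.edges(data=True)],
        columns=["gene1", "gene2", "r"],
    )
    labels = clustering.labels()
    clusters = pd.DataFrame(
        sorted(labels.items()), columns=["gene", "cluster_id"]
    )
    return {"edges": edges, "clusters": clusters}
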