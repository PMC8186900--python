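"""Gene-level collapsing burden test.

Rare damaging variants are collapsed to a per-sample, per-gene carrier
indicator (dosage >= 1 at any qualifying site).  Case enrichment of carriers
is tested per gene with a one-tailed Fisher exact test (upper hypergeometric
tail, enrichment direction = more carriers in cases), odds ratios carry a
Haldane–Anscombe +0.5 correction at zero cells, and Benjamini–Hochberg
adjustment runs across the genes with at least two qualifying variants.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import fisher_exact, hypergeom

from .cohort import GenotypeMatrix, PhenotypeTable
from .damaging import DamagingCall


def fisher_one_tailed(a: int, b: int, c: int, d: int) -> float:
    """Upper-tail Fisher exact p: P(X >= a) for the case-carrier count X
    conditioned on all margins of the 2x2 table [[a, b], [c, d]]."""
    if min(a, b, c, d) < 0:
        raise ValueError("negative cell count")
    N = a + b + c + d
    if N == 0:
        raise ValueError("all-zero table")
    return float(hypergeom.sf(a - 1, N, a + c, a + b))


def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    if min(a, b, c, d) < 0:
        raise ValueError("negative cell count")
    if a + b + c + d == 0:
        raise ValueError("all-zero table")
    return float(fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def odds_ratio(a: int, b: int, c: int, d: int) -> tuple[float, bool]:
    """(a*d)/(b*c); any zero cell triggers the Haldane–Anscombe +0.5 correction.

    Returns (odds ratio, corrected flag).
    """
    if min(a, b, c, d) < 0:
        raise ValueError("negative cell count")
    if 0 in (a, b, c, d):
        a2, b2, c2, d2 = (x + 0.5 for x in (a, b, c, d))
        return (a2 * d2) / (b2 * c2), True
    return (a * d) / (b * c), False


def bh_adjust(p_values: list[float] | np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, input order preserved.

    q_(i) = min over j with p_(j) >= p_(i) of p_(j) * m / rank(j), capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    q = np.empty(m)
    q[order] = q_sorted
    return q


@dataclass(frozen=True)
class GeneBurdenResult:
    gene: str
    n_rare_damaging_variants: int
    carriers_case: int
    noncarriers_case: int
    carriers_control: int
    noncarriers_control: int
    odds_ratio: float
    or_corrected: bool
    p_one_tailed: float
    q_bh: float | None  # None for genes excluded from testing
    included: bool

    @property
    def significant(self) -> bool:
        return self.included and self.q_bh is not None and self.q_bh < 0.20


def count_carriers(
    G: GenotypeMatrix, calls: list[DamagingCall]
) -> dict[str, dict[str, object]]:
    """Per-gene rare-damaging sites and carrier sample sets.

    A sample is a carrier for a gene iff it has dosage >= 1 at at least one
    rare damaging site of that gene; missing dosages contribute nothing, and
    a sample counts at most once per gene.  Only sites present in ``G``
    (i.e. QC-passing, when a QC-filtered matrix is passed) are used.
    """
    site_col = {sid: j for j, sid in enumerate(G.site_ids)}
    genes: dict[str, list[str]] = {}
    for call in calls:
        if call.rare_damaging and call.site_id in site_col:
            genes.setdefault(call.gene, []).append(call.site_id)
    out: dict[str, dict[str, object]] = {}
    samples = np.asarray(G.samples)
    for gene, site_ids in sorted(genes.items()):
        cols = [site_col[s] for s in site_ids]
        carrier_mask = (G.dosage[:, cols] >= 1).any(axis=1)
        out[gene] = {"sites": site_ids, "carriers": set(samples[carrier_mask])}
    return out


def run_burden(
    G: GenotypeMatrix,
    calls: list[DamagingCall],
    phen: PhenotypeTable,
    q_threshold: float = 0.20,
    min_variants: int = 2,
) -> list[GeneBurdenResult]:
    """Collapse, test and BH-adjust; genes with < ``min_variants`` rare
    damaging sites are reported but excluded from testing and from the BH
    family.  Results sorted by one-tailed p (excluded genes last)."""
    per_gene = count_carriers(G, calls)
    if not any(len(v["sites"]) >= min_variants for v in per_gene.values()):
        raise ValueError(f"no gene has >= {min_variants} rare damaging variants")
    cases, controls = set(phen.cases), set(phen.controls)
    n_case, n_control = len(cases), len(controls)

    rows = []
    for gene, info in per_gene.items():
        carriers = info["carriers"]
        a = len(carriers & cases)
        c = len(carriers & controls)
        b, d = n_case - a, n_control - c
        or_val, corrected = odds_ratio(a, b, c, d)
        rows.append(
            dict(
                gene=gene,
                n_var=len(info["sites"]),
                a=a, b=b, c=c, d=d,
                or_val=or_val,
                corrected=corrected,
                p=fisher_one_tailed(a, b, c, d),
                included=len(info["sites"]) >= min_variants,
            )
        )

    included = [r for r in rows if r["included"]]
    qs = bh_adjust([r["p"] for r in included])
    for r, q in zip(included, qs):
        r["q"] = float(q)

    results = [
        GeneBurdenResult(
            gene=r["gene"],
            n_rare_damaging_variants=r["n_var"],
            carriers_case=r["a"],
            noncarriers_case=r["b"],
            carriers_control=r["c"],
            noncarriers_control=r["d"],
            odds_ratio=r["or_val"],
            or_corrected=r["corrected"],
            p_one_tailed=r["p"],
            q_bh=r.get("q"),
            included=r["included"],
        )
        for r in rows
    ]
    results.sort(key=lambda r: (not r.included, r.p_one_tailed, r.gene))
    return results


@dataclass(frozen=True)
class SubgroupTestResult:
    subgroup: str
    carriers_in: int
    total_in: int
    carriers_out: int
    total_out: int
    p_value: float
    sidedness: str


def subgroup_carrier_test(
    phen: PhenotypeTable, carriers: set[str], subgroup: str, sidedness: str = "two"
) -> SubgroupTestResult:
    """Fisher exact test of carrier status against a case-only phenotype
    subgroup (e.g. atrial septal defect), among cases only."""
    cases = set(phen.cases)
    in_group = set(phen.in_subgroup(subgroup)) & cases
    out_group = cases - in_group
    if not in_group or not out_group:
        raise ValueError(f"subgroup {subgroup!r} empty or covering all cases")
    carriers_cases = carriers & cases
    a = len(carriers_cases & in_group)
    c = len(carriers_cases & out_group)
    table = (a, len(in_group) - a, c, len(out_group) - c)
    if sidedness == "two":
        p = fisher_two_sided(*table)
    elif sidedness == "one":
        p = fisher_one_tailed(*table)
    else:
        raise ValueError(f"sidedness must be 'one' or 'two', got {sidedness!r}")
    return SubgroupTestResult(
        subgroup=subgroup,
        carriers_in=a,
        total_in=len(in_group),
        carriers_out=c,
        total_out=len(out_group),
        p_value=p,
        sidedness=sidedness,
    )
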