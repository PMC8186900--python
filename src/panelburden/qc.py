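"""Post-calling site quality control.

Four exclusion rules, applied per site:

1. more than ``max_alt_alleles`` alternate alleles (default 2);
2. genotype call rate below 90% over all samples;
3. Hardy–Weinberg equilibrium exact-test p below 1e-7 in controls;
4. case/control differential genotype missingness, Fisher p below 1e-6.

HWE uses the Levene–Haldane exact conditional distribution of the
heterozygote count given the minor-allele count, with the two-sided
"sum of configurations no more likely than the observed one" p-value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln
from scipy.stats import fisher_exact

from .cohort import MISSING, GenotypeMatrix, PhenotypeTable


@dataclass(frozen=True)
class QCThresholds:
    """Exclusion thresholds; defaults are the published panel-QC settings."""

    max_alt_alleles: int = 2
    min_call_rate: float = 0.90
    hwe_p: float = 1e-7
    diff_missing_p: float = 1e-6
    biallelic_only: bool = False  # stricter alternative to the >2-alt rule

    def __post_init__(self) -> None:
        for name in ("min_call_rate", "hwe_p", "diff_missing_p"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name}={v} outside (0, 1]")


@dataclass
class SiteQCReport:
    site_id: str
    n_alt_alleles: int
    call_rate: float
    hwe_p_controls: float
    diff_missing_p: float
    reasons: frozenset[str] = field(default_factory=frozenset)

    @property
    def excluded(self) -> bool:
        return bool(self.reasons)


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact conditional (Levene–Haldane) Hardy–Weinberg test p-value.

    With n diploids and the minor-allele count fixed, the probability of k
    heterozygotes is proportional to n! 2^k / (n_hom_major! k! n_hom_minor!)
    over the feasible k (those sharing the parity of the minor-allele count).
    p is the total probability of all heterozygote counts whose probability
    does not exceed that of the observed count.
    """
    counts = (n_hom_ref, n_het, n_hom_alt)
    if any(c < 0 for c in counts):
        raise ValueError(f"negative genotype count in {counts}")
    n = sum(counts)
    if n < 1:
        raise ValueError("need at least one called genotype")
    n_alt = 2 * n_hom_alt + n_het
    minor = min(n_alt, 2 * n - n_alt)
    if minor == 0:  # monomorphic: single feasible configuration
        return 1.0
    ks = np.arange(minor % 2, minor + 1, 2)
    n_minor_hom = (minor - ks) // 2
    n_major_hom = n - ks - n_minor_hom
    logw = ks * np.log(2.0) - (
        gammaln(n_major_hom + 1) + gammaln(ks + 1) + gammaln(n_minor_hom + 1)
    )
    probs = np.exp(logw - logw.max())
    probs /= probs.sum()
    p_obs = probs[np.searchsorted(ks, n_het)]
    return float(min(1.0, probs[probs <= p_obs * (1.0 + 1e-12)].sum()))


def differential_missingness_test(
    missing_cases: int, present_cases: int, missing_controls: int, present_controls: int
) -> float:
    """Two-sided Fisher exact p for case/control imbalance in missing genotypes."""
    counts = (missing_cases, present_cases, missing_controls, present_controls)
    if any(c < 0 for c in counts):
        raise ValueError(f"negative count in {counts}")
    if missing_cases + present_cases == 0 or missing_controls + present_controls == 0:
        raise ValueError("both groups must be non-empty")
    table = [[missing_cases, present_cases], [missing_controls, present_controls]]
    return float(fisher_exact(table, alternative="two-sided")[1])


def _genotype_counts(dosages: np.ndarray) -> tuple[int, int, int]:
    called = dosages[dosages != MISSING]
    return int((called == 0).sum()), int((called == 1).sum()), int((called == 2).sum())


def run_site_qc(
    G: GenotypeMatrix, phen: PhenotypeTable, thresholds: QCThresholds | None = None
) -> list[SiteQCReport]:
    """Apply the four exclusion rules to every site; HWE on controls only."""
    thr = thresholds or QCThresholds()
    case_idx = G.sample_index(phen.cases)
    control_idx = G.sample_index(phen.controls)
    n_samples = G.n_samples
    max_alt = 1 if thr.biallelic_only else thr.max_alt_alleles

    reports: list[SiteQCReport] = []
    for j, site in enumerate(G.sites):
        col = G.dosage[:, j]
        call_rate = float((col != MISSING).sum()) / n_samples
        hwe_p = hwe_exact_test(*_genotype_counts(col[control_idx]))
        miss_ca = int((col[case_idx] == MISSING).sum())
        miss_co = int((col[control_idx] == MISSING).sum())
        dm_p = differential_missingness_test(
            miss_ca, len(case_idx) - miss_ca, miss_co, len(control_idx) - miss_co
        )
        reasons = set()
        if site.n_alt_alleles > max_alt:
            reasons.add("multiallelic")
        if call_rate < thr.min_call_rate:
            reasons.add("low_call_rate")
        if hwe_p < thr.hwe_p:
            reasons.add("hwe_fail")
        if dm_p < thr.diff_missing_p:
            reasons.add("diff_missing")
        reports.append(
            SiteQCReport(
                site_id=site.site_id,
                n_alt_alleles=site.n_alt_alleles,
                call_rate=call_rate,
                hwe_p_controls=hwe_p,
                diff_missing_p=dm_p,
                reasons=frozenset(reasons),
            )
        )
    return reports


def passing_site_ids(reports: list[SiteQCReport]) -> list[str]:
    return [r.site_id for r in reports if not r.excluded]
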