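"""Rare-damaging adjudication.

A variant is "rare damaging" when it is exonic (or splicing), non-synonymous,
has a reference-database (ExAC) MAF below 1%, and is either protein-truncating
or a missense call judged deleterious by at least two of PolyPhen2 (>= 0.95),
SIFT (<= 0.05) and MutationTaster (prediction D).  A variant absent from the
reference database counts as rare: novel variants are by construction rarer
than the database can resolve.
"""

from __future__ import annotations

from dataclasses import dataclass

from .cohort import AnnotatedVariant

_EXONIC_REGIONS = {"exonic", "splicing", "exonic;splicing"}
_SYNONYMOUS = {"synonymous", "synonymous snv"}
_LOF_EXONIC = {
    "stopgain",
    "stoploss",
    "frameshift",
    "frameshift insertion",
    "frameshift deletion",
    "frameshift substitution",
}


@dataclass(frozen=True)
class FilterThresholds:
    maf_max: float = 0.01
    min_algorithms: int = 2
    polyphen2_min: float = 0.95
    sift_max: float = 0.05
    mutation_taster_damaging: str = "D"
    lof_auto_damaging: bool = True


@dataclass(frozen=True)
class DamagingCall:
    site_id: str
    gene: str
    is_exonic: bool
    is_nonsynonymous: bool
    is_rare: bool
    n_damaging_algorithms: int
    is_lof: bool
    rare_damaging: bool


def adjudicate(v: AnnotatedVariant, thresholds: FilterThresholds | None = None) -> DamagingCall:
    """Apply the four-step rare-damaging filter to one annotated variant.

    Unknown predictor scores are non-votes; protein-truncating classes
    qualify without predictor votes when ``lof_auto_damaging`` is set
    (the predictors only score missense changes).
    """
    thr = thresholds or FilterThresholds()
    func = v.func_region.lower()
    exonic_func = v.exonic_func.lower()

    is_exonic = func in _EXONIC_REGIONS
    is_splicing = "splicing" in func
    # splicing records carry no exonic_func; they are not synonymous changes
    is_nonsynonymous = is_exonic and (is_splicing or exonic_func not in _SYNONYMOUS | {".", "unknown", "nan"})
    is_rare = (v.exac_af or 0.0) < thr.maf_max  # unknown frequency => novel => rare
    is_lof = is_splicing or exonic_func in _LOF_EXONIC

    votes = 0
    if v.polyphen2 is not None and v.polyphen2 >= thr.polyphen2_min:
        votes += 1
    if v.sift is not None and v.sift <= thr.sift_max:
        votes += 1
    if v.mutation_taster is not None and v.mutation_taster == thr.mutation_taster_damaging:
        votes += 1

    damaging = votes >= thr.min_algorithms or (thr.lof_auto_damaging and is_lof)
    rare_damaging = is_exonic and is_nonsynonymous and is_rare and damaging
    return DamagingCall(
        site_id=v.site_id,
        gene=v.gene,
        is_exonic=is_exonic,
        is_nonsynonymous=is_nonsynonymous,
        is_rare=is_rare,
        n_damaging_algorithms=votes,
        is_lof=is_lof,
        rare_damaging=rare_damaging,
    )


def adjudicate_all(
    annotations: list[AnnotatedVariant], thresholds: FilterThresholds | None = None
) -> list[DamagingCall]:
    return [adjudicate(v, thresholds) for v in annotations]


@dataclass(frozen=True)
class FilterFunnel:
    """Counts at each stage of the filter cascade."""

    n_total: int
    n_exonic: int
    n_nonsynonymous: int
    n_rare_nonsynonymous: int
    n_rare_damaging: int
    pct_rare_damaging_of_nonsynonymous: float | None  # None when undefined


def summarize_filter(calls: list[DamagingCall]) -> FilterFunnel:
    """Funnel summary: exonic -> nonsynonymous -> rare -> rare damaging.

    The percentage of nonsynonymous variants adjudicated rare damaging is
    reported at two decimals; undefined (None) when there are none.
    """
    if not calls:
        raise ValueError("no damaging calls to summarize")
    n_exonic = sum(c.is_exonic for c in calls)
    n_nonsyn = sum(c.is_nonsynonymous for c in calls)
    n_rare_nonsyn = sum(c.is_nonsynonymous and c.is_rare for c in calls)
    n_rd = sum(c.rare_damaging for c in calls)
    pct = round(100.0 * n_rd / n_nonsyn, 2) if n_nonsyn else None
    return FilterFunnel(len(calls), n_exonic, n_nonsyn, n_rare_nonsyn, n_rd, pct)
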