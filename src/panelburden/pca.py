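"""Ancestry PCA on SNP genotypes.

Sites are restricted to well-called polymorphic SNPs with MAF above a floor,
dosages are mean-imputed and normalised Patterson-style (centred by 2p, scaled
by sqrt(2p(1-p))), and components come from the singular decomposition.  Used
to confirm that cases and controls occupy the same region of genotype space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cohort import MISSING, GenotypeMatrix, PhenotypeTable


@dataclass
class PCAResult:
    samples: list[str]
    scores: np.ndarray  # samples x k
    explained_var: np.ndarray  # k fractions of total variance
    sites_used: list[str]
    k: int


def genotype_pca(
    G: GenotypeMatrix, k: int = 2, maf_min: float = 0.05, min_call_rate: float = 0.90
) -> PCAResult:
    """Principal components of the normalised dosage matrix."""
    if k < 1:
        raise ValueError("k must be >= 1")
    dos = G.dosage.astype(float)
    dos[dos == MISSING] = np.nan
    call_rate = 1.0 - np.isnan(dos).mean(axis=0)
    p_hat = np.nanmean(dos, axis=0) / 2.0
    maf = np.minimum(p_hat, 1.0 - p_hat)
    # a site where every called genotype is identical (e.g. all het) carries
    # no ancestry information even if its allele frequency is intermediate
    variable = np.nanvar(dos, axis=0) > 0
    keep = (call_rate >= min_call_rate) & (maf >= maf_min) & (maf > 0) & variable
    if not keep.any():
        raise ValueError("no polymorphic sites pass the PCA filters")
    dos = dos[:, keep]
    p = p_hat[keep]
    # mean imputation, then Patterson normalisation
    dos = np.where(np.isnan(dos), 2.0 * p, dos)
    X = (dos - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    X -= X.mean(axis=0)
    if k > min(X.shape):
        raise ValueError(f"k={k} exceeds matrix rank bound {min(X.shape)}")
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    var = s**2
    explained = var / var.sum()
    return PCAResult(
        samples=list(G.samples),
        scores=U[:, :k] * s[:k],
        explained_var=explained[:k],
        sites_used=[sid for sid, kp in zip(G.site_ids, keep) if kp],
        k=k,
    )


@dataclass(frozen=True)
class AncestryMatch:
    centroid_distance: float
    p_value: float
    n_permutations: int


def ancestry_overlay(
    res: PCAResult, phen: PhenotypeTable, n_permutations: int = 999, seed: int | None = None
) -> AncestryMatch:
    """Case/control centroid separation on (PC1, PC2) with a label-permutation p.

    A large p indicates the two groups are drawn from the same ancestry cloud
    (well matched); small p flags stratification.
    """
    groups = phen.table.loc[res.samples, "group"].to_numpy()
    for g in ("case", "control"):
        if (groups == g).sum() < 2:
            raise ValueError(f"group {g!r} has fewer than 2 scored samples")
    xy = res.scores[:, : min(2, res.k)]
    is_case = groups == "case"

    def centroid_dist(mask: np.ndarray) -> float:
        return float(np.linalg.norm(xy[mask].mean(axis=0) - xy[~mask].mean(axis=0)))

    observed = centroid_dist(is_case)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        exceed += centroid_dist(rng.permutation(is_case)) >= observed - 1e-12
    p = (1 + exceed) / (1 + n_permutations)
    return AncestryMatch(centroid_distance=observed, p_value=p, n_permutations=n_permutations)
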