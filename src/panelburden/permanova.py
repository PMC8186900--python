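"""Permutational multivariate analysis of variance (PERMANOVA).

Partitions the total sum of squared pairwise distances into among- and
within-group components and refers the pseudo-F ratio to a permutation null
obtained by shuffling group labels.  When the number of distinct label
assignments is small the null is enumerated exactly instead of sampled.
Used for joint tests of multi-gene expression differences (e.g. a combined
Notch + Shh target panel) where per-gene univariate tests lose power.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform


@dataclass
class ExpressionPanel:
    """samples x features expression values with a group label per sample."""

    samples: list[str]
    groups: list[str]
    features: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.samples), len(self.features)):
            raise ValueError("values shape inconsistent with samples x features")
        if np.isnan(self.values).any():
            raise ValueError("expression panel contains missing values")
        labels, counts = np.unique(self.groups, return_counts=True)
        if len(labels) < 2 or counts.min() < 2:
            raise ValueError("need >= 2 groups with >= 2 samples each")

    @classmethod
    def from_frame(cls, df: pd.DataFrame, group_col: str = "group") -> "ExpressionPanel":
        features = [c for c in df.columns if c != group_col]
        return cls(
            samples=list(df.index.astype(str)),
            groups=list(df[group_col]),
            features=features,
            values=df[features].to_numpy(float),
        )


@dataclass(frozen=True)
class PermanovaResult:
    pseudo_F: float
    p_value: float
    n_permutations: int
    exhaustive: bool
    seed: int | None


def _ss_parts(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> tuple[float, float]:
    """(SS_total, SS_within) from the squared distance matrix and group codes."""
    n = len(codes)
    ss_total = d2.sum() / (2.0 * n)
    ss_within = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        ss_within += d2[np.ix_(idx, idx)].sum() / (2.0 * len(idx))
    return ss_total, ss_within


def _pseudo_f(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> tuple[float, float]:
    """(pseudo_F, SS_among); F is +inf when SS_within vanishes."""
    n = len(codes)
    ss_total, ss_within = _ss_parts(d2, codes, n_groups)
    ss_among = ss_total - ss_within
    if ss_within <= 1e-12 * max(ss_total, 1.0):
        return np.inf, ss_among
    return (ss_among / (n_groups - 1)) / (ss_within / (n - n_groups)), ss_among


def permanova(
    panel: ExpressionPanel,
    n_permutations: int = 9999,
    seed: int | None = None,
    distance: str = "euclidean",
    exhaustive_if_small: bool = True,
) -> PermanovaResult:
    """One-way PERMANOVA on the panel's pairwise distances.

    Monte-Carlo p uses the small-sample correction (1 + exceedances) /
    (1 + n_permutations); the exhaustive p is the exact fraction of label
    assignments with pseudo-F at least the observed one (the observed
    assignment included).  Degenerate panels with zero within-group scatter
    are compared on SS_among across permutations.
    """
    if n_permutations < 99:
        raise ValueError("n_permutations must be >= 99")
    d2 = squareform(pdist(panel.values, metric=distance)) ** 2
    labels, codes = np.unique(panel.groups, return_inverse=True)
    a = len(labels)
    n = len(codes)

    f_obs, ss_among_obs = _pseudo_f(d2, codes, a)
    # infinite F (no within-group scatter): rank permutations on SS_among
    def stat(c: np.ndarray) -> float:
        f, ss_among = _pseudo_f(d2, c, a)
        return ss_among if np.isinf(f_obs) else f

    obs = ss_among_obs if np.isinf(f_obs) else f_obs
    eps = 1e-9 * max(abs(obs), 1.0)

    n_assignments = _count_assignments(codes, a)
    if exhaustive_if_small and a == 2 and n_assignments <= n_permutations:
        n1 = int((codes == 0).sum())
        exceed = 0
        for subset in combinations(range(n), n1):
            perm = np.ones(n, dtype=int)
            perm[list(subset)] = 0
            exceed += stat(perm) >= obs - eps
        return PermanovaResult(f_obs, exceed / n_assignments, n_assignments, True, seed)

    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        exceed += stat(rng.permutation(codes)) >= obs - eps
    p = (1 + exceed) / (1 + n_permutations)
    return PermanovaResult(f_obs, p, n_permutations, False, seed)


def _count_assignments(codes: np.ndarray, n_groups: int) -> int:
    n = len(codes)
    total = 1
    remaining = n
    for g in range(n_groups):
        ng = int((codes == g).sum())
        total *= comb(remaining, ng)
        remaining -= ng
    return total
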