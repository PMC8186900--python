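"""Co-expression network construction and Markov clustering.

Genes are linked when their expression profiles correlate at or above a
threshold (signed Pearson r >= 0.8 by default: positive co-regulation).
Clusters come from the Markov Cluster (MCL) algorithm — alternating random-
walk expansion (matrix power) and inflation (elementwise power with column
renormalisation) until the flow matrix stabilises into attractor blocks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


@dataclass
class CorrelationGraph:
    graph: nx.Graph  # nodes = genes kept; edge attribute "r"
    threshold: float
    signed: bool
    dropped_zero_variance: list[str]

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)


def build_correlation_graph(
    expr: pd.DataFrame,
    threshold: float = 0.8,
    signed: bool = True,
    method: str = "pearson",
) -> CorrelationGraph:
    """Thresholded gene-gene correlation graph from a genes x samples matrix."""
    if expr.shape[1] < 3:
        raise ValueError("need at least 3 samples to estimate correlations")
    variances = expr.var(axis=1)
    dropped = list(expr.index[variances == 0])
    if dropped:
        log.info("dropping %d zero-variance genes", len(dropped))
    expr = expr.loc[variances > 0]
    corr = expr.T.corr(method=method).to_numpy()
    genes = list(expr.index)
    g = nx.Graph()
    g.add_nodes_from(genes)
    n = len(genes)
    iu, ju = np.triu_indices(n, k=1)
    r = corr[iu, ju]
    keep = (np.abs(r) >= threshold) if not signed else (r >= threshold)
    for i, j, rij in zip(iu[keep], ju[keep], r[keep]):
        g.add_edge(genes[i], genes[j], r=float(rij))
    return CorrelationGraph(graph=g, threshold=threshold, signed=signed, dropped_zero_variance=dropped)


@dataclass
class MCLClustering:
    clusters: list[frozenset[str]]
    inflation: float
    n_iterations: int
    converged: bool

    def labels(self) -> dict[str, int]:
        return {gene: ci for ci, cluster in enumerate(self.clusters) for gene in cluster}


def mcl_cluster(
    cgraph: CorrelationGraph | nx.Graph,
    inflation: float = 2.0,
    expansion: int = 2,
    max_iter: int = 100,
    tol: float = 1e-6,
    self_loops: bool = True,
) -> MCLClustering:
    """Markov clustering of the (weighted) correlation graph.

    Deterministic for fixed inputs.  Non-convergence at ``max_iter`` is
    reported via ``converged=False`` together with the current clustering.
    """
    graph = cgraph.graph if isinstance(cgraph, CorrelationGraph) else cgraph
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    if inflation <= 1:
        raise ValueError("inflation must exceed 1")
    nodes = list(graph.nodes)
    # edge weights must be nonnegative flow capacities; |r| covers the
    # absolute-threshold mode where negative correlations pass (unweighted
    # edges default to 1)
    A = np.abs(nx.to_numpy_array(graph, nodelist=nodes, weight="r", nonedge=0.0))
    if self_loops:
        np.fill_diagonal(A, np.maximum(A.diagonal(), 1.0))
    M = A / A.sum(axis=0, keepdims=True)

    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        prev = M
        M = np.linalg.matrix_power(M, expansion)
        M = M**inflation
        M[M < 1e-12] = 0.0
        col = M.sum(axis=0, keepdims=True)
        col[col == 0] = 1.0
        M = M / col
        if np.max(np.abs(M - prev)) < tol:
            converged = True
            break

    clusters = _clusters_from_flow(M, nodes)
    return MCLClustering(clusters=clusters, inflation=inflation, n_iterations=it, converged=converged)


def _clusters_from_flow(M: np.ndarray, nodes: list[str], attr_tol: float = 1e-6) -> list[frozenset[str]]:
    """Read clusters off the limit flow matrix: each attractor row spans one
    cluster (columns with inbound flow); overlapping clusters are merged."""
    n = len(nodes)
    attractors = np.flatnonzero(M.diagonal() > attr_tol)
    if attractors.size == 0:  # not yet converged to attractors: fall back per column
        attractors = np.unique(M.argmax(axis=0))
    raw = [set(np.flatnonzero(M[i] > attr_tol)) | {i} for i in attractors]
    # union-find merge of overlapping attractor systems
    merged: list[set[int]] = []
    for cluster in raw:
        hit = [m for m in merged if m & cluster]
        for m in hit:
            merged.remove(m)
            cluster |= m
        merged.append(cluster)
    covered = set().union(*merged) if merged else set()
    for orphan in set(range(n)) - covered:  # column with all flow into attractors elsewhere
        target = int(M[:, orphan].argmax())
        for m in merged:
            if target in m:
                m.add(orphan)
                break
    out = [frozenset(nodes[i] for i in m) for m in merged]
    return sorted(out, key=lambda c: (-len(c), sorted(c)[0]))


def select_heart_specific_genes(
    expr_by_tissue: pd.DataFrame, heart_column: str = "heart", fold: float = 2.0
) -> list[str]:
    """Genes whose heart expression exceeds ``fold`` x the maximum across the
    other tissues (genes x tissues input)."""
    if heart_column not in expr_by_tissue.columns:
        raise ValueError(f"tissue column {heart_column!r} absent")
    if expr_by_tissue.shape[1] < 2:
        raise ValueError("need at least 2 tissues")
    heart = expr_by_tissue[heart_column]
    other_max = expr_by_tissue.drop(columns=[heart_column]).max(axis=1)
    selected = list(expr_by_tissue.index[heart > fold * other_max])
    log.info("selected %d heart-specific genes of %d", len(selected), len(expr_by_tissue))
    return selected
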