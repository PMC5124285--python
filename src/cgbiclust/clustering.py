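"""Grouping genes by signed profile and the cluster correlation matrix.

A cluster is born as the set of genes sharing one signed discretized
profile; its conditions are that profile's selected set.  Similarity
within and between clusters is the mean pairwise dot product of the
genes' L2-normalized full expression rows (cosine similarity).  Because
the mean of all cross-pair dot products factorizes, both quantities are
computed from per-cluster sum vectors rather than explicit pair loops:

    between(a, b) = (sum_a . sum_b) / (|a| |b|)
    within(a)     = (||sum_a||^2 - sum_i ||r_i||^2) / (|a| (|a| - 1))

which for unit rows reduces the within term to (||sum_a||^2 - n) / (n(n-1)).
Negative entries of the assembled matrix are truncated to zero so that
anti-correlated clusters can never look mergeable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .discretize import DiscretizationResult
from .matrix_io import ExpressionMatrix

__all__ = [
    "Cluster",
    "ClusterCorrelationMatrix",
    "group_by_profile",
    "within_cluster_correlation",
    "between_cluster_correlation",
    "cluster_correlation_matrix",
]

logger = logging.getLogger(__name__)


@dataclass
class Cluster:
    """A gene set with its co-expression conditions and summary stats.

    ``profile`` holds the shared signed state vector for grouping-stage
    clusters and is None for merged clusters, whose gene profiles need not
    be identical.
    """

    genes: tuple[str, ...]
    conditions: frozenset[str]
    profile: tuple[int, ...] | None = None
    correlation: float | None = None
    score: float | None = None
    member_rows: np.ndarray | None = field(default=None, repr=False, compare=False)

    @property
    def size(self) -> int:
        return len(self.genes)


@dataclass
class ClusterCorrelationMatrix:
    """Symmetric nonnegative K x K matrix of cluster similarities.

    Off-diagonal entries are between-cluster means, the diagonal holds each
    cluster's within-correlation; a row is the cluster's correlation
    profile.
    """

    values: np.ndarray
    clusters: list[Cluster]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        k = len(self.clusters)
        if self.values.shape != (k, k):
            raise ValueError("correlation matrix shape does not match cluster count")


# ---------------------------------------------------------------------------
# Array-level kernels (shared with the pipeline)
# ---------------------------------------------------------------------------

def _group_states(states: np.ndarray, kept: np.ndarray) -> tuple[np.ndarray, list[np.ndarray]]:
    """Group kept rows of a signed state matrix by identical profile.

    Returns the K unique profiles and, per profile, the member row indices
    (into the full matrix), ordered by first appearance of each profile.
    """
    if kept.size == 0:
        return np.empty((0, states.shape[1]), dtype=states.dtype), []
    sub = np.ascontiguousarray(states[kept])
    uniq, first, inverse = np.unique(
        sub, axis=0, return_index=True, return_inverse=True
    )
    inverse = np.asarray(inverse).ravel()
    order = np.argsort(first, kind="stable")  # order clusters by first member
    rank = np.empty_like(order)
    rank[order] = np.arange(order.size)
    inv_ordered = rank[inverse]
    by_cluster = np.argsort(inv_ordered, kind="stable")
    bounds = np.searchsorted(inv_ordered[by_cluster], np.arange(order.size + 1))
    members: list[np.ndarray] = [
        kept[by_cluster[bounds[k]:bounds[k + 1]]] for k in range(order.size)
    ]
    return uniq[order], members


def _sum_vectors(rows: np.ndarray, members: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Per-cluster sums of normalized rows and member counts."""
    c = rows.shape[1]
    sums = np.empty((len(members), c), dtype=float)
    counts = np.empty(len(members), dtype=float)
    for k, idx in enumerate(members):
        sums[k] = rows[idx].sum(axis=0)
        counts[k] = idx.size
    return sums, counts


def _within_from_sums(sums: np.ndarray, sqnorms: np.ndarray, counts: np.ndarray) -> np.ndarray:
    """Within-correlation per cluster; singletons are 1 by convention."""
    n = counts
    total = np.einsum("ij,ij->i", sums, sums)
    with np.errstate(invalid="ignore", divide="ignore"):
        within = (total - sqnorms) / (n * (n - 1.0))
    within[n < 2] = 1.0
    return within


def _correlation_matrix_arrays(
    sums: np.ndarray, sqnorms: np.ndarray, counts: np.ndarray
) -> np.ndarray:
    means = sums / counts[:, None]
    m = means @ means.T
    np.fill_diagonal(m, _within_from_sums(sums, sqnorms, counts))
    np.maximum(m, 0.0, out=m)
    return m


# ---------------------------------------------------------------------------
# Public API
# ---------------------------------------------------------------------------

def group_by_profile(
    disc: DiscretizationResult, matrix: ExpressionMatrix
) -> list[Cluster]:
    """One cluster per distinct signed profile among the non-skipped genes."""
    profiles, members = _group_states(disc.states, disc.kept)
    clusters: list[Cluster] = []
    for prof, idx in zip(profiles, members):
        conds = frozenset(
            matrix.condition_ids[j] for j in np.flatnonzero(prof != 0)
        )
        clusters.append(
            Cluster(
                genes=tuple(matrix.gene_ids[i] for i in idx),
                conditions=conds,
                profile=tuple(int(s) for s in prof),
                member_rows=idx,
            )
        )
    logger.info("group_by_profile: %d clusters from %d genes", len(clusters), disc.kept.size)
    return clusters


def _cluster_rows(cluster: Cluster, normalized: ExpressionMatrix) -> np.ndarray:
    if cluster.member_rows is not None:
        return np.asarray(cluster.member_rows, dtype=int)
    gidx = normalized.gene_index()
    return np.array([gidx[g] for g in cluster.genes], dtype=int)


def within_cluster_correlation(cluster: Cluster, normalized: ExpressionMatrix) -> float:
    """Mean pairwise dot product of member rows; 1.0 for singletons."""
    idx = _cluster_rows(cluster, normalized)
    rows = normalized.values[idx]
    n = idx.size
    if n < 2:
        return 1.0
    s = rows.sum(axis=0)
    sq = float(np.einsum("ij,ij->", rows, rows))
    return float((s @ s - sq) / (n * (n - 1.0)))


def between_cluster_correlation(
    a: Cluster, b: Cluster, normalized: ExpressionMatrix
) -> float:
    """Mean dot product over all cross pairs, via the sum-vector shortcut."""
    ia = _cluster_rows(a, normalized)
    ib = _cluster_rows(b, normalized)
    sa = normalized.values[ia].sum(axis=0)
    sb = normalized.values[ib].sum(axis=0)
    return float(sa @ sb / (ia.size * ib.size))


def cluster_correlation_matrix(
    clusters: list[Cluster], normalized: ExpressionMatrix
) -> ClusterCorrelationMatrix:
    """Assemble the K x K similarity matrix, negatives truncated to zero."""
    if not clusters:
        raise ValueError("need at least one cluster")
    members = [_cluster_rows(c, normalized) for c in clusters]
    sums, counts = _sum_vectors(normalized.values, members)
    sqnorms = np.array(
        [float(np.einsum("ij,ij->", normalized.values[idx], normalized.values[idx]))
         for idx in members]
    )
    values = _correlation_matrix_arrays(sums, sqnorms, counts)
    return ClusterCorrelationMatrix(values=values, clusters=list(clusters))
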