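"""Checkpoint-based cluster merging and optional bicluster overlap.

Two clusters may merge only when three independent checkpoints agree:

* CHECK1 — each cluster appears in the gap-discretized correlation profile
  of the other (mutual top-similarity membership);
* CHECK2 — gap-discretizing the element-wise product of the two correlation
  profiles selects exactly the input pair, and nothing else;
* CHECK3 — the between-cluster correlation strictly exceeds the smaller of
  the two within-correlations.

Pairs passing all three are consensus pairs; connected components of the
consensus graph are merged in a single round (union of genes, union of
conditions, within-correlation recomputed).  The optional OVERLAP stage
then lets gene-disjoint biclusters whose condition sets nest combine into
overlapping ones.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .clustering import Cluster, ClusterCorrelationMatrix, _cluster_rows
from .discretize import _gap_select_abs, gap_select
from .matrix_io import Bicluster, BiclusterSet, ExpressionMatrix

__all__ = [
    "ConsensusPairSet",
    "check1",
    "check2",
    "check3",
    "consensus_pairs",
    "merge_clusters",
    "build_overlapping_biclusters",
]

logger = logging.getLogger(__name__)

Pair = tuple[int, int]


def _canon(pairs) -> frozenset[Pair]:
    return frozenset((min(x, y), max(x, y)) for x, y in pairs if x != y)


@dataclass(frozen=True)
class ConsensusPairSet:
    """Cluster pairs passing all three merge checkpoints."""

    pairs: frozenset[Pair]
    check1: frozenset[Pair] = field(default_factory=frozenset)
    check2: frozenset[Pair] = field(default_factory=frozenset)
    check3: frozenset[Pair] = field(default_factory=frozenset)


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

def _matrix_values(corr) -> np.ndarray:
    if isinstance(corr, ClusterCorrelationMatrix):
        return corr.values
    return np.asarray(corr, dtype=float)


def check1(corr) -> frozenset[Pair]:
    """Mutual membership in gap-discretized correlation profiles."""
    m = _matrix_values(corr)
    k = m.shape[0]
    if k < 2:
        return frozenset()
    sel = _gap_select_abs(m)
    mutual = sel & sel.T
    xs, ys = np.nonzero(np.triu(mutual, k=1))
    return frozenset(zip(xs.tolist(), ys.tolist()))


def _check2_pair(m: np.ndarray, x: int, y: int) -> bool:
    prod = m[x] * m[y]
    norm = np.linalg.norm(prod)
    if norm == 0.0:
        return False
    sel = gap_select(prod / norm)
    chosen = np.flatnonzero(sel)
    return chosen.size == 2 and chosen[0] == min(x, y) and chosen[1] == max(x, y)


def check2(corr) -> frozenset[Pair]:
    """Discretized product of two correlation profiles selects exactly them."""
    m = _matrix_values(corr)
    k = m.shape[0]
    out = set()
    for x in range(k):
        for y in range(x + 1, k):
            if _check2_pair(m, x, y):
                out.add((x, y))
    return frozenset(out)


def check3(corr) -> frozenset[Pair]:
    """Between-correlation strictly above the smaller self-correlation."""
    m = _matrix_values(corr)
    diag = np.diag(m)
    floor = np.minimum.outer(diag, diag)
    xs, ys = np.nonzero(np.triu(m > floor, k=1))
    return frozenset(zip(xs.tolist(), ys.tolist()))


def consensus_pairs(c1, c2, c3) -> ConsensusPairSet:
    """Intersection of the three checkpoint pair sets."""
    c1, c2, c3 = _canon(c1), _canon(c2), _canon(c3)
    return ConsensusPairSet(pairs=c1 & c2 & c3, check1=c1, check2=c2, check3=c3)


def consensus_from_matrix(corr) -> ConsensusPairSet:
    """All three checkpoints on one correlation matrix, intersected.

    CHECK2 is only evaluated on pairs already passing CHECK1 and CHECK3;
    the intersection is identical, but the cost drops from O(K^3) to
    O(K^2 + |candidates| K), which matters on null-matrix calibration runs
    where K runs into the thousands.  The per-check sets reported here are
    therefore the pruned ones, not the full CHECK2 set.
    """
    m = _matrix_values(corr)
    k = m.shape[0]
    if k < 2:
        return ConsensusPairSet(pairs=frozenset())
    sel = _gap_select_abs(m)
    mutual = sel & sel.T
    diag = np.diag(m)
    above = m > np.minimum.outer(diag, diag)
    cand = np.triu(mutual & above, k=1)
    xs, ys = np.nonzero(cand)
    passing = {
        (int(x), int(y)) for x, y in zip(xs, ys) if _check2_pair(m, int(x), int(y))
    }
    c13 = frozenset(zip(xs.tolist(), ys.tolist()))
    return ConsensusPairSet(
        pairs=frozenset(passing), check1=c13, check2=frozenset(passing), check3=c13
    )


# ---------------------------------------------------------------------------
# Merging
# ---------------------------------------------------------------------------

def merge_clusters(
    clusters: list[Cluster],
    consensus: ConsensusPairSet,
    normalized: ExpressionMatrix,
) -> list[Cluster]:
    """Merge connected components of the consensus graph, one round.

    Untouched clusters pass through unchanged; merged clusters take the
    union of genes and conditions and a freshly computed within-correlation
    over the merged gene set.  Output order follows the smallest input
    index of each component, so an empty consensus set is the identity.
    """
    k = len(clusters)
    pairs = list(consensus.pairs)
    if not pairs:
        return list(clusters)
    for x, y in pairs:
        if not (0 <= x < k and 0 <= y < k):
            raise ValueError(f"consensus pair ({x},{y}) out of range for {k} clusters")
    rows = np.array([p[0] for p in pairs])
    cols = np.array([p[1] for p in pairs])
    graph = coo_matrix((np.ones(len(pairs)), (rows, cols)), shape=(k, k))
    n_comp, labels = connected_components(graph, directed=False)
    merged: list[Cluster] = []
    for comp in range(n_comp):
        idx = np.flatnonzero(labels == comp)
        if idx.size == 1:
            merged.append(clusters[int(idx[0])])
            continue
        parts = [clusters[int(i)] for i in idx]
        genes: tuple[str, ...] = tuple(g for p in parts for g in p.genes)
        conds = frozenset().union(*(p.conditions for p in parts))
        member_rows = None
        if all(p.member_rows is not None for p in parts):
            member_rows = np.concatenate([p.member_rows for p in parts])
        out = Cluster(
            genes=genes, conditions=conds, profile=None, member_rows=member_rows
        )
        out.correlation = _merged_within(parts, out, normalized)
        merged.append(out)
    logger.info(
        "merge_clusters: %d consensus pairs, %d -> %d clusters",
        len(pairs), k, len(merged),
    )
    return merged


def _merged_within(
    parts: list[Cluster], merged: Cluster, normalized: ExpressionMatrix
) -> float:
    idx = _cluster_rows(merged, normalized)
    rows = normalized.values[idx]
    n = idx.size
    if n < 2:
        return 1.0
    s = rows.sum(axis=0)
    sq = float(np.einsum("ij,ij->", rows, rows))
    return float((s @ s - sq) / (n * (n - 1.0)))


# ---------------------------------------------------------------------------
# Overlap construction
# ---------------------------------------------------------------------------

def build_overlapping_biclusters(
    bset: BiclusterSet, normalized: ExpressionMatrix | None = None
) -> BiclusterSet:
    """Allow gene overlap between biclusters whose condition sets nest.

    For each query bicluster q:

    1. if other biclusters exist whose condition sets contain q's, emit the
       union of their genes with q's, on q's conditions (the intersection);
    2. otherwise collect the biclusters whose condition sets are strict
       subsets of q's: q survives unchanged only if their conditions do not
       jointly cover q's condition set.

    Duplicate outputs (same gene and condition sets) are emitted once.  The
    input is expected to be gene-disjoint (the pre-overlap pipeline state).
    """
    items = list(bset.biclusters)
    out: list[Bicluster] = []
    seen: set[tuple[frozenset[str], frozenset[str]]] = set()

    def emit(
        genes: frozenset[str], conds: frozenset[str], unchanged: Bicluster | None = None
    ) -> None:
        key = (genes, conds)
        if key in seen:
            return
        seen.add(key)
        if unchanged is not None:  # pass-through query keeps its stats/signs
            out.append(unchanged)
            return
        corr = None
        if normalized is not None:
            corr = within_gene_set_correlation(genes, normalized)
        out.append(Bicluster(genes=genes, conditions=conds, correlation=corr))

    for q in items:
        supersets = [
            r for r in items if r is not q and r.conditions >= q.conditions
        ]
        if supersets:
            genes = q.genes.union(*(r.genes for r in supersets))
            emit(frozenset(genes), q.conditions)
            continue
        subsets = [r for r in items if r is not q and r.conditions < q.conditions]
        covered = frozenset().union(*(r.conditions for r in subsets)) if subsets else frozenset()
        if covered < q.conditions:
            emit(q.genes, q.conditions, unchanged=q)
    result = BiclusterSet(biclusters=out, source_matrix_shape=bset.source_matrix_shape)
    logger.info("overlap: %d -> %d biclusters", len(items), len(out))
    return result


def within_gene_set_correlation(
    genes: frozenset[str], normalized: ExpressionMatrix
) -> float:
    """Mean pairwise dot product over an arbitrary gene-id set."""
    gidx = normalized.gene_index()
    idx = np.array(sorted(gidx[g] for g in genes), dtype=int)
    rows = normalized.values[idx]
    n = idx.size
    if n < 2:
        return 1.0
    s = rows.sum(axis=0)
    sq = float(np.einsum("ij,ij->", rows, rows))
    return float((s @ s - sq) / (n * (n - 1.0)))
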