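"""End-to-end clustered-groups run: discretize, group, merge, overlap, select.

`run_cg` is the user-facing entry point operating on labelled expression
matrices.  `cluster_stats_from_values` is the lean array-level variant the
random-matrix calibration loops over; it shares every kernel with the
labelled path but skips identifier bookkeeping.
"""

from __future__ import annotations

import logging

import numpy as np

from . import select_calibration
from .clustering import (
    Cluster,
    _correlation_matrix_arrays,
    _group_states,
    _sum_vectors,
    cluster_correlation_matrix,
    group_by_profile,
    within_cluster_correlation,
)
from .discretize import discretize_matrix, gap_select, l2_normalize
from .matrix_io import Bicluster, BiclusterSet, ExpressionMatrix
from .merge_overlap import (
    build_overlapping_biclusters,
    consensus_from_matrix,
    merge_clusters,
)

__all__ = ["run_cg", "cluster_stats_from_values"]

logger = logging.getLogger(__name__)


def run_cg(
    matrix: ExpressionMatrix,
    overlap_param: int = 1,
    apply_select: bool = False,
    cstar: float | str = "default",
    seed: int | None = None,
) -> BiclusterSet:
    """Run the full clustered-groups pipeline on an expression matrix.

    Parameters
    ----------
    matrix : input genes x conditions matrix.
    overlap_param : 1 allows output biclusters to share genes (default),
        0 keeps the gene-disjoint merged clusters.
    apply_select : when True, keep only clusters whose score
        y + log(x)/log(N) strictly exceeds the cutoff.
    cstar : the cutoff — a float, "default" for the dimension-averaged
        constant, or "calibrate" to derive it from null matrices of this
        matrix's dimensions (requires ``seed``).
    seed : RNG seed, used only by cstar="calibrate"; the pipeline itself
        is deterministic.
    """
    if overlap_param not in (0, 1):
        raise ValueError("overlap_param must be 0 or 1")
    n, _ = matrix.shape
    disc = discretize_matrix(matrix)
    if disc.kept.size == 0:
        logger.info("run_cg: no discretizable genes, empty result")
        return BiclusterSet(biclusters=[], source_matrix_shape=matrix.shape)
    normalized, _ = l2_normalize(matrix)
    clusters = group_by_profile(disc, matrix)
    corr = cluster_correlation_matrix(clusters, normalized)
    for cl in clusters:
        cl.correlation = within_cluster_correlation(cl, normalized)
    consensus = consensus_from_matrix(corr.values)
    merged = merge_clusters(clusters, consensus, normalized)
    bset = BiclusterSet(
        biclusters=[_to_bicluster(cl, matrix.condition_ids) for cl in merged],
        source_matrix_shape=matrix.shape,
    )
    if overlap_param == 1:
        bset = build_overlapping_biclusters(bset, normalized)
    if apply_select:
        cutoff = _resolve_cstar(cstar, matrix, seed)
        kept = select_calibration.filter_clusters(list(bset.biclusters), cutoff, n)
        bset = BiclusterSet(biclusters=kept, source_matrix_shape=matrix.shape)
    result = bset.sorted()
    logger.info("run_cg: %d final biclusters", len(result))
    return result


def _resolve_cstar(
    cstar: float | str, matrix: ExpressionMatrix, seed: int | None
) -> float:
    if cstar == "default":
        return select_calibration.default_cstar()
    if cstar == "calibrate":
        if seed is None:
            raise ValueError("cstar='calibrate' requires a seed")
        return select_calibration.calibrate_cutoff(
            matrix.n_genes, matrix.n_conditions, seed=seed
        ).cstar
    return float(cstar)


def _to_bicluster(cl: Cluster, condition_ids: list[str]) -> Bicluster:
    signs = None
    if cl.profile is not None:
        shared = {
            condition_ids[i]: int(s) for i, s in enumerate(cl.profile) if s != 0
        }
        signs = {g: shared for g in cl.genes}
    return Bicluster(
        genes=frozenset(cl.genes),
        conditions=cl.conditions,
        correlation=cl.correlation if cl.correlation is not None else _self_corr(cl),
        score=cl.score,
        signs=signs,
    )


def _self_corr(cl: Cluster) -> float | None:
    return 1.0 if cl.size == 1 else None


def cluster_stats_from_values(values: np.ndarray) -> list[tuple[int, float]]:
    """(size, within-correlation) of every cluster after the merge stage.

    Array-level pipeline used by calibration: no identifiers, no overlap,
    no selection.  Mirrors run_cg stage for stage on an unlabeled matrix.
    """
    values = np.asarray(values, dtype=float)
    n, c = values.shape
    norms = np.linalg.norm(values, axis=1)
    nonzero = norms > 0
    rows = values / np.where(nonzero, norms, 1.0)[:, None]
    sel = gap_select(rows)
    sel[~nonzero] = False
    states = np.where(sel, np.sign(values), 0.0).astype(np.int8)
    kept = np.flatnonzero(sel.any(axis=1))
    if kept.size == 0:
        return []
    profiles, members = _group_states(states, kept)
    sums, counts = _sum_vectors(rows, members)
    corr = _correlation_matrix_arrays(sums, counts.copy(), counts)
    consensus = consensus_from_matrix(corr)
    k = len(members)
    if not consensus.pairs:
        labels = np.arange(k)
    else:
        from scipy.sparse import coo_matrix
        from scipy.sparse.csgraph import connected_components

        pairs = list(consensus.pairs)
        graph = coo_matrix(
            (np.ones(len(pairs)),
             ([p[0] for p in pairs], [p[1] for p in pairs])),
            shape=(k, k),
        )
        _, labels = connected_components(graph, directed=False)
    stats: list[tuple[int, float]] = []
    for comp in np.unique(labels):
        idx = np.flatnonzero(labels == comp)
        ntot = int(counts[idx].sum())
        if idx.size == 1:
            i = int(idx[0])
            y = 1.0 if counts[i] < 2 else float(
                (sums[i] @ sums[i] - counts[i]) / (counts[i] * (counts[i] - 1.0))
            )
        else:
            s = sums[idx].sum(axis=0)
            y = float((s @ s - ntot) / (ntot * (ntot - 1.0)))
        stats.append((ntot, y))
    return stats
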