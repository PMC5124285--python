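"""Recovery/relevance scoring of bicluster sets and size diagnostics.

Two bicluster sets are compared with the asymmetric match score

    S(M1, M2) = (1/|M1|) * sum over b1 in M1 of max over b2 in M2 of s(b1, b2)

where s is either the element-wise Jaccard coefficient (matrix cells
shared by the two submatrices) or its conditions-only variant.  With E the
implanted (actual) biclusters and F the found ones, recovery = S(E, F)
and relevance = S(F, E).  A power-law fit to the cumulative cluster-size
distribution serves as a non-randomness diagnostic of clustering output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .matrix_io import Bicluster, BiclusterSet

__all__ = [
    "ScoreReport",
    "jaccard_elements",
    "jaccard_conditions",
    "match_score",
    "recovery_relevance",
    "size_distribution_powerlaw",
    "benchmark_replicates",
]

logger = logging.getLogger(__name__)


@dataclass
class ScoreReport:
    """Recovery/relevance pair plus each truth bicluster's best match."""

    recovery: float
    relevance: float
    per_bicluster_best: list[tuple[int, float]]
    found_empty: bool = False


def jaccard_elements(b1: Bicluster, b2: Bicluster) -> float:
    """Jaccard coefficient on matrix cells: |b1 ∩ b2| / |b1 ∪ b2|.

    A bicluster covers |genes| x |conditions| cells; the intersection
    covers the product of the shared gene and condition counts.
    """
    inter = len(b1.genes & b2.genes) * len(b1.conditions & b2.conditions)
    n1 = len(b1.genes) * len(b1.conditions)
    n2 = len(b2.genes) * len(b2.conditions)
    union = n1 + n2 - inter
    return inter / union if union else 0.0


def jaccard_conditions(b1: Bicluster, b2: Bicluster) -> float:
    """Jaccard coefficient on the condition sets only."""
    union = b1.conditions | b2.conditions
    return len(b1.conditions & b2.conditions) / len(union) if union else 0.0


_SIMILARITIES = {"elements": jaccard_elements, "conditions": jaccard_conditions}


def match_score(M1: BiclusterSet, M2: BiclusterSet, similarity: str = "elements") -> float:
    """Mean over M1 of the best similarity attained in M2 (asymmetric)."""
    if len(M1) == 0 or len(M2) == 0:
        raise ValueError("match_score is undefined for empty bicluster sets")
    sim = _SIMILARITIES[similarity]
    return float(
        np.mean([max(sim(b1, b2) for b2 in M2) for b1 in M1])
    )


def recovery_relevance(
    E: BiclusterSet, F: BiclusterSet, similarity: str = "elements"
) -> ScoreReport:
    """Recovery S(E, F) and relevance S(F, E) of found set F against truth E.

    An empty found set yields both scores 0, flagged in the report.  The
    per-bicluster entries are each truth bicluster's best similarity — the
    individual recovery scores.
    """
    if len(E) == 0:
        raise ValueError("truth set is empty")
    sim = _SIMILARITIES[similarity]
    if len(F) == 0:
        logger.info("recovery_relevance: found set empty")
        return ScoreReport(
            recovery=0.0, relevance=0.0,
            per_bicluster_best=[(i, 0.0) for i in range(len(E))],
            found_empty=True,
        )
    best = [(i, max(sim(e, f) for f in F)) for i, e in enumerate(E)]
    return ScoreReport(
        recovery=float(np.mean([b for _, b in best])),
        relevance=match_score(F, E, similarity),
        per_bicluster_best=best,
    )


def size_distribution_powerlaw(
    sizes, size_range: tuple[int, int]
) -> tuple[float, float]:
    """Fit log10(cumulative count of size >= s) against log10(s).

    ``sizes`` may be a list of cluster sizes or of objects with a ``size``
    attribute.  The fit runs over the distinct sizes falling inside
    ``size_range`` (inclusive); at least 3 distinct sizes are required.
    Returns (slope, r_squared).
    """
    vals = np.array(
        [s.size if hasattr(s, "size") and not isinstance(s, (int, np.integer)) else int(s)
         for s in sizes],
        dtype=float,
    )
    lo, hi = size_range
    grid = np.unique(vals[(vals >= lo) & (vals <= hi)])
    if grid.size < 3:
        raise ValueError(
            f"need >= 3 distinct sizes in [{lo}, {hi}], got {grid.size}"
        )
    cum = np.array([(vals >= s).sum() for s in grid], dtype=float)
    lx, ly = np.log10(grid), np.log10(cum)
    slope, intercept = np.polyfit(lx, ly, 1)
    fitted = slope * lx + intercept
    ss_res = float(((ly - fitted) ** 2).sum())
    ss_tot = float(((ly - ly.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return float(slope), float(r2)


def benchmark_replicates(
    noise_sd: float,
    overlap_degree: int = 0,
    n_replicates: int = 10,
    seed: int = 0,
    apply_select: bool = False,
    with_noisy_genes: bool = False,
    similarity: str = "elements",
) -> dict:
    """Mean recovery/relevance over seeded replicate simulations.

    Each replicate implants the ten-block dataset at the given noise and
    overlap, optionally appends an equal number of pure-noise genes, runs
    the pipeline without gene overlap, and scores against the implanted
    truth.  Returns mean and per-replicate scores.
    """
    from .pipeline import run_cg
    from .synthetic_data import append_noisy_genes, generate_block_dataset

    recs, rels = [], []
    for r in range(n_replicates):
        ds = generate_block_dataset(
            noise_sd=noise_sd, overlap_degree=overlap_degree, seed=seed + 7919 * r
        )
        if with_noisy_genes:
            ds = append_noisy_genes(ds, noise_sd, seed=seed + 7919 * r + 1)
        found = run_cg(ds.matrix, overlap_param=0, apply_select=apply_select)
        report = recovery_relevance(ds.truth, found, similarity)
        recs.append(report.recovery)
        rels.append(report.relevance)
    return {
        "noise_sd": noise_sd,
        "overlap_degree": overlap_degree,
        "recovery_mean": float(np.mean(recs)),
        "relevance_mean": float(np.mean(rels)),
        "recovery": recs,
        "relevance": rels,
    }
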