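"""Cluster scoring and random-matrix calibration of the selection cutoff.

Every cluster is scored as

    c = y + log(x) / log(N)

with y its within-correlation, x its gene count and N the gene count of
the input matrix.  The cutoff c* is the largest score that pure-noise
matrices of matching dimension can produce: for each noise level, run the
pipeline (through merging) on several Gaussian null matrices, keep the
per-matrix maximal score c-bar, take the per-level max and finally the max
over levels.  Clusters of a real dataset scoring strictly above c* are
deemed non-random.  Because every stage of the pipeline is invariant to a
positive rescaling of the matrix, the noise levels act as replicate
draws rather than genuinely different nulls; the cutoff is nevertheless
computed over the full grid the procedure prescribes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .clustering import Cluster

__all__ = [
    "CalibrationResult",
    "cluster_score",
    "calibrate_cutoff",
    "filter_clusters",
    "default_cstar",
    "DEFAULT_CSTAR",
    "DEFAULT_NOISE_LEVELS",
]

logger = logging.getLogger(__name__)

#: dimension-averaged cutoff usable on any dataset without recalibration
DEFAULT_CSTAR = 1.0887

#: noise standard deviations of the null matrices
DEFAULT_NOISE_LEVELS = (0.01, 0.05, 0.10)


@dataclass
class CalibrationResult:
    """Nested-max calibration record: per-matrix, per-level, and final cutoff."""

    per_matrix_cbar: list[list[float]]  # [level][matrix] -> c-bar
    per_noise_chat: list[float]  # per-level max of c-bar
    cstar: float
    noise_levels: list[float]
    n_matrices_per_level: int
    N: int
    C: int
    seed: int

    def __post_init__(self) -> None:
        flat = [c for level in self.per_matrix_cbar for c in level]
        if not all(math.isfinite(c) for c in flat + list(self.per_noise_chat)):
            raise ValueError("calibration produced non-finite scores")
        for level, chat in zip(self.per_matrix_cbar, self.per_noise_chat):
            if abs(chat - max(level)) > 1e-12:
                raise ValueError("per-level max inconsistent with per-matrix values")
        if abs(self.cstar - max(self.per_noise_chat)) > 1e-12:
            raise ValueError("cstar inconsistent with per-level maxima")

    def to_dict(self) -> dict:
        return {
            "cstar": self.cstar,
            "per_noise_chat": list(self.per_noise_chat),
            "per_matrix_cbar": [list(l) for l in self.per_matrix_cbar],
            "noise_levels": list(self.noise_levels),
            "n_matrices_per_level": self.n_matrices_per_level,
            "N": self.N,
            "C": self.C,
            "seed": self.seed,
        }


def cluster_score(x: int, y: float, N: int) -> float:
    """Score c = y + log(x)/log(N); base-independent, x >= 1, N >= 2."""
    if x < 1:
        raise ValueError("cluster size must be >= 1")
    if N < 2:
        raise ValueError("scoring needs N >= 2 genes in the input matrix")
    return float(y) + math.log(x) / math.log(N)


def default_cstar() -> float:
    """The dimension-averaged cutoff, for use without explicit calibration."""
    return DEFAULT_CSTAR


def filter_clusters(clusters: list[Cluster], cstar: float, N: int) -> list[Cluster]:
    """Keep clusters scoring strictly above the cutoff; order preserved.

    N is the gene count of the input matrix, not the number of clusters.
    Scores are stored on the clusters (kept and dropped alike).
    """
    kept: list[Cluster] = []
    for cl in clusters:
        y = cl.correlation if cl.correlation is not None else 1.0
        cl.score = cluster_score(cl.size, y, N)
        if cl.score > cstar:
            kept.append(cl)
    logger.info("filter_clusters: kept %d/%d at cutoff %.4f", len(kept), len(clusters), cstar)
    return kept


def _max_score_random_matrix(N: int, C: int, noise_sd: float, seed_key) -> float | None:
    """c-bar of one null matrix: max cluster score after the merge stage.

    Returns None when every gene was skipped (no clusters); callers retry
    with a fresh substream.
    """
    from .pipeline import cluster_stats_from_values  # deferred: avoids import cycle

    rng = np.random.default_rng(np.random.SeedSequence(seed_key))
    values = rng.normal(0.0, noise_sd, size=(N, C))
    stats = cluster_stats_from_values(values)
    if not stats:
        return None
    return max(cluster_score(x, y, N) for x, y in stats)


def calibrate_cutoff(
    N: int,
    C: int,
    noise_levels=DEFAULT_NOISE_LEVELS,
    n_matrices: int = 10,
    seed: int | None = None,
) -> CalibrationResult:
    """Compute c* for an N x C dataset from Gaussian null matrices.

    For each noise level, ``n_matrices`` N(0, sd) matrices are pushed
    through discretize -> group -> correlation -> checks -> merge (no
    overlap, no selection — selection is what is being calibrated) and the
    maximal cluster score per matrix is recorded.  c* is the max of the
    per-level maxima.  Deterministic given ``seed``; each (level, matrix)
    cell draws from its own substream.
    """
    if seed is None:
        raise ValueError("calibration requires an explicit seed")
    if N < 2 or C < 2:
        raise ValueError("calibration needs N >= 2 and C >= 2")
    noise_levels = list(noise_levels)
    if not noise_levels or any(sd <= 0 for sd in noise_levels):
        raise ValueError("noise levels must be positive")
    per_matrix: list[list[float]] = []
    for li, sd in enumerate(noise_levels):
        level_cbars: list[float] = []
        for mi in range(n_matrices):
            for attempt in range(100):
                cbar = _max_score_random_matrix(N, C, sd, (seed, li, mi, attempt))
                if cbar is not None:
                    break
                logger.info(
                    "calibrate: level %g matrix %d produced no clusters, retrying", sd, mi
                )
            else:  # pragma: no cover - would need 100 degenerate draws
                raise RuntimeError("null matrix repeatedly produced no clusters")
            level_cbars.append(cbar)
        per_matrix.append(level_cbars)
        logger.info("calibrate: level %g -> c-hat %.4f", sd, max(level_cbars))
    per_noise = [max(l) for l in per_matrix]
    result = CalibrationResult(
        per_matrix_cbar=per_matrix,
        per_noise_chat=per_noise,
        cstar=max(per_noise),
        noise_levels=noise_levels,
        n_matrices_per_level=n_matrices,
        N=N,
        C=C,
        seed=seed,
    )
    logger.info("calibrate: N=%d C=%d -> c* = %.4f", N, C, result.cstar)
    return result


def calibration_grid_mean(
    seed: int,
    n_matrices: int = 10,
    noise_levels=DEFAULT_NOISE_LEVELS,
    condition_grid=tuple(range(10, 101, 10)),
    gene_grid=tuple(range(1000, 10001, 1000)),
) -> tuple[float, list[CalibrationResult]]:
    """Mean c* over a dimension grid: C varied 10-fold at N=1000, then N
    varied 10-fold at C=10.  This mean is the recommended dataset-agnostic
    cutoff."""
    results: list[CalibrationResult] = []
    configs = [(1000, c) for c in condition_grid] + [(n, 10) for n in gene_grid]
    for i, (n, c) in enumerate(configs):
        results.append(
            calibrate_cutoff(
                n, c, noise_levels=noise_levels, n_matrices=n_matrices,
                seed=seed + 1000 * i,
            )
        )
    mean_cstar = float(np.mean([r.cstar for r in results]))
    logger.info("calibration grid: mean c* over %d configs = %.4f", len(configs), mean_cstar)
    return mean_cstar, results
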