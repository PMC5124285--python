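"""Implanted-bicluster simulation and Gaussian null matrices.

The benchmark datasets implant unit-valued diagonal blocks (the ground
truth biclusters) into a zero matrix, optionally letting consecutive
blocks share genes and conditions, then add i.i.d. Gaussian noise to every
entry.  Pure-noise matrices of arbitrary dimension back the score-cutoff
calibration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .matrix_io import Bicluster, BiclusterSet, ExpressionMatrix

__all__ = [
    "SyntheticDataset",
    "generate_block_dataset",
    "generate_narrow_block_dataset",
    "append_noisy_genes",
    "generate_random_matrix",
]


@dataclass
class SyntheticDataset:
    """A simulated matrix together with its implanted ground truth."""

    matrix: ExpressionMatrix
    truth: BiclusterSet
    noise_sd: float
    overlap_degree: int
    seed: int


def _gene_ids(n: int) -> list[str]:
    return [f"g{i + 1:04d}" for i in range(n)]


def _cond_ids(c: int) -> list[str]:
    return [f"c{j + 1:04d}" for j in range(c)]


def generate_block_dataset(
    n_blocks: int = 10,
    block_genes: int = 10,
    block_conds: int = 10,
    noise_sd: float = 0.0,
    overlap_degree: int = 0,
    seed: int = 0,
) -> SyntheticDataset:
    """Diagonal blocks of 1s in a zero matrix, plus Gaussian noise.

    With ``overlap_degree`` d > 0, consecutive blocks share d genes and d
    conditions (block origins step by block size minus d); shared cells
    stay at 1.  Defaults give the classic 100 x 100 matrix with ten
    10-gene x 10-condition blocks.
    """
    if not (0 <= overlap_degree < min(block_genes, block_conds)):
        raise ValueError(
            "overlap_degree must be in [0, min(block_genes, block_conds))"
        )
    g_step = block_genes - overlap_degree
    c_step = block_conds - overlap_degree
    n = block_genes + (n_blocks - 1) * g_step
    c = block_conds + (n_blocks - 1) * c_step
    gene_ids = _gene_ids(n)
    cond_ids = _cond_ids(c)
    base = np.zeros((n, c))
    truth: list[Bicluster] = []
    for b in range(n_blocks):
        g0, c0 = b * g_step, b * c_step
        base[g0 : g0 + block_genes, c0 : c0 + block_conds] = 1.0
        truth.append(
            Bicluster(
                genes=frozenset(gene_ids[g0 : g0 + block_genes]),
                conditions=frozenset(cond_ids[c0 : c0 + block_conds]),
            )
        )
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    values = base + (rng.normal(0.0, noise_sd, size=base.shape) if noise_sd > 0 else 0.0)
    return SyntheticDataset(
        matrix=ExpressionMatrix(values=values, gene_ids=gene_ids, condition_ids=cond_ids),
        truth=BiclusterSet(biclusters=truth, source_matrix_shape=(n, c)),
        noise_sd=noise_sd,
        overlap_degree=overlap_degree,
        seed=seed,
    )


def generate_narrow_block_dataset(noise_sd: float = 0.0, seed: int = 0) -> SyntheticDataset:
    """The 100 x 50 variant: ten 10-gene x 5-condition diagonal blocks."""
    return generate_block_dataset(
        n_blocks=10, block_genes=10, block_conds=5,
        noise_sd=noise_sd, overlap_degree=0, seed=seed,
    )


def append_noisy_genes(
    ds: SyntheticDataset, noise_sd: float, seed: int = 0
) -> SyntheticDataset:
    """Double the gene count with pure-noise rows; truth is unchanged."""
    mat = ds.matrix
    n, c = mat.shape
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    noise = rng.normal(0.0, noise_sd, size=(n, c))
    values = np.vstack([mat.values, noise])
    gene_ids = list(mat.gene_ids) + [f"noise{i + 1:04d}" for i in range(n)]
    return SyntheticDataset(
        matrix=ExpressionMatrix(
            values=values, gene_ids=gene_ids, condition_ids=list(mat.condition_ids)
        ),
        truth=BiclusterSet(
            biclusters=list(ds.truth.biclusters), source_matrix_shape=(2 * n, c)
        ),
        noise_sd=noise_sd,
        overlap_degree=ds.overlap_degree,
        seed=seed,
    )


def generate_random_matrix(
    N: int, C: int, noise_sd: float, seed: int = 0
) -> ExpressionMatrix:
    """Pure-noise N x C matrix of i.i.d. N(0, noise_sd) entries."""
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    return ExpressionMatrix(
        values=rng.normal(0.0, noise_sd, size=(N, C)),
        gene_ids=_gene_ids(N),
        condition_ids=_cond_ids(C),
    )
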