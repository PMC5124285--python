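"""Threshold-free discretization of expression profiles.

Each gene's profile is reduced to signed states in {-1, 0, +1}: the
conditions where the gene is "expressed" are those whose sorted absolute
normalized values sit above the single largest consecutive gap in the
sorted sequence, and each selected condition carries the sign of the raw
value there.  Two conventional fixed-cutoff discretizers (2-fold change on
a log2 scale, and a per-gene Z-score) are provided for comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .matrix_io import ExpressionMatrix

__all__ = [
    "SignedDiscreteProfile",
    "DiscretizationResult",
    "l2_normalize",
    "discretize_profile",
    "discretize_matrix",
    "discretize_foldchange",
    "discretize_zscore",
    "gap_select",
]

logger = logging.getLogger(__name__)

#: tolerance on the row norm accepted by discretize_profile
_NORM_TOL = 1e-6


@dataclass(frozen=True)
class SignedDiscreteProfile:
    """Per-gene signed states over conditions: -1 down, 0 off, +1 up."""

    states: tuple[int, ...]

    @property
    def selected(self) -> frozenset[int]:
        return frozenset(i for i, s in enumerate(self.states) if s != 0)

    def __len__(self) -> int:
        return len(self.states)


@dataclass
class DiscretizationResult:
    """Signed state matrix plus the skip report of non-discretizable genes."""

    states: np.ndarray  # (N, C) int8 in {-1, 0, +1}; skipped rows all-zero
    kept: np.ndarray  # indices of genes with a nonempty selection
    skipped: list[tuple[str, str]]  # (gene_id, reason)

    def profile(self, row: int) -> SignedDiscreteProfile:
        return SignedDiscreteProfile(tuple(int(s) for s in self.states[row]))


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def l2_normalize(matrix: ExpressionMatrix) -> tuple[ExpressionMatrix, list[tuple[str, str]]]:
    """Scale each gene row to unit Euclidean norm.

    All-zero rows cannot be normalized; they are left as zeros and reported
    in the returned skip list as ``(gene_id, "zero norm")``.
    """
    norms = np.linalg.norm(matrix.values, axis=1)
    zero = norms == 0.0
    safe = np.where(zero, 1.0, norms)
    values = matrix.values / safe[:, None]
    skipped = [(matrix.gene_ids[i], "zero norm") for i in np.flatnonzero(zero)]
    if skipped:
        logger.info("l2_normalize: %d gene(s) skipped (zero norm)", len(skipped))
    out = ExpressionMatrix(
        values=values,
        gene_ids=list(matrix.gene_ids),
        condition_ids=list(matrix.condition_ids),
    )
    return out, skipped


# ---------------------------------------------------------------------------
# Maximum-gap selection
# ---------------------------------------------------------------------------

def gap_select(values: np.ndarray) -> np.ndarray:
    """Vectorized maximum-gap selection on the rows of ``values``.

    For each row, sort the absolute values ascending (stable, so ties keep
    original order), take consecutive differences, locate the largest gap
    (ties broken toward the largest index, i.e. the fewest selections), and
    mark every entry whose sorted rank lies above the gap.  Rows whose
    entries are all equal in magnitude have no gap and select nothing.

    Returns a boolean matrix of the same shape.  This kernel is shared by
    the profile discretizer and the cluster-merge checkpoints (which apply
    it to rows of the cluster correlation matrix).
    """
    a = np.abs(np.asarray(values, dtype=float))
    if a.ndim == 1:
        return gap_select(a[None, :])[0]
    return _gap_select_abs(a)


def _gap_select_abs(a: np.ndarray) -> np.ndarray:
    """gap_select kernel on an already-nonnegative 2-D array (no abs copy)."""
    n, m = a.shape
    if m < 2:
        raise ValueError("gap selection needs at least two entries per row")
    v = np.sort(a, axis=1)
    d = v[:, 1:] - v[:, :-1]  # d[:, j] = gap between sorted ranks j and j+1
    # argmax with largest-index tie-break, via argmax on the reversed gaps
    jstar = (m - 2) - np.argmax(d[:, ::-1], axis=1)
    rows = np.arange(n)
    maxgap = d[rows, jstar]
    # the max gap is strictly positive, so "sorted rank above the gap" is
    # exactly "value >= smallest value above the gap" (equal values can
    # never straddle a positive gap)
    sel = a >= v[rows, jstar + 1][:, None]
    sel[maxgap == 0.0] = False
    return sel


def discretize_profile(
    normalized_row: np.ndarray, raw_row: np.ndarray | None = None
) -> SignedDiscreteProfile:
    """Discretize one unit-norm profile by its maximum gap.

    ``raw_row`` supplies the signs; the normalized row may be used when raw
    values are unavailable (normalization preserves signs).  A row whose
    norm deviates from 1 by more than 1e-6 violates the contract.
    """
    row = np.asarray(normalized_row, dtype=float)
    if row.ndim != 1 or row.size < 2:
        raise ValueError("profile must be a 1-D vector with at least 2 entries")
    norm = float(np.linalg.norm(row))
    if abs(norm - 1.0) > _NORM_TOL:
        raise ValueError(f"profile is not L2-normalized (norm={norm:.6g})")
    signs_from = row if raw_row is None else np.asarray(raw_row, dtype=float)
    sel = gap_select(row)
    states = np.where(sel, np.sign(signs_from), 0.0).astype(np.int8)
    return SignedDiscreteProfile(tuple(int(s) for s in states))


def discretize_matrix(matrix: ExpressionMatrix) -> DiscretizationResult:
    """Normalize and gap-discretize every gene of an expression matrix.

    Genes that cannot be discretized — all-zero rows, or rows whose
    absolute values are all equal so that no gap exists — end up in the
    skip report and are excluded from clustering.
    """
    normalized, skipped = l2_normalize(matrix)
    zero_rows = {g for g, _ in skipped}
    sel = gap_select(normalized.values)
    states = np.where(sel, np.sign(matrix.values), 0.0).astype(np.int8)
    empty = ~sel.any(axis=1)
    skip_list = list(skipped)
    for i in np.flatnonzero(empty):
        gid = matrix.gene_ids[i]
        if gid not in zero_rows:
            skip_list.append((gid, "no gap (all values equal in magnitude)"))
    states[empty] = 0
    kept = np.flatnonzero(~empty)
    logger.info(
        "discretize_matrix: %d/%d genes discretized, %d skipped",
        kept.size, matrix.n_genes, len(skip_list),
    )
    return DiscretizationResult(states=states, kept=kept, skipped=skip_list)


# ---------------------------------------------------------------------------
# Fixed-cutoff comparison discretizers
# ---------------------------------------------------------------------------

def discretize_foldchange(
    matrix: ExpressionMatrix, log_threshold: float = 1.0
) -> DiscretizationResult:
    """Fixed fold-change cutoff on log2 data: |value| >= log_threshold.

    The default of 1.0 corresponds to a 2-fold change on the log2 scale;
    the boundary is inclusive.
    """
    sel = np.abs(matrix.values) >= log_threshold
    states = np.where(sel, np.sign(matrix.values), 0.0).astype(np.int8)
    empty = ~sel.any(axis=1)
    skip_list = [
        (matrix.gene_ids[i], "no condition beyond fold-change cutoff")
        for i in np.flatnonzero(empty)
    ]
    return DiscretizationResult(
        states=states, kept=np.flatnonzero(~empty), skipped=skip_list
    )


def discretize_zscore(matrix: ExpressionMatrix, z: float = 1.5) -> DiscretizationResult:
    """Per-gene Z-score cutoff: |value - mean| / sd >= z, sample (n-1) sd.

    Constant genes (sd == 0) select nothing.  Signs come from the deviation
    from the gene's own mean, so a condition below the mean is "down" even
    if its raw value is positive.
    """
    mean = matrix.values.mean(axis=1, keepdims=True)
    sd = matrix.values.std(axis=1, ddof=1, keepdims=True)
    dev = matrix.values - mean
    with np.errstate(divide="ignore", invalid="ignore"):
        zval = np.where(sd > 0, np.abs(dev) / sd, 0.0)
    sel = zval >= z
    states = np.where(sel, np.sign(dev), 0.0).astype(np.int8)
    empty = ~sel.any(axis=1)
    skip_list = [
        (matrix.gene_ids[i], "no condition beyond z cutoff")
        for i in np.flatnonzero(empty)
    ]
    return DiscretizationResult(
        states=states, kept=np.flatnonzero(~empty), skipped=skip_list
    )
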