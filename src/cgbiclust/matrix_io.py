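"""Expression-matrix and bicluster containers, with tab-separated / JSON I/O.

The on-disk matrix dialect is the plain GEO-style table: a header row of
condition identifiers, a first column of gene identifiers, and real-valued
cells.  Bicluster sets round-trip through either JSON (one object per
bicluster) or TSV (one row per bicluster with semicolon-joined members).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "Bicluster",
    "BiclusterSet",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_biclusters",
    "write_biclusters",
]


@dataclass
class ExpressionMatrix:
    """A named genes x conditions real matrix.

    Parameters
    ----------
    values : (N, C) float array, no missing entries.
    gene_ids : N unique row labels.
    condition_ids : C unique column labels; C >= 2 is required because a
        single-condition profile cannot be discretized by gaps.
    """

    values: np.ndarray
    gene_ids: list[str]
    condition_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.condition_ids = [str(c) for c in self.condition_ids]
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        n, c = self.values.shape
        if n != len(self.gene_ids):
            raise ValueError(
                f"{len(self.gene_ids)} gene ids for {n} rows"
            )
        if c != len(self.condition_ids):
            raise ValueError(
                f"{len(self.condition_ids)} condition ids for {c} columns"
            )
        if n < 1:
            raise ValueError("matrix needs at least one gene")
        if c < 2:
            raise ValueError("matrix needs at least two conditions")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("matrix contains missing or non-finite entries")
        for name, ids in (("gene", self.gene_ids), ("condition", self.condition_ids)):
            dup = _first_duplicate(ids)
            if dup is not None:
                raise ValueError(f"duplicate {name} id: {dup!r}")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_conditions(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}

    def condition_index(self) -> dict[str, int]:
        return {c: j for j, c in enumerate(self.condition_ids)}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.gene_ids, columns=self.condition_ids
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ExpressionMatrix":
        return cls(
            values=frame.to_numpy(dtype=float),
            gene_ids=[str(i) for i in frame.index],
            condition_ids=[str(c) for c in frame.columns],
        )


def _first_duplicate(ids: Sequence[str]) -> str | None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            return x
        seen.add(x)
    return None


@dataclass
class Bicluster:
    """A gene set paired with the condition set where the genes co-express.

    ``size`` is the number of genes (the x of the score), ``correlation``
    the mean pairwise cosine similarity of the member genes' normalized
    profiles (the y), and ``score`` the value y + log(x)/log(N) once the
    selection stage has filled it in.  ``signs`` optionally records, per
    gene, the up/down direction on each member condition.
    """

    genes: frozenset[str]
    conditions: frozenset[str]
    correlation: float | None = None
    score: float | None = None
    signs: Mapping[str, Mapping[str, int]] | None = None

    def __post_init__(self) -> None:
        self.genes = frozenset(str(g) for g in self.genes)
        self.conditions = frozenset(str(c) for c in self.conditions)
        if not self.genes:
            raise ValueError("bicluster has no genes")
        if not self.conditions:
            raise ValueError("bicluster has no conditions")

    @property
    def size(self) -> int:
        return len(self.genes)

    def key(self) -> tuple[frozenset[str], frozenset[str]]:
        return (self.genes, self.conditions)


@dataclass
class BiclusterSet:
    """An ordered collection of biclusters from one source matrix."""

    biclusters: list[Bicluster] = field(default_factory=list)
    source_matrix_shape: tuple[int, int] | None = None

    def __len__(self) -> int:
        return len(self.biclusters)

    def __iter__(self) -> Iterator[Bicluster]:
        return iter(self.biclusters)

    def __getitem__(self, i: int) -> Bicluster:
        return self.biclusters[i]

    def validate_against(self, matrix: ExpressionMatrix) -> None:
        genes = set(matrix.gene_ids)
        conds = set(matrix.condition_ids)
        for b in self.biclusters:
            missing_g = b.genes - genes
            missing_c = b.conditions - conds
            if missing_g:
                raise ValueError(f"unknown gene id(s): {sorted(missing_g)[:5]}")
            if missing_c:
                raise ValueError(f"unknown condition id(s): {sorted(missing_c)[:5]}")

    def sorted(self) -> "BiclusterSet":
        """Deterministic order: size desc, correlation desc, smallest gene id."""

        def keyfn(b: Bicluster):
            corr = b.correlation if b.correlation is not None else float("-inf")
            return (-b.size, -corr, min(b.genes))

        return BiclusterSet(
            biclusters=sorted(self.biclusters, key=keyfn),
            source_matrix_shape=self.source_matrix_shape,
        )


# ---------------------------------------------------------------------------
# Expression-matrix I/O
# ---------------------------------------------------------------------------

def read_expression_matrix(path, delimiter: str = "\t") -> ExpressionMatrix:
    """Read a delimited expression table (header = conditions, col 0 = genes).

    Raises ``ValueError`` naming the offending cell for non-numeric entries,
    the offending id for duplicates, and the offending row for ragged lines.
    """
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split(delimiter)
        # header may or may not carry a corner label for the id column
        rows: list[list[str]] = []
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            rows.append(line.split(delimiter))
    if not rows:
        raise ValueError(f"{path}: no data rows")
    width = len(rows[0])
    conds = header[-(width - 1):] if len(header) >= width - 1 else header
    if len(conds) != width - 1:
        raise ValueError(f"{path}: header has {len(header)} fields for {width - 1} data columns")
    gene_ids: list[str] = []
    values = np.empty((len(rows), width - 1), dtype=float)
    for i, row in enumerate(rows):
        if len(row) != width:
            raise ValueError(
                f"{path}: ragged row {i + 2} ({len(row)} fields, expected {width})"
            )
        gene_ids.append(row[0])
        for j, cell in enumerate(row[1:]):
            try:
                values[i, j] = float(cell)
            except ValueError:
                raise ValueError(
                    f"{path}: non-numeric value {cell!r} at row {i + 2}, "
                    f"column {conds[j]!r}"
                ) from None
    return ExpressionMatrix(values=values, gene_ids=gene_ids, condition_ids=conds)


def write_expression_matrix(
    matrix: ExpressionMatrix, path, delimiter: str = "\t"
) -> None:
    matrix.to_frame().to_csv(path, sep=delimiter, index_label="gene_id")


# ---------------------------------------------------------------------------
# Bicluster-set I/O
# ---------------------------------------------------------------------------

def write_biclusters(bset: BiclusterSet, path, format: str = "json") -> None:
    """Serialize a bicluster set to JSON or TSV; inverse of read_biclusters."""
    if format == "json":
        payload = {
            "source_matrix_shape": list(bset.source_matrix_shape)
            if bset.source_matrix_shape
            else None,
            "biclusters": [
                {
                    "genes": sorted(b.genes),
                    "conditions": sorted(b.conditions),
                    "size": b.size,
                    "correlation": b.correlation,
                    "score": b.score,
                }
                for b in bset
            ],
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1)
            fh.write("\n")
    elif format == "tsv":
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("genes\tconditions\tsize\tcorrelation\tscore\n")
            for b in bset:
                corr = "NA" if b.correlation is None else repr(b.correlation)
                score = "NA" if b.score is None else repr(b.score)
                fh.write(
                    ";".join(sorted(b.genes))
                    + "\t"
                    + ";".join(sorted(b.conditions))
                    + f"\t{b.size}\t{corr}\t{score}\n"
                )
    else:
        raise ValueError(f"unknown format {format!r} (expected 'json' or 'tsv')")


def read_biclusters(path, format: str = "json") -> BiclusterSet:
    if format == "json":
        with open(path, "r", encoding="utf-8") as fh:
            payload = json.load(fh)
        shape = payload.get("source_matrix_shape")
        return BiclusterSet(
            biclusters=[
                Bicluster(
                    genes=frozenset(d["genes"]),
                    conditions=frozenset(d["conditions"]),
                    correlation=d.get("correlation"),
                    score=d.get("score"),
                )
                for d in payload["biclusters"]
            ],
            source_matrix_shape=tuple(shape) if shape else None,
        )
    elif format == "tsv":
        out: list[Bicluster] = []
        with open(path, "r", encoding="utf-8") as fh:
            next(fh)  # header
            for line in fh:
                if not line.strip():
                    continue
                genes_s, conds_s, _size, corr_s, score_s = line.rstrip("\n").split("\t")
                out.append(
                    Bicluster(
                        genes=frozenset(genes_s.split(";")),
                        conditions=frozenset(conds_s.split(";")),
                        correlation=None if corr_s == "NA" else float(corr_s),
                        score=None if score_s == "NA" else float(score_s),
                    )
                )
        return BiclusterSet(biclusters=out)
    else:
        raise ValueError(f"unknown format {format!r} (expected 'json' or 'tsv')")
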