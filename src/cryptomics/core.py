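"""Core data model: count matrices, cell annotations, signatures, normalization.

The in-memory substrate shared by every analysis stage. Counts are kept
sparse (CSR, cells x genes); all identifiers are opaque, case-preserved
strings matched exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "CountMatrix",
    "CellAnnotation",
    "ExpressionMatrix",
    "SignatureSet",
    "ValidationError",
    "normalize_log1p_cpm",
]


class ValidationError(ValueError):
    """An input violated a structural invariant (shape, ids, sign, domain)."""


def _check_unique(ids: list[str], what: str) -> None:
    if len(set(ids)) != len(ids):
        dupes = pd.Index(ids)[pd.Index(ids).duplicated()].unique().tolist()
        raise ValidationError(f"duplicate {what} ids: {dupes[:5]}")


@dataclass
class CountMatrix:
    """Non-negative integer cell x gene count matrix with string identifiers.

    Parameters
    ----------
    counts
        Sparse or dense matrix, cells in rows, genes in columns. Stored as
        CSR with an integer dtype.
    cell_ids, gene_ids
        Unique identifier lists matching the matrix dimensions.
    """

    counts: sp.csr_matrix
    cell_ids: list[str]
    gene_ids: list[str]

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        n, g = self.counts.shape
        if len(self.cell_ids) != n:
            raise ValidationError(
                f"{len(self.cell_ids)} cell ids for {n} matrix rows"
            )
        if len(self.gene_ids) != g:
            raise ValidationError(
                f"{len(self.gene_ids)} gene ids for {g} matrix columns"
            )
        _check_unique(self.cell_ids, "cell")
        _check_unique(self.gene_ids, "gene")
        data = self.counts.data
        if data.size and data.min() < 0:
            raise ValidationError("negative counts present")
        if not np.issubdtype(data.dtype, np.integer):
            if data.size and not np.allclose(data, np.round(data)):
                raise ValidationError("non-integer count entries present")
            self.counts = self.counts.astype(np.int64)

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def cell_totals(self) -> np.ndarray:
        return np.asarray(self.counts.sum(axis=1)).ravel()

    def to_dense(self) -> np.ndarray:
        return self.counts.toarray()


@dataclass
class CellAnnotation:
    """Per-cell factors: sample of origin, condition, cluster, optional labels.

    ``condition`` must be a two-level factor wherever condition contrasts are
    computed; this is validated lazily by the stages that need it.
    """

    table: pd.DataFrame  # indexed by cell_id

    REQUIRED = ("sample", "condition", "cluster")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValidationError(f"annotation missing columns: {missing}")
        if self.table.index.duplicated().any():
            raise ValidationError("duplicate cell ids in annotation")

    def validate_against(self, matrix: CountMatrix) -> None:
        missing = set(self.table.index) - set(matrix.cell_ids)
        if missing:
            raise ValidationError(
                f"{len(missing)} annotated cells absent from count matrix, "
                f"e.g. {sorted(missing)[:3]}"
            )

    def condition_levels(self) -> list[str]:
        levels = sorted(self.table["condition"].unique().tolist())
        if len(levels) != 2:
            raise ValidationError(
                f"condition must have exactly 2 levels, found {levels}"
            )
        return levels

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class ExpressionMatrix:
    """Log-normalized real-valued expression, same shape/ids as its source."""

    values: np.ndarray  # dense cells x genes, float
    cell_ids: list[str]
    gene_ids: list[str]
    scale: float = 1e4
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("non-finite expression values")
        n, g = self.values.shape
        if len(self.cell_ids) != n or len(self.gene_ids) != g:
            raise ValidationError("id lists do not match matrix shape")
        _check_unique(self.cell_ids, "cell")
        _check_unique(self.gene_ids, "gene")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def gene_index(self, genes: list[str], on_missing: str = "drop") -> np.ndarray:
        """Column indices for ``genes``; unknown genes dropped or fatal."""
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        found = [lookup[g] for g in genes if g in lookup]
        if on_missing == "error" and len(found) != len(genes):
            missing = [g for g in genes if g not in lookup]
            raise ValidationError(f"genes absent from matrix: {missing[:5]}")
        return np.asarray(found, dtype=int)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.cell_ids, columns=self.gene_ids)


@dataclass
class SignatureSet:
    """A named gene list, optionally signed (+1 up, -1 down)."""

    name: str
    genes: list[str]
    weights: list[int] | None = None

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValidationError(f"signature {self.name!r} is empty")
        if self.weights is not None and len(self.weights) != len(self.genes):
            raise ValidationError("weights length != genes length")

    def matched(self, universe: list[str]) -> "SignatureSet":
        """Restrict to genes present in ``universe`` (order preserved)."""
        present = set(universe)
        keep = [i for i, g in enumerate(self.genes) if g in present]
        if not keep:
            raise ValidationError(
                f"no gene of signature {self.name!r} found in matrix"
            )
        return SignatureSet(
            self.name,
            [self.genes[i] for i in keep],
            None if self.weights is None else [self.weights[i] for i in keep],
        )


def normalize_log1p_cpm(matrix: CountMatrix, scale: float = 1e4) -> ExpressionMatrix:
    """Library-size normalize to ``scale`` counts per cell, then log1p.

    value = log(1 + scale * count / cell_total).  Zeros stay zero and the
    result is invariant to multiplying a cell's counts by a constant.

    Raises
    ------
    ValidationError
        If any cell has zero total count (lists the offending cell ids).
    """
    totals = matrix.cell_totals().astype(float)
    zero = totals == 0
    if zero.any():
        bad = [matrix.cell_ids[i] for i in np.flatnonzero(zero)[:10]]
        raise ValidationError(f"all-zero cells cannot be normalized: {bad}")
    dense = matrix.counts.toarray().astype(float)
    values = np.log1p(scale * dense / totals[:, None])
    return ExpressionMatrix(
        values=values,
        cell_ids=list(matrix.cell_ids),
        gene_ids=list(matrix.gene_ids),
        scale=scale,
        pseudocount=1.0,
    )
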