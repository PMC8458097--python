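"""File I/O: MatrixMarket counts with TSV sidecars, annotations, signatures.

Formats are deliberately plain text: MTX + one-column TSVs for counts,
TSV for cell annotations and signatures, CSV/JSON for results.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io as sio
import scipy.sparse as sp

from .core import CellAnnotation, CountMatrix, SignatureSet, ValidationError

__all__ = [
    "read_count_matrix",
    "write_count_matrix",
    "read_annotation",
    "write_annotation",
    "read_signatures",
    "write_signatures",
    "read_reaction_map",
    "write_reaction_map",
]


def _read_id_column(path: str | Path, what: str) -> list[str]:
    ids = pd.read_csv(path, sep="\t", header=None, dtype=str)[0].tolist()
    if len(set(ids)) != len(ids):
        raise ValidationError(f"duplicate ids in {what} file {path}")
    return ids


def read_count_matrix(
    mtx_path: str | Path,
    cells_path: str | Path,
    genes_path: str | Path,
    transposed: bool | None = None,
) -> CountMatrix:
    """Read a MatrixMarket coordinate file plus id sidecars.

    Parameters
    ----------
    transposed
        ``None`` (default) auto-detects orientation from the id counts;
        ``True`` forces interpretation of the MTX as genes x cells;
        ``False`` forces cells x genes.
    """
    try:
        mat = sp.csr_matrix(sio.mmread(str(mtx_path)))
    except Exception as exc:  # pragma: no cover - scipy error text varies
        raise ValidationError(f"cannot parse MatrixMarket file {mtx_path}: {exc}")
    cells = _read_id_column(cells_path, "cells")
    genes = _read_id_column(genes_path, "genes")
    n_rows, n_cols = mat.shape
    if transposed is None:
        if (n_rows, n_cols) == (len(cells), len(genes)):
            transposed = False
        elif (n_rows, n_cols) == (len(genes), len(cells)):
            transposed = True
        else:
            raise ValidationError(
                f"matrix {mat.shape} in {mtx_path} matches neither "
                f"{len(cells)} cells x {len(genes)} genes nor its transpose"
            )
    if transposed:
        mat = sp.csr_matrix(mat.T)
    if mat.shape != (len(cells), len(genes)):
        raise ValidationError(
            f"matrix {mat.shape} in {mtx_path} does not match id files "
            f"({len(cells)} cells in {cells_path}, {len(genes)} genes in {genes_path})"
        )
    if mat.data.size and not np.issubdtype(mat.data.dtype, np.integer):
        if not np.allclose(mat.data, np.round(mat.data)):
            raise ValidationError(f"non-integer entries in {mtx_path}")
        mat = mat.astype(np.int64)
    return CountMatrix(counts=mat, cell_ids=cells, gene_ids=genes)


def write_count_matrix(
    matrix: CountMatrix,
    mtx_path: str | Path,
    cells_path: str | Path,
    genes_path: str | Path,
) -> None:
    sio.mmwrite(str(mtx_path), matrix.counts.tocoo(), field="integer")
    pd.Series(matrix.cell_ids).to_csv(cells_path, sep="\t", header=False, index=False)
    pd.Series(matrix.gene_ids).to_csv(genes_path, sep="\t", header=False, index=False)


def read_annotation(path: str | Path) -> CellAnnotation:
    """Read a TSV of per-cell factors; first column is the cell id."""
    table = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    return CellAnnotation(table=table)


def write_annotation(annotation: CellAnnotation, path: str | Path) -> None:
    annotation.table.to_csv(path, sep="\t", index_label="cell_id")


def read_signatures(path: str | Path) -> dict[str, SignatureSet]:
    """Read a two/three-column TSV: set_name, gene [, weight]."""
    table = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if table.shape[1] < 2:
        raise ValidationError(f"signature file {path} needs >=2 columns")
    out: dict[str, SignatureSet] = {}
    for name, grp in table.groupby(0, sort=False):
        genes = grp[1].tolist()
        weights = None
        if table.shape[1] >= 3 and grp[2].notna().all():
            weights = grp[2].astype(int).tolist()
        out[str(name)] = SignatureSet(str(name), genes, weights)
    return out


def write_signatures(signatures: dict[str, SignatureSet], path: str | Path) -> None:
    rows = []
    for sig in signatures.values():
        for i, g in enumerate(sig.genes):
            w = "" if sig.weights is None else sig.weights[i]
            rows.append((sig.name, g, w))
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def load_default_signatures() -> dict[str, SignatureSet]:
    """The bundled signature lists: canonical S/G2M cell-cycle genes plus
    placeholder proximal/distal sets (replace the latter for real data)."""
    from importlib.resources import files

    path = files("cryptomics").joinpath("data/default_signatures.tsv")
    return read_signatures(str(path))


def read_reaction_map(path: str | Path) -> dict:
    """Read a reaction map as JSON: {reaction: {genes, metabolites, pathway}}."""
    with open(path) as fh:
        raw = json.load(fh)
    return raw


def write_reaction_map(rmap: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(rmap, fh, indent=1, sort_keys=True)
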