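"""Readers and writers for matrices and annotations.

Supported on-disk formats:

* MatrixMarket ``.mtx`` with sidecar one-id-per-line gene and cell lists.
  CellRanger-style files are genes × cells; they are transposed on load so
  the in-memory orientation is always cells × genes.
* Dense delimited tables (TSV/CSV): header row = gene ids, first column =
  cell ids.
* Annotation TSV with columns ``cell_id`` and ``group``.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import scipy.io
import scipy.sparse as sp

from .matrix import COUNTS, CellAnnotation, ExpressionMatrix


def _read_ids(path: str | Path) -> list[str]:
    return [line.strip() for line in Path(path).read_text().splitlines()
            if line.strip()]


def read_mtx(mtx_path: str | Path, genes_path: str | Path,
             cells_path: str | Path, layer_tag: str = COUNTS,
             orientation: str = "genes_by_cells") -> ExpressionMatrix:
    """Load a MatrixMarket matrix with sidecar gene/cell id lists.

    ``orientation`` says how the file is laid out; ``genes_by_cells`` (the
    CellRanger convention) is transposed on load.
    """
    X = sp.csr_matrix(scipy.io.mmread(str(mtx_path)))
    if orientation == "genes_by_cells":
        X = X.T.tocsr()
    elif orientation != "cells_by_genes":
        raise ValueError(f"unknown orientation {orientation!r}")
    return ExpressionMatrix(X, _read_ids(genes_path), _read_ids(cells_path),
                            layer_tag=layer_tag)


def write_mtx(matrix: ExpressionMatrix, mtx_path: str | Path,
              genes_path: str | Path, cells_path: str | Path,
              orientation: str = "genes_by_cells") -> None:
    X = matrix.values
    if orientation == "genes_by_cells":
        X = X.T
    elif orientation != "cells_by_genes":
        raise ValueError(f"unknown orientation {orientation!r}")
    scipy.io.mmwrite(str(mtx_path), X)
    Path(genes_path).write_text("\n".join(matrix.gene_ids) + "\n")
    Path(cells_path).write_text("\n".join(matrix.cell_ids) + "\n")


def read_dense(path: str | Path, layer_tag: str = COUNTS,
               sep: str | None = None) -> ExpressionMatrix:
    """Read a dense cells × genes table (header = gene ids, col 0 = cell ids)."""
    path = Path(path)
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    frame = pd.read_csv(path, sep=sep, index_col=0)
    return ExpressionMatrix.from_frame(frame, layer_tag=layer_tag)


def write_dense(matrix: ExpressionMatrix, path: str | Path,
                sep: str | None = None) -> None:
    path = Path(path)
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    matrix.to_frame().to_csv(path, sep=sep)


def read_annotation(path: str | Path) -> CellAnnotation:
    """Read a TSV with columns ``cell_id`` and ``group``."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("cell_id", "group"):
        if col not in frame.columns:
            raise ValueError(f"annotation file is missing column {col!r}")
    return CellAnnotation(frame.set_index("cell_id")["group"])


def write_annotation(annotation: CellAnnotation, path: str | Path) -> None:
    annotation.to_frame().to_csv(path, sep="\t", index=False)


def read_matrix_auto(path: str | Path, genes: str | Path | None = None,
                     cells: str | Path | None = None,
                     layer_tag: str = COUNTS) -> ExpressionMatrix:
    """Dispatch on extension: ``.mtx`` (needs sidecars) or dense table."""
    path = Path(path)
    if path.suffix.lower() == ".mtx":
        if genes is None or cells is None:
            raise ValueError("MTX input requires gene and cell id sidecar files")
        return read_mtx(path, genes, cells, layer_tag=layer_tag)
    return read_dense(path, layer_tag=layer_tag)
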