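"""Core expression-matrix container and per-cell utilities.

The central object is :class:`ExpressionMatrix`: a non-negative cells × genes
matrix with unique string identifiers on both axes and a layer tag saying
whether the values are raw counts or normalized expression.  Cells are rows
and genes are columns throughout the package; per-cell operations (ranking,
gene counting, depth normalization) dominate every downstream computation,
so the row axis is the cell axis.  Values are held sparse (CSR) internally
because scRNA-seq matrices are mostly zeros; dense inputs are accepted and
converted.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import scipy.sparse as sp

log = logging.getLogger(__name__)

#: layer tags
COUNTS = "counts"
NORMALIZED = "normalized"


class ExpressionMatrix:
    """Non-negative cells × genes expression matrix with identifiers.

    Parameters
    ----------
    values
        Dense array, sparse matrix, or anything ``scipy.sparse.csr_matrix``
        accepts, of shape ``(n_cells, n_genes)``.  All entries must be
        non-negative; a ``counts`` layer must be integer-valued.
    gene_ids, cell_ids
        Ordered, unique string identifiers for columns and rows.
    layer_tag
        ``"counts"`` or ``"normalized"``.
    """

    def __init__(self, values, gene_ids: Iterable[str], cell_ids: Iterable[str],
                 layer_tag: str = COUNTS):
        X = sp.csr_matrix(values, dtype=np.float64)
        X = X.copy()
        X.eliminate_zeros()
        X.sort_indices()
        gene_index = pd.Index([str(g) for g in gene_ids], name="gene_id")
        cell_index = pd.Index([str(c) for c in cell_ids], name="cell_id")
        if gene_index.has_duplicates:
            dup = gene_index[gene_index.duplicated()][0]
            raise ValueError(f"duplicate gene identifier: {dup!r}")
        if cell_index.has_duplicates:
            dup = cell_index[cell_index.duplicated()][0]
            raise ValueError(f"duplicate cell identifier: {dup!r}")
        if X.shape != (len(cell_index), len(gene_index)):
            raise ValueError(
                f"matrix shape {X.shape} does not match "
                f"{len(cell_index)} cells x {len(gene_index)} genes")
        if X.nnz and X.data.min() < 0:
            raise ValueError("expression values must be non-negative")
        if layer_tag not in (COUNTS, NORMALIZED):
            raise ValueError(f"unknown layer tag {layer_tag!r}")
        if layer_tag == COUNTS and X.nnz and np.any(X.data != np.round(X.data)):
            raise ValueError("counts layer contains non-integer values")
        self.values: sp.csr_matrix = X
        self.gene_index = gene_index
        self.cell_index = cell_index
        self.layer_tag = layer_tag

    # -- basic introspection ------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    @property
    def gene_ids(self) -> np.ndarray:
        return self.gene_index.to_numpy()

    @property
    def cell_ids(self) -> np.ndarray:
        return self.cell_index.to_numpy()

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"ExpressionMatrix({self.n_cells} cells x {self.n_genes} genes, "
                f"layer={self.layer_tag!r}, nnz={self.values.nnz})")

    # -- conversions --------------------------------------------------------

    def to_dense(self) -> np.ndarray:
        return self.values.toarray()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.to_dense(), index=self.cell_index,
                            columns=self.gene_index)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, layer_tag: str = COUNTS
                   ) -> "ExpressionMatrix":
        """Build from a cells × genes DataFrame (index = cell ids)."""
        return cls(frame.to_numpy(), frame.columns, frame.index, layer_tag)

    def to_anndata(self):
        """Convert to :class:`anndata.AnnData` (optional dependency)."""
        import anndata  # deferred: convenience only

        return anndata.AnnData(
            X=self.values.copy(),
            obs=pd.DataFrame(index=self.cell_index.copy()),
            var=pd.DataFrame(index=self.gene_index.copy()),
        )

    # -- per-cell utilities -------------------------------------------------

    def cell(self, cell_id: str) -> pd.Series:
        """Per-gene value vector of one cell, indexed by gene id."""
        i = self.cell_index.get_loc(cell_id)
        return pd.Series(self.values[i].toarray().ravel(),
                         index=self.gene_index, name=cell_id)

    def gene_counts(self) -> np.ndarray:
        """Number of detected (value > 0) genes per cell."""
        return np.diff(self.values.indptr)

    def cell_totals(self) -> np.ndarray:
        return np.asarray(self.values.sum(axis=1)).ravel()

    def normalize_cells(self, target_total: float) -> "ExpressionMatrix":
        """Rescale every cell so its total equals ``target_total``.

        The zero pattern is unchanged; the result is a ``normalized`` layer.
        A zero-total cell cannot be rescaled and raises a ``ValueError``
        naming the cell.
        """
        if target_total <= 0:
            raise ValueError("target_total must be positive")
        totals = self.cell_totals()
        if np.any(totals == 0):
            bad = self.cell_index[int(np.argmax(totals == 0))]
            raise ValueError(f"cell {bad!r} has zero total expression")
        scale = sp.diags(target_total / totals)
        return ExpressionMatrix(scale @ self.values, self.gene_index,
                                self.cell_index, layer_tag=NORMALIZED)

    # -- subsetting / combining --------------------------------------------

    def subset_cells(self, cell_ids: Iterable[str]) -> "ExpressionMatrix":
        ids = list(cell_ids)
        idx = self.cell_index.get_indexer(ids)
        if np.any(idx < 0):
            missing = ids[int(np.argmax(idx < 0))]
            raise KeyError(f"unknown cell id {missing!r}")
        return ExpressionMatrix(self.values[idx], self.gene_index,
                                ids, layer_tag=self.layer_tag)

    def with_cell_ids(self, cell_ids: Iterable[str]) -> "ExpressionMatrix":
        """Same values with renamed cells (e.g. to tag down-sampled twins)."""
        return ExpressionMatrix(self.values, self.gene_index, cell_ids,
                                layer_tag=self.layer_tag)

    def equals(self, other: "ExpressionMatrix") -> bool:
        return (self.shape == other.shape
                and self.gene_index.equals(other.gene_index)
                and self.cell_index.equals(other.cell_index)
                and self.layer_tag == other.layer_tag
                and (self.values != other.values).nnz == 0)


def concat_cells(a: ExpressionMatrix, b: ExpressionMatrix,
                 layer_tag: str | None = None) -> ExpressionMatrix:
    """Stack two matrices over the same gene universe along the cell axis.

    When the layers disagree (e.g. counts next to rescaled counts) the result
    is tagged ``normalized``.
    """
    if not a.gene_index.equals(b.gene_index):
        raise ValueError("gene universes differ; cannot concatenate cells")
    if layer_tag is None:
        layer_tag = a.layer_tag if a.layer_tag == b.layer_tag else NORMALIZED
    return ExpressionMatrix(sp.vstack([a.values, b.values], format="csr"),
                            a.gene_index,
                            list(a.cell_ids) + list(b.cell_ids),
                            layer_tag=layer_tag)


def gene_counts(matrix: ExpressionMatrix) -> np.ndarray:
    """Per-cell number of detected genes (value > 0)."""
    return matrix.gene_counts()


def normalize_cells(matrix: ExpressionMatrix, target_total: float
                    ) -> ExpressionMatrix:
    """Rescale each cell to a common total; see the method of the same name."""
    return matrix.normalize_cells(target_total)


class CellAnnotation:
    """Mapping of cell id → group label (e.g. Tumor / Normal).

    Backed by a pandas Series indexed by cell id.  Group labels are plain
    strings; at least two distinct groups are required for any contrast,
    which is checked where the contrast is computed.
    """

    def __init__(self, groups: Mapping[str, str] | pd.Series):
        s = pd.Series(groups, dtype=object)
        s.index = s.index.astype(str)
        s.index.name = "cell_id"
        if s.index.has_duplicates:
            dup = s.index[s.index.duplicated()][0]
            raise ValueError(f"duplicate cell id in annotation: {dup!r}")
        self.groups: pd.Series = s.astype(str).rename("group")

    def __len__(self) -> int:
        return len(self.groups)

    @property
    def cell_ids(self) -> np.ndarray:
        return self.groups.index.to_numpy()

    @property
    def group_labels(self) -> list[str]:
        return sorted(self.groups.unique())

    def cells_in_group(self, label: str) -> list[str]:
        return list(self.groups.index[self.groups == label])

    def validate_against(self, matrix: ExpressionMatrix) -> None:
        """Every annotated cell must exist in the companion matrix."""
        missing = self.groups.index.difference(matrix.cell_index)
        if len(missing):
            raise ValueError(
                f"{len(missing)} annotated cell(s) not in matrix, "
                f"e.g. {missing[0]!r}")

    def subset(self, cell_ids: Iterable[str]) -> "CellAnnotation":
        return CellAnnotation(self.groups.loc[list(cell_ids)])

    def to_frame(self) -> pd.DataFrame:
        return self.groups.rename_axis("cell_id").reset_index()
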