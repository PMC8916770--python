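"""Gene sets, gene-set collections, and the GMT format.

A gene set ("gene signature") is a named list of unique gene symbols; a
collection maps unique names to sets, preserving file order.  GMT is the
tab-separated MSigDB distribution format: ``name<TAB>description<TAB>gene...``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd

from .matrix import ExpressionMatrix

log = logging.getLogger(__name__)


def _unique(genes: Iterable[str]) -> tuple[str, ...]:
    return tuple(dict.fromkeys(str(g) for g in genes))


@dataclass(frozen=True)
class GeneSet:
    """A named gene signature. Genes are deduplicated, order-preserving."""

    name: str
    genes: tuple[str, ...]
    description: str = ""

    def __post_init__(self):
        if not self.name:
            raise ValueError("gene set name must be non-empty")
        genes = _unique(self.genes)
        if not genes:
            raise ValueError(f"gene set {self.name!r} has no genes")
        object.__setattr__(self, "genes", genes)

    def __len__(self) -> int:
        return len(self.genes)

    @property
    def members(self) -> frozenset[str]:
        return frozenset(self.genes)

    def intersect(self, universe: Iterable[str]) -> tuple[str, ...]:
        """Genes also present in ``universe``, in signature order."""
        u = universe if isinstance(universe, (set, frozenset)) else set(universe)
        return tuple(g for g in self.genes if g in u)


class GeneSetCollection:
    """Ordered mapping of unique set names to :class:`GeneSet`."""

    def __init__(self, sets: Iterable[GeneSet] = ()):
        self._sets: dict[str, GeneSet] = {}
        for gs in sets:
            self.add(gs)

    def add(self, gs: GeneSet) -> None:
        if gs.name in self._sets:
            raise ValueError(f"duplicate gene set name: {gs.name!r}")
        self._sets[gs.name] = gs

    def __len__(self) -> int:
        return len(self._sets)

    def __iter__(self) -> Iterator[GeneSet]:
        return iter(self._sets.values())

    def __contains__(self, name: str) -> bool:
        return name in self._sets

    def __getitem__(self, name: str) -> GeneSet:
        return self._sets[name]

    @property
    def names(self) -> list[str]:
        return list(self._sets)

    def subset(self, names: Iterable[str]) -> "GeneSetCollection":
        return GeneSetCollection(self._sets[n] for n in names)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file into a collection.

    Each non-empty line must have at least three tab-separated fields
    (name, description, one or more genes); duplicate genes within a line
    are collapsed, and set order follows file order.  A malformed line or
    a duplicate set name raises ``ValueError`` naming the line.
    """
    path = Path(path)
    collection = GeneSetCollection()
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            genes = [g for g in fields[2:] if g]
            if len(fields) < 3 or not genes:
                raise ValueError(
                    f"{path.name}: line {lineno}: expected >=3 tab-separated "
                    "fields (name, description, genes...)")
            try:
                collection.add(GeneSet(fields[0], tuple(genes), fields[1]))
            except ValueError as exc:
                raise ValueError(f"{path.name}: line {lineno}: {exc}") from exc
    return collection


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    """Write a collection as GMT; inverse of :func:`read_gmt`."""
    with Path(path).open("w") as fh:
        for gs in collection:
            fh.write("\t".join([gs.name, gs.description, *gs.genes]) + "\n")


def effective_sizes(collection: GeneSetCollection, matrix: ExpressionMatrix
                    ) -> pd.Series:
    """Per-set size of the intersection with the matrix gene universe.

    This intersection size is the signature size used everywhere downstream
    (contingency tables, size filters, size–effect correlations).
    """
    universe = set(matrix.gene_ids)
    return pd.Series({gs.name: len(gs.intersect(universe)) for gs in collection},
                     name="effective_size", dtype=int)


def filter_min_size(collection: GeneSetCollection, matrix: ExpressionMatrix,
                    min_size: int = 20) -> GeneSetCollection:
    """Keep sets with at least ``min_size`` genes present in the matrix.

    The boundary is inclusive (an intersection of exactly ``min_size``
    survives).  An empty result is permitted but logged as a warning.
    """
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    sizes = effective_sizes(collection, matrix)
    keep = [gs for gs in collection if sizes[gs.name] >= min_size]
    if not keep:
        log.warning("filter_min_size(min_size=%d) removed all %d gene sets",
                    min_size, len(collection))
    return GeneSetCollection(keep)
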