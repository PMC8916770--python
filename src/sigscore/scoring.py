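"""Signature-scoring backends: JASMINE, SCSE, AUCell-style AUC, ssGSEA.

All four map an :class:`~sigscore.matrix.ExpressionMatrix` and a gene
signature to one score per cell, independent of other samples except where
a method's own normalization couples cells (JASMINE's min–max scaling,
ssGSEA's optional range normalization).

JASMINE (Jointly Assessing Signature Mean and Inferring Enrichment)
averages two [0,1]-scaled components per cell:

* ``V_mean`` — the mean rank of the expressed signature genes among all
  expressed genes, ``sum(R_g) / (m * N)``, where ranks are ascending over
  genes with value > 0 (highest-expressed gene has rank ``N``), ``m`` is the
  number of expressed signature genes and ``N`` the number of expressed
  genes.  Dropouts are excluded entirely, which is what makes the mean
  robust to gene-count differences between cells.
* an enrichment of the signature in the expressed-gene fraction, either an
  odds ratio ``OR = a*d / (b*c)`` (with ``b`` replaced by 1 when ``b = 0``)
  or a likelihood ratio ``LR = (a/(a+b)) / (c/(c+d))`` over the contingency
  table a/b/c/d = signature-expressed / signature-dropped-out /
  non-signature-expressed / non-signature-dropped-out.

SCSE is the signature's share of a cell's total expression; the AUCell-style
score is the area under the recovery curve of signature genes among the top
ranked genes of a cell; ssGSEA is the Barbie-style weighted running sum over
the full ranked gene list — the one backend that assigns dropouts an
informative (tie) rank, and hence the one whose scores move when only the
dropout pattern changes.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from functools import cached_property
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .genesets import GeneSet, GeneSetCollection
from .matrix import ExpressionMatrix

log = logging.getLogger(__name__)

#: recognised method tags
METHODS = ("jasmine_or", "jasmine_lr", "scse", "aucell", "ssgsea")
#: methods designed for single-cell data (used by consensus benchmarking)
SINGLE_CELL_METHODS = ("jasmine_or", "scse", "aucell")


class ContingencyCounts(NamedTuple):
    """2×2 expressed/dropout table for one cell and one signature.

    ``a`` signature genes expressed, ``b`` signature genes not expressed,
    ``c`` non-signature genes expressed, ``d`` non-signature genes not
    expressed.  ``a + b`` is the effective signature size and
    ``a + b + c + d`` the size of the gene universe.
    """

    a: int
    b: int
    c: int
    d: int


def _signature_genes(signature) -> tuple[str, ...]:
    if isinstance(signature, GeneSet):
        return signature.genes
    return tuple(dict.fromkeys(str(g) for g in signature))


# ---------------------------------------------------------------------------
# per-cell reference operations
# ---------------------------------------------------------------------------

def jasmine_mean_rank(cell_values: pd.Series, signature) -> float:
    """Mean-rank component ``V_mean`` of JASMINE for a single cell.

    Ranks are computed only over expressed genes (value > 0), ascending so
    the highest-expressed gene has rank ``N``; ties get the average rank.
    Returns 0 when no signature gene is expressed; raises on a cell with no
    expressed genes at all.
    """
    values = np.asarray(cell_values, dtype=float)
    expressed = values > 0
    n_expressed = int(expressed.sum())
    if n_expressed == 0:
        raise ValueError("cell has no expressed genes")
    members = frozenset(_signature_genes(signature))
    in_sig = np.fromiter((g in members for g in cell_values.index[expressed]),
                         dtype=bool, count=n_expressed)
    m = int(in_sig.sum())
    if m == 0:
        return 0.0
    ranks = rankdata(values[expressed])
    return float(ranks[in_sig].sum() / (m * n_expressed))


def contingency(cell_values: pd.Series, signature,
                universe: Sequence[str] | None = None) -> ContingencyCounts:
    """Expressed/dropout contingency counts for one cell and one signature.

    The signature is intersected with ``universe`` (default: the cell's own
    gene index) before counting.
    """
    if universe is None:
        universe_index = cell_values.index
        values = np.asarray(cell_values, dtype=float)
    else:
        universe_index = pd.Index(universe)
        values = np.asarray(cell_values.reindex(universe_index, fill_value=0.0),
                            dtype=float)
    if len(universe_index) == 0:
        raise ValueError("empty gene universe")
    members = frozenset(_signature_genes(signature))
    in_sig = universe_index.isin(members)
    expressed = values > 0
    a = int(np.sum(in_sig & expressed))
    b = int(np.sum(in_sig & ~expressed))
    c = int(np.sum(~in_sig & expressed))
    d = int(np.sum(~in_sig & ~expressed))
    return ContingencyCounts(a, b, c, d)


def enrichment_or(counts: ContingencyCounts) -> float:
    """Odds ratio ``a*d / (b*c)``, substituting ``b = 1`` when ``b = 0``.

    ``c = 0`` means the cell expresses no gene outside the signature — a
    degenerate cell the method refuses to score.
    """
    a, b, c, d = counts
    if c == 0:
        raise ValueError("degenerate cell: no expressed non-signature genes (c=0)")
    b_eff = 1 if b == 0 else b
    return (a * d) / (b_eff * c)


def enrichment_lr(counts: ContingencyCounts) -> float:
    """Likelihood ratio of expressed fractions, ``(a/(a+b)) / (c/(c+d))``.

    Returns 0 when no signature gene is expressed (``a = 0``).
    """
    a, b, c, d = counts
    if a + b == 0:
        raise ValueError("empty signature (a+b=0)")
    if c == 0:
        raise ValueError("degenerate cell: no expressed non-signature genes (c=0)")
    if a == 0:
        return 0.0
    return (a * (c + d)) / (c * (a + b))


def minmax_scale(values: np.ndarray) -> np.ndarray:
    """Linear scaling to [0, 1] across cells.

    A constant vector has no range to scale by and maps to all zeros, with
    a logged warning.
    """
    values = np.asarray(values, dtype=float)
    lo, hi = values.min(), values.max()
    if hi == lo:
        log.warning("min-max scaling a constant vector; returning zeros")
        return np.zeros_like(values)
    return (values - lo) / (hi - lo)


# ---------------------------------------------------------------------------
# whole-matrix workspace: per-cell caches shared across signatures
# ---------------------------------------------------------------------------

class _Workspace:
    """Dense rank/order caches for one matrix, reused across signatures.

    Built lazily; the dense footprint is cells × genes doubles per cache,
    appropriate at the matrix sizes this package targets.
    """

    def __init__(self, matrix: ExpressionMatrix):
        self.matrix = matrix
        self._aucell_cache: dict[int, np.ndarray] = {}

    @cached_property
    def dense(self) -> np.ndarray:
        return self.matrix.to_dense()

    @cached_property
    def expressed(self) -> np.ndarray:
        return self.dense > 0

    @cached_property
    def n_expressed(self) -> np.ndarray:
        return self.expressed.sum(axis=1)

    @cached_property
    def n_zero(self) -> np.ndarray:
        return self.matrix.n_genes - self.n_expressed

    @cached_property
    def ranks_all(self) -> np.ndarray:
        """Ascending average-tie ranks over all genes (zeros share a tie rank)."""
        return rankdata(self.dense, axis=1)

    @cached_property
    def walk_rank_from_bottom(self) -> np.ndarray:
        """ssGSEA walk positions counted from the list bottom.

        Genes are walked in descending rank order, ties broken by gene index
        (stable).  ``q = N - position + 1``, so the first-walked gene has
        ``q = N``; the term ``sum_i [gene at step <= i]`` of a running sum
        equals ``q`` for that gene.
        """
        n_cells, n_genes = self.dense.shape
        order = np.argsort(-self.ranks_all, axis=1, kind="stable")
        q = np.empty_like(order)
        walk_pos = np.arange(1, n_genes + 1)
        rows = np.arange(n_cells)[:, None]
        q[rows, order] = n_genes - walk_pos + 1
        return q

    def rank_weights(self, tau: float) -> np.ndarray:
        return self.ranks_all ** tau

    def aucell_order_positions(self, seed: int) -> np.ndarray:
        """1-based position of each gene in the per-cell descending ranking.

        Ties (including the zero-expression block) are broken by a random
        permutation drawn per cell, sequentially from ``default_rng(seed)``.
        """
        if seed not in self._aucell_cache:
            rng = np.random.default_rng(seed)
            n_cells, n_genes = self.dense.shape
            positions = np.empty((n_cells, n_genes), dtype=np.int64)
            for i in range(n_cells):
                perm = rng.permutation(n_genes)
                order = perm[np.argsort(-self.dense[i, perm], kind="stable")]
                positions[i, order] = np.arange(1, n_genes + 1)
            self._aucell_cache[seed] = positions
        return self._aucell_cache[seed]

    def signature_index(self, signature) -> np.ndarray:
        genes = _signature_genes(signature)
        idx = self.matrix.gene_index.get_indexer(genes)
        return idx[idx >= 0]


# ---------------------------------------------------------------------------
# vectorized scorers
# ---------------------------------------------------------------------------

def _jasmine_components(ws: _Workspace, idx: np.ndarray, variant: str
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Raw ``V_mean`` and enrichment (OR or LR) per cell, before scaling."""
    n_genes = ws.matrix.n_genes
    size = len(idx)
    if size == 0:
        raise ValueError("signature does not intersect the gene universe")
    if np.any(ws.n_expressed == 0):
        bad = ws.matrix.cell_index[int(np.argmax(ws.n_expressed == 0))]
        raise ValueError(f"cell {bad!r} has no expressed genes")
    sig_expressed = ws.expressed[:, idx]
    m = sig_expressed.sum(axis=1)
    # rank among expressed genes = rank among all genes - number of zeros
    rank_sum = ((ws.ranks_all[:, idx] - ws.n_zero[:, None])
                * sig_expressed).sum(axis=1)
    with np.errstate(invalid="ignore"):
        v_mean = np.where(m > 0, rank_sum / (np.maximum(m, 1) * ws.n_expressed),
                          0.0)
    a = m
    b = size - m
    c = ws.n_expressed - m
    d = n_genes - size - c
    if np.any(c == 0):
        bad = ws.matrix.cell_index[int(np.argmax(c == 0))]
        raise ValueError(
            f"degenerate cell {bad!r}: no expressed non-signature genes")
    if variant == "or":
        b_eff = np.where(b == 0, 1, b)
        enrich = (a * d) / (b_eff * c)
    elif variant == "lr":
        with np.errstate(invalid="ignore"):
            enrich = np.where(a > 0, (a * (c + d)) / (c * (a + b)), 0.0)
    else:
        raise ValueError(f"unknown JASMINE variant {variant!r}")
    return v_mean.astype(float), enrich.astype(float)


def jasmine_components(matrix: ExpressionMatrix, signature, variant: str = "or"
                       ) -> tuple[pd.Series, pd.Series]:
    """Unscaled per-cell ``V_mean`` and enrichment vectors (diagnostic view)."""
    ws = _Workspace(matrix)
    v_mean, enrich = _jasmine_components(ws, ws.signature_index(signature),
                                         variant)
    return (pd.Series(v_mean, index=matrix.cell_index, name="v_mean"),
            pd.Series(enrich, index=matrix.cell_index, name=f"enrich_{variant}"))


def jasmine_scores(matrix: ExpressionMatrix, signature, variant: str = "or"
                   ) -> pd.Series:
    """JASMINE score per cell: mean of min–max scaled V_mean and enrichment.

    Scaling is across cells, per signature, so at least two cells are
    required; scores always lie in [0, 1].
    """
    if matrix.n_cells < 2:
        raise ValueError("JASMINE scaling needs at least 2 cells")
    ws = _Workspace(matrix)
    v_mean, enrich = _jasmine_components(ws, ws.signature_index(signature),
                                         variant)
    scores = (minmax_scale(v_mean) + minmax_scale(enrich)) / 2.0
    return pd.Series(scores, index=matrix.cell_index, name="jasmine_" + variant)


def scse_scores(matrix: ExpressionMatrix, signature,
                scale_factor: float = 100.0) -> pd.Series:
    """SCSE: signature share of each cell's total expression, times a scale."""
    if scale_factor <= 0:
        raise ValueError("scale_factor must be positive")
    totals = matrix.cell_totals()
    if np.any(totals == 0):
        bad = matrix.cell_index[int(np.argmax(totals == 0))]
        raise ValueError(f"cell {bad!r} has zero total expression")
    ws = _Workspace(matrix)
    idx = ws.signature_index(signature)
    if len(idx) == 0:
        raise ValueError("signature does not intersect the gene universe")
    sig_sum = np.asarray(matrix.values[:, idx].sum(axis=1)).ravel()
    return pd.Series(sig_sum / totals * scale_factor,
                     index=matrix.cell_index, name="scse")


def _aucell_from_positions(positions: np.ndarray, idx: np.ndarray, k: int
                           ) -> np.ndarray:
    """AUC of the recovery curve over the top-``k`` ranks, normalized to [0,1].

    With ``c_i`` = number of signature genes among the top ``i`` ranks, the
    raw AUC is ``sum_{i<=k} c_i = sum_{g in S, pos_g <= k} (k - pos_g + 1)``;
    the maximum for a size-``s`` signature packs the set into the top ranks.
    """
    s = len(idx)
    pos = positions[:, idx]
    contrib = np.where(pos <= k, k - pos + 1, 0)
    auc = contrib.sum(axis=1).astype(float)
    if s >= k:
        max_auc = k * (k + 1) / 2.0
    else:
        max_auc = s * (s + 1) / 2.0 + s * (k - s)
    return auc / max_auc


def aucell_scores(matrix: ExpressionMatrix, signature,
                  top_fraction: float = 0.05, seed: int = 0) -> pd.Series:
    """AUCell-style score: recovery-curve AUC among the top expressed genes.

    ``k = ceil(top_fraction * n_genes)`` ranks are considered; rank ties
    (notably the zero-expression block) are broken by a seeded per-cell
    random permutation so runs are reproducible.
    """
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must lie in (0, 1]")
    k = math.ceil(top_fraction * matrix.n_genes)
    ws = _Workspace(matrix)
    idx = ws.signature_index(signature)
    if len(idx) == 0:
        raise ValueError("signature does not intersect the gene universe")
    positions = ws.aucell_order_positions(seed)
    return pd.Series(_aucell_from_positions(positions, idx, k),
                     index=matrix.cell_index, name="aucell")


def _ssgsea_raw(ws: _Workspace, idx: np.ndarray, tau: float) -> np.ndarray:
    """Raw ssGSEA running-sum statistic per cell, in closed form.

    The running sum ``sum_i (P_in(i) - P_out(i))`` telescopes: each gene
    contributes its weight times the number of steps at or after its walk
    position, i.e. ``q = N - pos + 1``.  Hence

    ``score = sum_{g in S} w_g q_g / sum_{g in S} w_g
              - sum_{g not in S} q_g / (N - |S|)``

    with ``w_g = rank_g ** tau``.  Identical to walking the list, but O(|S|)
    per cell once the rank/order caches exist.
    """
    n_genes = ws.matrix.n_genes
    size = len(idx)
    if size == 0:
        raise ValueError("signature does not intersect the gene universe")
    if size >= n_genes:
        raise ValueError("signature must be a strict subset of the universe")
    weights = ws.rank_weights(tau)[:, idx]
    q = ws.walk_rank_from_bottom[:, idx]
    w_total = weights.sum(axis=1)
    p_in_sum = (weights * q).sum(axis=1) / w_total
    total_q = n_genes * (n_genes + 1) / 2.0
    p_out_sum = (total_q - q.sum(axis=1)) / (n_genes - size)
    return p_in_sum - p_out_sum


def ssgsea_scores(matrix: ExpressionMatrix, signature, tau: float = 0.25,
                  normalize: bool = True) -> pd.Series:
    """ssGSEA score per cell.

    Genes are ranked over the whole universe (ties, including all dropouts,
    get the average rank), walked from high to low; the score is the summed
    difference between the weighted in-signature and uniform out-of-signature
    cumulative distributions.  With ``normalize`` the scores are divided by
    the (max − min) range over the score matrix, which for a single signature
    is the per-cell score vector.
    """
    if tau < 0:
        raise ValueError("tau must be non-negative")
    ws = _Workspace(matrix)
    raw = _ssgsea_raw(ws, ws.signature_index(signature), tau)
    if normalize:
        raw = _range_normalize(raw)
    return pd.Series(raw, index=matrix.cell_index, name="ssgsea")


def _range_normalize(scores: np.ndarray) -> np.ndarray:
    span = float(scores.max() - scores.min())
    if span == 0:
        log.warning("ssGSEA normalization: zero score range, leaving raw scores")
        return scores
    return scores / span


# ---------------------------------------------------------------------------
# collection-level scoring
# ---------------------------------------------------------------------------

@dataclass
class ScoreMatrix:
    """Signatures × cells score table plus the settings that produced it."""

    scores: pd.DataFrame
    method: str
    parameters: dict = field(default_factory=dict)

    @property
    def signature_names(self) -> list[str]:
        return list(self.scores.index)

    @property
    def cell_ids(self) -> list[str]:
        return list(self.scores.columns)

    def to_tsv(self, path: str | Path) -> None:
        """Write the score table, with a JSON run-parameter sidecar."""
        path = Path(path)
        self.scores.rename_axis("signature").to_csv(path, sep="\t")
        sidecar = path.with_suffix(path.suffix + ".params.json")
        sidecar.write_text(json.dumps(
            {"method": self.method, "parameters": self.parameters}, indent=2))


def score_collection(matrix: ExpressionMatrix, collection: GeneSetCollection,
                     method: str, *, tau: float = 0.25,
                     top_fraction: float = 0.05, scale_factor: float = 100.0,
                     normalize: bool = True, seed: int = 0) -> ScoreMatrix:
    """Score every signature in a collection with one backend.

    Per-matrix caches (rank matrices, walk orders, AUCell orderings) are
    built once and shared across signatures, so scoring many signatures
    costs little more than scoring one.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    if len(collection) == 0:
        raise ValueError("empty gene set collection")
    ws = _Workspace(matrix)
    rows: list[np.ndarray] = []
    params: dict = {"seed": seed}
    if method in ("jasmine_or", "jasmine_lr"):
        if matrix.n_cells < 2:
            raise ValueError("JASMINE scaling needs at least 2 cells")
        variant = method.split("_")[1]
        params["variant"] = variant
        for gs in collection:
            v_mean, enrich = _jasmine_components(ws, ws.signature_index(gs),
                                                 variant)
            rows.append((minmax_scale(v_mean) + minmax_scale(enrich)) / 2.0)
    elif method == "scse":
        params["scale_factor"] = scale_factor
        totals = matrix.cell_totals()
        if np.any(totals == 0):
            bad = matrix.cell_index[int(np.argmax(totals == 0))]
            raise ValueError(f"cell {bad!r} has zero total expression")
        for gs in collection:
            idx = ws.signature_index(gs)
            if len(idx) == 0:
                raise ValueError(
                    f"signature {gs.name!r} does not intersect the universe")
            sig_sum = np.asarray(matrix.values[:, idx].sum(axis=1)).ravel()
            rows.append(sig_sum / totals * scale_factor)
    elif method == "aucell":
        params["top_fraction"] = top_fraction
        k = math.ceil(top_fraction * matrix.n_genes)
        positions = ws.aucell_order_positions(seed)
        for gs in collection:
            idx = ws.signature_index(gs)
            if len(idx) == 0:
                raise ValueError(
                    f"signature {gs.name!r} does not intersect the universe")
            rows.append(_aucell_from_positions(positions, idx, k))
    elif method == "ssgsea":
        params.update(tau=tau, normalize=normalize)
        for gs in collection:
            rows.append(_ssgsea_raw(ws, ws.signature_index(gs), tau))
    table = pd.DataFrame(np.vstack(rows), index=pd.Index(collection.names,
                                                         name="signature"),
                         columns=matrix.cell_index)
    if method == "ssgsea" and normalize:
        span = float(table.to_numpy().max() - table.to_numpy().min())
        if span == 0:
            log.warning("ssGSEA normalization: zero score range over matrix")
        else:
            table = table / span
    return ScoreMatrix(table, method, params)
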