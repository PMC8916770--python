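"""Dummy-cell dropout probe.

A single synthetic cell with strictly decreasing expression over its genes
(gene i has value ``n - i + 1``, so the gene index *is* the expression rank)
is compared against a copy of itself whose lowest-expressed genes are zeroed.
A 100-gene signature — 99 fixed genes drawn from the top ranks plus one
"floating" gene swept down the list — is scored on both cells.  Backends
that only use expressed genes give identical curves while the floating gene
is expressed in both cells; ssGSEA, which assigns all dropouts a shared
average (tie) rank, diverges the moment the floating gene enters the
dropout zone and changes sign at the dropout tie rank.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

log = logging.getLogger(__name__)

#: backends with a raw (single-cell, no cross-cell normalization) score
SWEEP_SCORERS = ("ssgsea", "scse", "aucell", "jasmine_vmean")


def make_dummy_cell(n_genes: int = 10_000) -> pd.Series:
    """Strictly decreasing dummy expression profile.

    Gene ``i`` (1-based) has value ``n_genes - i + 1``; ranking descending
    returns the genes in index order at every dropout rate, by construction.
    """
    if n_genes < 3:
        raise ValueError("need at least 3 genes")
    values = np.arange(n_genes, 0, -1, dtype=float)
    index = pd.Index([f"g{i:05d}" for i in range(1, n_genes + 1)],
                     name="gene_id")
    return pd.Series(values, index=index, name="dummy_cell")


def apply_dropout(cell: pd.Series, rate: float) -> pd.Series:
    """Zero the ``floor(rate * n)`` lowest-expressed genes of a cell.

    Ties among equal low values are resolved by storage order (stable sort).
    """
    if not 0 <= rate < 1:
        raise ValueError("dropout rate must lie in [0, 1)")
    values = np.asarray(cell, dtype=float).copy()
    n_drop = math.floor(rate * len(values))
    if n_drop:
        lowest = np.argsort(values, kind="stable")[:n_drop]
        values[lowest] = 0.0
    return pd.Series(values, index=cell.index, name=cell.name)


def tie_rank_of_dropouts(cell_after_dropout: pd.Series) -> float:
    """Shared average rank (high→low) of the zero-expression genes."""
    values = np.asarray(cell_after_dropout, dtype=float)
    zero = values == 0
    if not zero.any():
        raise ValueError("cell has no dropouts")
    ranks_desc = rankdata(-values)  # descending, ties at average position
    return float(ranks_desc[zero][0])


# ---------------------------------------------------------------------------
# raw per-cell scorers for the sweep
# ---------------------------------------------------------------------------

class _SsgseaCell:
    """Closed-form raw ssGSEA for one cell with an exchangeable float gene.

    The running sum telescopes into per-gene contributions (see
    ``sigscore.scoring._ssgsea_raw``); with 99 fixed genes the sweep over
    floating positions is O(1) per position.
    """

    def __init__(self, values: np.ndarray, tau: float):
        n = len(values)
        self.n = n
        self.ranks = rankdata(values)  # ascending, average ties
        order = np.argsort(-self.ranks, kind="stable")
        q = np.empty(n, dtype=float)
        q[order] = n - np.arange(1, n + 1) + 1
        self.q = q
        self.w = self.ranks ** tau
        self.total_q = n * (n + 1) / 2.0

    def sweep(self, fixed_idx: np.ndarray, float_idx: np.ndarray) -> np.ndarray:
        w_fixed = self.w[fixed_idx].sum()
        wq_fixed = (self.w[fixed_idx] * self.q[fixed_idx]).sum()
        q_fixed = self.q[fixed_idx].sum()
        size = len(fixed_idx) + 1
        w_f = self.w[float_idx]
        q_f = self.q[float_idx]
        p_in = (wq_fixed + w_f * q_f) / (w_fixed + w_f)
        p_out = (self.total_q - q_fixed - q_f) / (self.n - size)
        return p_in - p_out


def _scse_sweep(values: np.ndarray, fixed_idx, float_idx,
                scale_factor: float) -> np.ndarray:
    total = values.sum()
    if total <= 0:
        raise ValueError("cell has zero total expression")
    return (values[fixed_idx].sum() + values[float_idx]) / total * scale_factor


def _aucell_sweep(values: np.ndarray, fixed_idx, float_idx,
                  top_fraction: float, rng: np.random.Generator) -> np.ndarray:
    n = len(values)
    k = math.ceil(top_fraction * n)
    perm = rng.permutation(n)
    order = perm[np.argsort(-values[perm], kind="stable")]
    positions = np.empty(n, dtype=np.int64)
    positions[order] = np.arange(1, n + 1)
    fixed_contrib = np.where(positions[fixed_idx] <= k,
                             k - positions[fixed_idx] + 1, 0).sum()
    s = len(fixed_idx) + 1
    if s >= k:
        max_auc = k * (k + 1) / 2.0
    else:
        max_auc = s * (s + 1) / 2.0 + s * (k - s)
    float_pos = positions[float_idx]
    float_contrib = np.where(float_pos <= k, k - float_pos + 1, 0)
    return (fixed_contrib + float_contrib) / max_auc


def _vmean_sweep(values: np.ndarray, fixed_idx, float_idx) -> np.ndarray:
    expressed = values > 0
    n_expressed = int(expressed.sum())
    if n_expressed == 0:
        raise ValueError("cell has no expressed genes")
    ranks = np.zeros(len(values))
    ranks[expressed] = rankdata(values[expressed])
    fixed_m = int(expressed[fixed_idx].sum())
    fixed_sum = ranks[fixed_idx].sum()
    float_in = expressed[float_idx].astype(int)
    m = fixed_m + float_in
    rank_sum = fixed_sum + ranks[float_idx]
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(m > 0, rank_sum / (np.maximum(m, 1) * n_expressed), 0.0)
    return out


# ---------------------------------------------------------------------------
# the sweep itself
# ---------------------------------------------------------------------------

@dataclass
class DropoutCurve:
    """Paired score curves of the floating-gene sweep and their summary."""

    floating_positions: np.ndarray
    score_reference: np.ndarray
    score_dropout: np.ndarray
    dropout_rate: float
    n_genes: int
    n_fixed: int
    top_pool: int
    scorer: str
    tie_rank: float | None = None
    fixed_ranks: np.ndarray = field(default_factory=lambda: np.empty(0, int))

    def __post_init__(self):
        if len(self.floating_positions) != len(self.score_reference) or \
                len(self.score_reference) != len(self.score_dropout):
            raise ValueError("curve vectors must have equal length")
        if np.any(np.diff(self.floating_positions) <= 0):
            raise ValueError("floating positions must be strictly increasing")

    def _equal_mask(self) -> np.ndarray:
        return np.isclose(self.score_reference, self.score_dropout,
                          rtol=1e-12, atol=1e-9)

    @property
    def divergence_rank(self) -> int | None:
        """Largest swept position at which the two scores are equal."""
        eq = self._equal_mask()
        if not eq.any():
            return None
        return int(self.floating_positions[eq][-1])

    @property
    def crossing_rank(self) -> int | None:
        """Largest swept position where the dropout score >= reference."""
        ge = (self.score_dropout > self.score_reference) | self._equal_mask()
        if not ge.any():
            return None
        return int(self.floating_positions[ge][-1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"position": self.floating_positions,
                             "score_reference": self.score_reference,
                             "score_dropout": self.score_dropout})

    def summary(self) -> dict:
        return {"scorer": self.scorer, "dropout_rate": self.dropout_rate,
                "n_genes": self.n_genes, "n_fixed": self.n_fixed,
                "top_pool": self.top_pool,
                "divergence_rank": self.divergence_rank,
                "crossing_rank": self.crossing_rank,
                "tie_rank": self.tie_rank}

    def write(self, curve_path: str | Path, summary_path: str | Path) -> None:
        import json

        self.to_frame().to_csv(curve_path, sep="\t", index=False)
        Path(summary_path).write_text(json.dumps(self.summary(), indent=2))


def floating_gene_sweep(cell: pd.Series | None = None, rate: float = 0.6,
                        n_fixed: int = 99, top_pool: int = 1000,
                        scorer: str = "ssgsea", seed: int = 0,
                        positions: Sequence[int] | None = None,
                        tau: float = 0.25, top_fraction: float = 0.05,
                        scale_factor: float = 100.0) -> DropoutCurve:
    """Score a 99+1-gene signature on a cell and its dropout twin.

    ``n_fixed`` signature genes are drawn (seeded) from the ``top_pool``
    highest-expressed genes; the remaining gene floats over reference ranks
    ``top_pool + 1 ... n_genes`` (or the supplied subset of ``positions``).
    Both cells are scored with the chosen backend in its raw, single-cell
    form — no cross-cell normalization — so the curves react only to the
    dropout pattern.  Backends that cannot produce a raw per-cell score
    (JASMINE's full score needs cross-cell min–max scaling) are refused;
    its rank-mean component is available as ``jasmine_vmean``.
    """
    if cell is None:
        cell = make_dummy_cell()
    if scorer not in SWEEP_SCORERS:
        if scorer in ("jasmine_or", "jasmine_lr"):
            raise ValueError(
                f"{scorer!r} has no raw single-cell score (its min-max "
                "scaling couples cells); use 'jasmine_vmean' for the sweep")
        raise ValueError(f"unknown sweep scorer {scorer!r}; "
                         f"expected one of {SWEEP_SCORERS}")
    n = len(cell)
    if not top_pool < n:
        raise ValueError("top_pool must be smaller than the number of genes")
    if not n_fixed < top_pool:
        raise ValueError("n_fixed must be smaller than top_pool")
    ref_values = np.asarray(cell, dtype=float)
    drop_series = apply_dropout(cell, rate)
    drop_values = np.asarray(drop_series, dtype=float)

    # reference ranking (high -> low), ties broken by storage order
    ref_order = np.argsort(-ref_values, kind="stable")
    rng = np.random.default_rng(seed)
    fixed_ranks = np.sort(rng.choice(np.arange(1, top_pool + 1), n_fixed,
                                     replace=False))
    fixed_idx = ref_order[fixed_ranks - 1]

    if positions is None:
        positions = np.arange(top_pool + 1, n + 1)
    positions = np.asarray(positions, dtype=np.int64)
    if np.any((positions <= top_pool) | (positions > n)):
        raise ValueError("floating positions must lie in (top_pool, n_genes]")
    float_idx = ref_order[positions - 1]

    if scorer == "ssgsea":
        ref = _SsgseaCell(ref_values, tau).sweep(fixed_idx, float_idx)
        drop = _SsgseaCell(drop_values, tau).sweep(fixed_idx, float_idx)
    elif scorer == "scse":
        ref = _scse_sweep(ref_values, fixed_idx, float_idx, scale_factor)
        drop = _scse_sweep(drop_values, fixed_idx, float_idx, scale_factor)
    elif scorer == "aucell":
        tie_rng = np.random.default_rng(seed)
        ref = _aucell_sweep(ref_values, fixed_idx, float_idx, top_fraction,
                            tie_rng)
        drop = _aucell_sweep(drop_values, fixed_idx, float_idx, top_fraction,
                             tie_rng)
    else:  # jasmine_vmean
        ref = _vmean_sweep(ref_values, fixed_idx, float_idx)
        drop = _vmean_sweep(drop_values, fixed_idx, float_idx)

    tie = tie_rank_of_dropouts(drop_series) if rate > 0 else None
    return DropoutCurve(positions, np.asarray(ref, float),
                        np.asarray(drop, float), rate, n, n_fixed, top_pool,
                        scorer, tie_rank=tie, fixed_ranks=fixed_ranks)
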