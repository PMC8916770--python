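"""Benchmark experiment generators: noisy gold-standard gene sets and
binomial down-sampling of count matrices.

The gold-standard design: gene sets of known direction are drawn from true
up-/down-regulated gene pools; a noise fraction of each set is replaced by
genes drawn from the rest of the universe, attenuating the signal.  The
specificity design: a group of cells is contrasted against its own
down-sampled (thinned and depth-rescaled) twin, so any non-neutral call is
false by construction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.sparse as sp

from .contrast import ContrastOutcome, contrast_collection
from .genesets import GeneSet, GeneSetCollection, effective_sizes
from .matrix import (COUNTS, NORMALIZED, CellAnnotation, ExpressionMatrix,
                     concat_cells)
from .scoring import score_collection

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SimulatedGeneSet:
    """A gold-standard signature with known direction and noise content."""

    genes: tuple[str, ...]
    direction: str
    size: int
    noise_level: float
    replicate_id: int
    n_true: int

    def __post_init__(self):
        if len(self.genes) != self.size:
            raise ValueError("|genes| must equal size")
        if len(set(self.genes)) != self.size:
            raise ValueError("simulated set contains duplicate genes")

    @property
    def name(self) -> str:
        return (f"{self.direction}_s{self.size}"
                f"_q{int(round(self.noise_level * 100))}_r{self.replicate_id}")

    def to_gene_set(self) -> GeneSet:
        description = (f"{self.direction}|{self.size}|{self.noise_level}"
                       f"|{self.replicate_id}")
        return GeneSet(self.name, self.genes, description)


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def simulate_noisy_sets(up_pool: Sequence[str], down_pool: Sequence[str],
                        universe: Sequence[str], sizes: Sequence[int],
                        noise_levels: Sequence[float], n_per_combo: int = 200,
                        seed: int = 0) -> list[SimulatedGeneSet]:
    """Generate gold-standard gene sets with controlled noise.

    For each direction × size × noise level, ``n_per_combo`` sets are drawn:
    ``size - round(noise * size)`` genes without replacement from the
    direction's true-DE pool, the rest from the universe minus that pool.
    One seeded generator drives everything in direction-major, then size,
    noise, replicate order, so output is deterministic for fixed inputs.
    An empty pool skips its direction.
    """
    up_pool = list(dict.fromkeys(up_pool))
    down_pool = list(dict.fromkeys(down_pool))
    if set(up_pool) & set(down_pool):
        raise ValueError("up and down pools must be disjoint")
    universe_set = set(universe)
    for pool, tag in ((up_pool, "up"), (down_pool, "down")):
        if not set(pool) <= universe_set:
            raise ValueError(f"{tag} pool contains genes outside the universe")
    for q in noise_levels:
        if not 0 <= q < 1:
            raise ValueError(f"noise level {q} outside [0, 1)")
    rng = np.random.default_rng(seed)
    out: list[SimulatedGeneSet] = []
    for direction, pool in (("up", up_pool), ("down", down_pool)):
        if not pool:
            continue
        pool_arr = np.asarray(pool, dtype=object)
        complement = np.asarray(sorted(universe_set - set(pool)), dtype=object)
        for size in sizes:
            for q in noise_levels:
                n_noise = _round_half_away(q * size)
                n_true = size - n_noise
                if n_true > len(pool_arr):
                    raise ValueError(
                        f"{direction} pool too small for size={size}, "
                        f"noise={q}: need {n_true} true genes, have "
                        f"{len(pool_arr)}")
                if n_noise > len(complement):
                    raise ValueError(
                        f"universe too small for size={size}, noise={q}: "
                        f"need {n_noise} noise genes, have {len(complement)}")
                for rep in range(n_per_combo):
                    true_genes = rng.choice(pool_arr, n_true, replace=False)
                    noise_genes = rng.choice(complement, n_noise, replace=False)
                    genes = tuple(true_genes) + tuple(noise_genes)
                    out.append(SimulatedGeneSet(genes, direction, int(size),
                                                float(q), rep, int(n_true)))
    return out


def sets_to_collection(sets: Sequence[SimulatedGeneSet]) -> GeneSetCollection:
    """Package simulated sets as a collection (metadata in the description)."""
    return GeneSetCollection(s.to_gene_set() for s in sets)


def random_gene_sets(universe: Sequence[str], n_sets: int, size: int,
                     seed: int = 0, exclude: Sequence[str] = (),
                     prefix: str = "neutral") -> GeneSetCollection:
    """Random signatures with no built-in direction (a neutral collection).

    Genes are drawn uniformly without replacement from the universe minus
    ``exclude`` (typically the true DE pools).
    """
    candidates = np.asarray(sorted(set(universe) - set(exclude)), dtype=object)
    if size > len(candidates):
        raise ValueError("requested set size exceeds the candidate universe")
    rng = np.random.default_rng(seed)
    sets = [GeneSet(f"{prefix}_{i}", tuple(rng.choice(candidates, size,
                                                      replace=False)))
            for i in range(n_sets)]
    return GeneSetCollection(sets)


def downsample_matrix(matrix: ExpressionMatrix, rate: float, seed: int = 0,
                      rescale: bool = True) -> ExpressionMatrix:
    """Binomially thin a counts matrix to a fraction of its coverage.

    Every count ``k`` is replaced by a Binomial(k, rate) draw — the standard
    read-thinning model — so thinning only removes reads and zero counts
    stay zero.  With ``rescale`` each cell is scaled back to its own
    original total ("equal total coverage"), giving a normalized layer;
    ``rate = 1`` returns the input unchanged.
    """
    if matrix.layer_tag != COUNTS:
        raise ValueError("down-sampling requires a counts layer")
    if not 0 < rate <= 1:
        raise ValueError("rate must lie in (0, 1]")
    if rate == 1:
        return ExpressionMatrix(matrix.values, matrix.gene_index,
                                matrix.cell_index, layer_tag=COUNTS)
    rng = np.random.default_rng(seed)
    original_totals = matrix.cell_totals()
    thinned = matrix.values.copy()
    thinned.data = rng.binomial(thinned.data.astype(np.int64), rate
                                ).astype(np.float64)
    thinned.eliminate_zeros()
    if not rescale:
        return ExpressionMatrix(thinned, matrix.gene_index, matrix.cell_index,
                                layer_tag=COUNTS)
    new_totals = np.asarray(thinned.sum(axis=1)).ravel()
    empty = (new_totals == 0) & (original_totals > 0)
    if np.any(empty):
        log.warning("%d cell(s) lost all counts during down-sampling and "
                    "cannot be rescaled", int(empty.sum()))
    scale = np.divide(original_totals, new_totals,
                      out=np.ones_like(original_totals, dtype=float),
                      where=new_totals > 0)
    rescaled = sp.diags(scale) @ thinned
    return ExpressionMatrix(rescaled, matrix.gene_index, matrix.cell_index,
                            layer_tag=NORMALIZED)


def _null_run(matrix: ExpressionMatrix, annotation: CellAnnotation,
              collection: GeneSetCollection, method: str, n_cells: int = 100,
              rate: float = 0.5, seed: int = 0, tumor_label: str = "Tumor",
              threshold: float = 1.0, **score_kwargs):
    """Down-sampling null with full intermediates (scores, groups)."""
    annotation.validate_against(matrix)
    tumor_cells = sorted(annotation.cells_in_group(tumor_label))
    if len(tumor_cells) < n_cells:
        raise ValueError(
            f"need {n_cells} {tumor_label!r} cells, have {len(tumor_cells)}")
    rng = np.random.default_rng(seed)
    chosen = list(rng.choice(np.asarray(tumor_cells, dtype=object), n_cells,
                             replace=False))
    original = matrix.subset_cells(chosen)
    thin_seed = int(rng.integers(2 ** 31))
    twin = downsample_matrix(original, rate, seed=thin_seed, rescale=True)
    original = original.with_cell_ids([f"orig:{c}" for c in chosen])
    twin = twin.with_cell_ids([f"ds:{c}" for c in chosen])
    combined = concat_cells(original, twin)
    groups = CellAnnotation({**{c: "original" for c in original.cell_ids},
                             **{c: "downsampled" for c in twin.cell_ids}})
    scores = score_collection(combined, collection, method,
                              seed=int(rng.integers(2 ** 31)), **score_kwargs)
    sizes = effective_sizes(collection, combined)
    outcome = contrast_collection(scores, groups, "original", "downsampled",
                                  threshold=threshold, sizes=sizes)
    return outcome, scores, groups


def null_specificity_experiment(matrix: ExpressionMatrix,
                                annotation: CellAnnotation,
                                collection: GeneSetCollection, method: str,
                                n_cells: int = 100, rate: float = 0.5,
                                seed: int = 0, tumor_label: str = "Tumor",
                                threshold: float = 1.0,
                                **score_kwargs) -> ContrastOutcome:
    """Specificity null: original cells versus their down-sampled twins.

    Samples ``n_cells`` tumor cells (seeded), builds a thinned and rescaled
    twin group, scores both with one backend on the combined matrix, and
    contrasts original vs down-sampled with Cohen's d.  Every non-neutral
    call in the result is a false call.
    """
    outcome, _, _ = _null_run(matrix, annotation, collection, method,
                              n_cells=n_cells, rate=rate, seed=seed,
                              tumor_label=tumor_label, threshold=threshold,
                              **score_kwargs)
    return outcome
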