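"""Benchmark orchestration: sensitivity (recovery of gold-standard sets),
specificity (down-sampling nulls), stability (CV), and consensus accuracy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .contrast import (CALL_DOWN, CALL_UP, consensus_accuracy,
                       contrast_collection, score_cv)
from .genesets import GeneSetCollection, effective_sizes
from .matrix import CellAnnotation, ExpressionMatrix
from .scoring import METHODS, score_collection
from .simulate import (SimulatedGeneSet, _null_run, sets_to_collection,
                       simulate_noisy_sets)

log = logging.getLogger(__name__)


@dataclass
class RecoveryBenchmark:
    """Outputs of the gold-standard recovery experiment."""

    calls: pd.DataFrame       # one row per simulated set x method
    recovery: pd.DataFrame    # method x direction x noise (mean over sizes)
    recovery_detail: pd.DataFrame  # method x direction x size x noise
    consensus: pd.DataFrame | None
    failed_methods: dict[str, str] = field(default_factory=dict)


def run_recovery_benchmark(matrix: ExpressionMatrix,
                           annotation: CellAnnotation,
                           up_pool: Sequence[str], down_pool: Sequence[str],
                           methods: Sequence[str] = METHODS,
                           sizes: Sequence[int] = (50, 100, 150, 200, 300),
                           noise_levels: Sequence[float] = (0, .2, .4, .6, .8),
                           n_per_combo: int = 200, threshold: float = 1.0,
                           seed: int = 0, group1: str = "Tumor",
                           group2: str = "Normal") -> RecoveryBenchmark:
    """Score noisy gold-standard sets with each method and measure recovery.

    A method that fails outright is recorded in ``failed_methods`` and the
    run continues with the rest.
    """
    annotation.validate_against(matrix)
    sim_sets = simulate_noisy_sets(up_pool, down_pool, list(matrix.gene_ids),
                                   sizes, noise_levels, n_per_combo, seed)
    collection = sets_to_collection(sim_sets)
    sizes_map = effective_sizes(collection, matrix)
    meta = pd.DataFrame(
        [(s.name, s.direction, s.size, s.noise_level, s.replicate_id)
         for s in sim_sets],
        columns=["signature", "truth", "size", "noise", "replicate"]
    ).set_index("signature")

    failed: dict[str, str] = {}
    call_cols = {}
    d_cols = {}
    for method in methods:
        try:
            scores = score_collection(matrix, collection, method, seed=seed)
            outcome = contrast_collection(scores, annotation, group1, group2,
                                          threshold=threshold, sizes=sizes_map)
        except Exception as exc:  # noqa: BLE001 - record and continue
            log.warning("method %s failed: %s", method, exc)
            failed[method] = str(exc)
            continue
        call_cols[method] = pd.Series(
            {r.signature: r.call for r in outcome.results})
        d_cols[method] = pd.Series(
            {r.signature: r.cohens_d for r in outcome.results})

    calls = meta.copy()
    for method in call_cols:
        calls[f"call_{method}"] = call_cols[method]
        calls[f"d_{method}"] = d_cols[method]

    rows = []
    detail_rows = []
    for method in call_cols:
        col = calls[f"call_{method}"]
        for direction in (CALL_UP, CALL_DOWN):
            sub = calls[calls["truth"] == direction]
            if sub.empty:
                continue
            for noise, grp in sub.groupby("noise"):
                rows.append((method, direction, noise, len(grp),
                             (col.loc[grp.index] == direction).mean()))
            for (size, noise), grp in sub.groupby(["size", "noise"]):
                detail_rows.append((method, direction, size, noise, len(grp),
                                    (col.loc[grp.index] == direction).mean()))
    recovery = pd.DataFrame(rows, columns=["method", "direction", "noise",
                                           "n_sets", "recovery"])
    detail = pd.DataFrame(detail_rows,
                          columns=["method", "direction", "size", "noise",
                                   "n_sets", "recovery"])

    consensus = None
    if len(call_cols) >= 3:
        by_method = {m: list(calls[f"call_{m}"]) for m in call_cols}
        consensus = consensus_accuracy(by_method).per_method.reset_index()
    return RecoveryBenchmark(calls.reset_index(), recovery, detail, consensus,
                             failed)


def run_null_benchmark(matrix: ExpressionMatrix, annotation: CellAnnotation,
                       collection: GeneSetCollection,
                       methods: Sequence[str] = METHODS, n_cells: int = 100,
                       rate: float = 0.5, threshold: float = 1.0,
                       seed: int = 0, tumor_label: str = "Tumor"
                       ) -> pd.DataFrame:
    """Down-sampling specificity null per method.

    Every method sees the identical seed-fixed cell subset and thinning, so
    false-call rates are comparable across methods.  Returns one row per
    method with false-up/false-down rates and the mean per-signature CV in
    the original and down-sampled groups.
    """
    rows = []
    for method in methods:
        try:
            outcome, scores, groups = _null_run(
                matrix, annotation, collection, method, n_cells=n_cells,
                rate=rate, seed=seed, tumor_label=tumor_label,
                threshold=threshold)
        except Exception as exc:  # noqa: BLE001
            log.warning("null benchmark: method %s failed: %s", method, exc)
            rows.append((method, np.nan, np.nan, np.nan, np.nan, str(exc)))
            continue
        n = len(outcome.results)
        false_up = sum(r.call == CALL_UP for r in outcome.results) / n
        false_down = sum(r.call == CALL_DOWN for r in outcome.results) / n
        orig_cells = groups.cells_in_group("original")
        ds_cells = groups.cells_in_group("downsampled")
        cv_orig = np.nanmean([score_cv(scores.scores.loc[s, orig_cells])
                              for s in scores.scores.index])
        cv_ds = np.nanmean([score_cv(scores.scores.loc[s, ds_cells])
                            for s in scores.scores.index])
        rows.append((method, false_up, false_down, cv_orig, cv_ds, ""))
    return pd.DataFrame(rows, columns=["method", "false_up", "false_down",
                                       "mean_cv_original",
                                       "mean_cv_downsampled", "error"])


def call_ratio(outcome_results, correction: float = 1.0) -> float:
    """Up:down call ratio with a continuity correction on both counts.

    ``(n_up + c) / (n_down + c)`` stays finite when a method makes no down
    calls, while preserving the ordering of interest (gene-count-biased
    methods call far more ups than downs on neutral signatures).
    """
    n_up = sum(r.call == CALL_UP for r in outcome_results)
    n_down = sum(r.call == CALL_DOWN for r in outcome_results)
    return (n_up + correction) / (n_down + correction)
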