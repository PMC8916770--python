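"""Synthetic tumor/normal cohort generator.

Emulates the statistical structure that makes gene-count bias visible in
real cancer scRNA-seq cohorts: negative-binomial counts with log-normally
heterogeneous gene means (so ranks are informative), known true up- and
down-regulated gene programs in tumor cells, and a controlled detected-gene
imbalance — tumor cells systematically detect more genes than normal cells.

The imbalance is produced by per-cell binomial thinning of the normal
cells.  For a negative-binomial gene with mean ``mu`` and dispersion
``phi`` (variance ``mu + phi mu^2``), thinning by ``r`` keeps it negative
binomial with mean ``r mu``, so the expected detected-gene count at
thinning ``r`` is ``sum_g 1 - (1 + r mu_g phi)^(-1/phi)``.  The thinning
rate is solved numerically so that the expected tumor:normal detected-gene
ratio equals ``detect_shift``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from .matrix import CellAnnotation, ExpressionMatrix

log = logging.getLogger(__name__)


@dataclass
class CohortConfig:
    """Generator settings; defaults are the package's desk-scale cohort."""

    n_tumor: int = 200
    n_normal: int = 200
    n_genes: int = 2000
    #: log-normal parameters of the per-gene mean expression
    mean_log_mu: float = 0.0
    mean_log_sigma: float = 1.0
    #: optional explicit per-gene means; overrides the log-normal draw
    gene_means: np.ndarray | None = None
    #: negative-binomial dispersion (variance = mu + dispersion * mu^2)
    dispersion: float = 0.3
    #: expected tumor:normal detected-gene ratio (>= 1)
    detect_shift: float = 1.75
    n_up: int = 150
    n_down: int = 150
    #: fold change of true DE genes in tumor cells
    effect_size: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_tumor, self.n_normal) < 1 or self.n_genes < 1:
            raise ValueError("cohort dimensions must be positive")
        if self.n_up + self.n_down > self.n_genes:
            raise ValueError("n_up + n_down exceeds n_genes")
        if self.detect_shift < 1:
            raise ValueError("detect_shift must be >= 1")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if self.effect_size <= 0:
            raise ValueError("effect_size must be positive")
        if self.gene_means is not None:
            means = np.asarray(self.gene_means, dtype=float)
            if means.shape != (self.n_genes,) or np.any(means <= 0):
                raise ValueError("gene_means must be n_genes positive reals")


@dataclass
class CohortTruth:
    """Ground-truth DE gene programs and cell labels of a synthetic cohort."""

    up_genes: tuple[str, ...]
    down_genes: tuple[str, ...]
    annotation: CellAnnotation

    def __post_init__(self):
        if set(self.up_genes) & set(self.down_genes):
            raise ValueError("up and down truth pools must be disjoint")


def _expected_detected(means: np.ndarray, dispersion: float,
                       thinning: float) -> float:
    """Expected detected-gene count of an NB cell thinned by ``thinning``."""
    inv = 1.0 / dispersion
    return float(np.sum(1.0 - (1.0 + thinning * means * dispersion) ** (-inv)))


def _solve_normal_thinning(tumor_means: np.ndarray, normal_means: np.ndarray,
                           dispersion: float, detect_shift: float) -> float:
    """Thinning rate for normal cells hitting the detected-gene ratio."""
    target = _expected_detected(tumor_means, dispersion, 1.0) / detect_shift
    if target > normal_means.size:
        raise ValueError("expected detection target exceeds the gene count")
    full = _expected_detected(normal_means, dispersion, 1.0)
    if target >= full:
        return 1.0
    lo = 1e-9
    if _expected_detected(normal_means, dispersion, lo) > target:
        raise ValueError("detect_shift is infeasible for these gene means")
    return float(brentq(
        lambda r: _expected_detected(normal_means, dispersion, r) - target,
        lo, 1.0, xtol=1e-10))


def generate_cohort(config: CohortConfig
                    ) -> tuple[ExpressionMatrix, CohortTruth]:
    """Draw a tumor/normal counts cohort with known DE truth.

    Fully reproducible from ``config.seed``: gene means, DE gene choice,
    counts, and thinning all come from one seeded generator.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_genes = config.n_genes
    if config.gene_means is not None:
        base_means = np.asarray(config.gene_means, dtype=float).copy()
    else:
        base_means = rng.lognormal(config.mean_log_mu, config.mean_log_sigma,
                                   n_genes)
    de_order = rng.permutation(n_genes)
    up_idx = de_order[:config.n_up]
    down_idx = de_order[config.n_up:config.n_up + config.n_down]
    tumor_means = base_means.copy()
    tumor_means[up_idx] *= config.effect_size
    tumor_means[down_idx] /= config.effect_size

    thinning = _solve_normal_thinning(tumor_means, base_means,
                                      config.dispersion, config.detect_shift)
    log.info("normal-cell thinning rate %.4f for detect_shift %.2f",
             thinning, config.detect_shift)

    shape = 1.0 / config.dispersion

    def _draw(n_cells: int, means: np.ndarray) -> np.ndarray:
        lam = rng.gamma(shape, means * config.dispersion,
                        size=(n_cells, n_genes))
        return rng.poisson(lam)

    tumor_counts = _draw(config.n_tumor, tumor_means)
    normal_counts = _draw(config.n_normal, base_means)
    if thinning < 1.0:
        normal_counts = rng.binomial(normal_counts, thinning)

    gene_ids = [f"g{i:04d}" for i in range(n_genes)]
    cell_ids = ([f"T{i:04d}" for i in range(config.n_tumor)]
                + [f"N{i:04d}" for i in range(config.n_normal)])
    counts = np.vstack([tumor_counts, normal_counts])
    matrix = ExpressionMatrix(counts, gene_ids, cell_ids, layer_tag="counts")
    annotation = CellAnnotation(
        {c: ("Tumor" if c.startswith("T") else "Normal") for c in cell_ids})
    truth = CohortTruth(tuple(gene_ids[i] for i in sorted(up_idx)),
                        tuple(gene_ids[i] for i in sorted(down_idx)),
                        annotation)
    return matrix, truth


def truth_pools(truth: CohortTruth) -> tuple[tuple[str, ...], tuple[str, ...]]:
    """The generator's true DE gene lists, feeding the noisy-set simulator."""
    return truth.up_genes, truth.down_genes
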