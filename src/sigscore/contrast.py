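"""Effect-size contrasts between cell groups and benchmark summaries.

Signature scores from different methods live on different scales, so group
differences are compared with Cohen's d — the mean difference divided by
the pooled standard deviation — which is unitless and comparable across
methods.  A signature is called *up* when ``d >= +threshold`` and *down*
when ``d <= -threshold`` (both boundaries inclusive; default threshold 1).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .matrix import CellAnnotation
from .scoring import ScoreMatrix

log = logging.getLogger(__name__)

#: finite stand-in for an infinite effect (zero pooled SD, unequal means)
LARGE_D = 1e6

CALL_UP = "up"
CALL_DOWN = "down"
CALL_NEUTRAL = "neutral"


def cohens_d(x: Sequence[float], y: Sequence[float]) -> float:
    """Cohen's d with the classic pooled standard deviation.

    ``d = (mean(x) - mean(y)) / s_pooled`` with
    ``s_pooled^2 = ((n1-1) s1^2 + (n2-1) s2^2) / (n1 + n2 - 2)`` using sample
    variances.  Degenerate cases: both groups constant with equal means → 0;
    constant with unequal means → ``sign(diff) * LARGE_D`` with a warning,
    keeping summaries finite while preserving the call.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least 2 values")
    diff = x.mean() - y.mean()
    n1, n2 = len(x), len(y)
    pooled_var = (((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1))
                  / (n1 + n2 - 2))
    if pooled_var == 0:
        if diff == 0:
            return 0.0
        log.warning("zero pooled SD with unequal means; returning signed %g",
                    LARGE_D)
        return math.copysign(LARGE_D, diff)
    return float(diff / math.sqrt(pooled_var))


def classify(d: float, threshold: float = 1.0) -> str:
    """Direction call from an effect size; boundaries are inclusive."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if d >= threshold:
        return CALL_UP
    if d <= -threshold:
        return CALL_DOWN
    return CALL_NEUTRAL


@dataclass(frozen=True)
class ContrastResult:
    """Per-signature contrast: effect size, call, group sizes, set size."""

    signature: str
    cohens_d: float
    call: str
    n1: int
    n2: int
    size: int | None = None


@dataclass
class ContrastOutcome:
    """All per-signature results of one contrast plus call fractions."""

    results: list[ContrastResult]
    frac_up: float
    frac_down: float
    frac_neutral: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.signature, r.size, r.cohens_d, r.call) for r in self.results],
            columns=["signature", "size", "cohens_d", "call"])


def contrast_collection(scores: ScoreMatrix | pd.DataFrame,
                        annotation: CellAnnotation, group1: str, group2: str,
                        threshold: float = 1.0,
                        sizes: Mapping[str, int] | pd.Series | None = None
                        ) -> ContrastOutcome:
    """Cohen's d of every signature between two annotated cell groups.

    ``group1`` is the reference of the sign convention: ``d > 0`` means the
    signature scores higher in ``group1`` (e.g. tumor) than ``group2``.
    ``sizes`` optionally attaches effective signature sizes to the results
    (needed by the size–effect correlation).
    """
    table = scores.scores if isinstance(scores, ScoreMatrix) else scores
    for label in (group1, group2):
        if label not in set(annotation.groups):
            raise ValueError(f"annotation has no group {label!r}")
    cols = pd.Index(table.columns)
    cells1 = [c for c in annotation.cells_in_group(group1) if c in cols]
    cells2 = [c for c in annotation.cells_in_group(group2) if c in cols]
    if len(cells1) < 2 or len(cells2) < 2:
        raise ValueError("both groups need at least 2 scored cells")
    x = table[cells1].to_numpy()
    y = table[cells2].to_numpy()
    results = []
    for i, name in enumerate(table.index):
        d = cohens_d(x[i], y[i])
        size = None if sizes is None else int(sizes[name])
        results.append(ContrastResult(str(name), d, classify(d, threshold),
                                      len(cells1), len(cells2), size))
    n = len(results)
    n_up = sum(r.call == CALL_UP for r in results)
    n_down = sum(r.call == CALL_DOWN for r in results)
    return ContrastOutcome(results, n_up / n, n_down / n,
                           (n - n_up - n_down) / n)


def recovery_rate(results: Sequence[ContrastResult], truth_direction: str
                  ) -> float:
    """Fraction of gold-standard signatures whose call matches the truth."""
    if truth_direction not in (CALL_UP, CALL_DOWN):
        raise ValueError("truth_direction must be 'up' or 'down'")
    if not results:
        raise ValueError("empty result list")
    return sum(r.call == truth_direction for r in results) / len(results)


def false_call_rates(results: Sequence[ContrastResult]
                     ) -> tuple[float, float]:
    """(false-up, false-down) fractions under a null contrast.

    The caller guarantees the contrast is a null (e.g. original cells versus
    their own down-sampled twins), so every non-neutral call is false.
    """
    if not results:
        raise ValueError("empty result list")
    n = len(results)
    return (sum(r.call == CALL_UP for r in results) / n,
            sum(r.call == CALL_DOWN for r in results) / n)


@dataclass
class ConsensusAccuracy:
    """Consensus calls and per-method agreement, split by direction."""

    consensus: list[str]
    per_method: pd.DataFrame  # rows = methods, columns = up / down

    def to_frame(self) -> pd.DataFrame:
        return self.per_method


def consensus_accuracy(calls_by_method: Mapping[str, Sequence[str]],
                       min_agree: int = 2) -> ConsensusAccuracy:
    """Accuracy of each method against the multi-method consensus.

    The consensus call of a signature is a direction supported by at least
    ``min_agree`` methods (else neutral).  Accuracy is computed only over
    signatures with a non-neutral consensus, separately for up- and
    down-consensus sets; an empty consensus set yields NaN.
    """
    methods = list(calls_by_method)
    if len(methods) < 3:
        raise ValueError("consensus needs at least 3 methods")
    lengths = {len(calls_by_method[m]) for m in methods}
    if len(lengths) != 1:
        raise ValueError("call lists are not aligned across methods")
    n = lengths.pop()
    consensus: list[str] = []
    for i in range(n):
        calls = [calls_by_method[m][i] for m in methods]
        n_up = calls.count(CALL_UP)
        n_down = calls.count(CALL_DOWN)
        if n_up >= min_agree and n_down >= min_agree:
            raise ValueError(
                f"conflicting consensus at signature index {i}: "
                f"{n_up} up vs {n_down} down calls")
        if n_up >= min_agree:
            consensus.append(CALL_UP)
        elif n_down >= min_agree:
            consensus.append(CALL_DOWN)
        else:
            consensus.append(CALL_NEUTRAL)
    rows = {}
    for m in methods:
        calls = calls_by_method[m]
        accs = {}
        for direction in (CALL_UP, CALL_DOWN):
            idx = [i for i in range(n) if consensus[i] == direction]
            accs[direction] = (np.nan if not idx else
                               sum(calls[i] == direction for i in idx) / len(idx))
        rows[m] = accs
    frame = pd.DataFrame(rows).T.rename_axis("method")
    return ConsensusAccuracy(consensus, frame)


def score_cv(scores: Sequence[float]) -> float:
    """Coefficient of variation, sample SD / mean.

    Used to measure score stability under down-sampling.  A zero mean has
    no defined CV and returns NaN with a warning.
    """
    scores = np.asarray(scores, dtype=float)
    mean = scores.mean()
    if mean == 0:
        log.warning("score CV undefined for zero-mean scores; returning NaN")
        return float("nan")
    return float(scores.std(ddof=1) / mean)


def size_correlation(results: Sequence[ContrastResult]
                     ) -> tuple[float, float]:
    """Spearman correlation of effective signature size with Cohen's d.

    A positive correlation is the hallmark of gene-count-sensitive scorers;
    p-values are two-sided asymptotic.
    """
    if len(results) < 3:
        raise ValueError("need at least 3 signatures")
    sizes = [r.size for r in results]
    if any(s is None for s in sizes):
        raise ValueError("results lack effective signature sizes")
    if len(set(sizes)) == 1:
        raise ValueError("all signature sizes identical; correlation undefined")
    ds = [r.cohens_d for r in results]
    rho, p = spearmanr(sizes, ds)
    return float(rho), float(p)
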