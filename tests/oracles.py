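"""Naive, loop-based reference implementations used as independent oracles.

Everything here is written with explicit Python loops and comparison
counting — no scipy ranking, no vectorized shortcuts — so agreement with
the package's vectorized scorers is a genuine cross-check, not a tautology.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd


def average_rank(values) -> list[float]:
    """Ascending average-tie ranks by pairwise comparison counting."""
    values = list(values)
    ranks = []
    for v in values:
        n_less = sum(1 for u in values if u < v)
        n_eq = sum(1 for u in values if u == v)
        ranks.append(n_less + (n_eq + 1) / 2.0)
    return ranks


def _minmax(vec: list[float]) -> list[float]:
    lo, hi = min(vec), max(vec)
    if hi == lo:
        return [0.0] * len(vec)
    return [(v - lo) / (hi - lo) for v in vec]


def naive_jasmine(frame: pd.DataFrame, genes, variant: str) -> np.ndarray:
    members = set(genes) & set(frame.columns)
    size = len(members)
    v_means, enrichments = [], []
    for _, row in frame.iterrows():
        expressed = [g for g in frame.columns if row[g] > 0]
        n = len(expressed)
        ranks = dict(zip(expressed, average_rank([row[g] for g in expressed])))
        sig_expr = [g for g in expressed if g in members]
        m = len(sig_expr)
        v_means.append(sum(ranks[g] for g in sig_expr) / (m * n) if m else 0.0)
        a = m
        b = size - m
        c = n - m
        d = len(frame.columns) - size - c
        if variant == "or":
            enrichments.append(a * d / ((1 if b == 0 else b) * c))
        else:
            enrichments.append(a * (c + d) / (c * (a + b)) if a else 0.0)
    return np.array([(x + y) / 2.0
                     for x, y in zip(_minmax(v_means), _minmax(enrichments))])


def naive_scse(frame: pd.DataFrame, genes, scale_factor: float = 100.0
               ) -> np.ndarray:
    members = set(genes) & set(frame.columns)
    out = []
    for _, row in frame.iterrows():
        out.append(sum(row[g] for g in members) / row.sum() * scale_factor)
    return np.array(out)


def naive_aucell(frame: pd.DataFrame, genes, top_fraction: float,
                 seed: int) -> np.ndarray:
    """Recovery-curve AUC; tie-break contract: per-cell permutation drawn
    sequentially from ``default_rng(seed)``, ties ordered by permutation
    position."""
    members = set(genes) & set(frame.columns)
    n_genes = len(frame.columns)
    k = math.ceil(top_fraction * n_genes)
    s = len(members)
    max_auc = sum(min(i, s) for i in range(1, k + 1))
    rng = np.random.default_rng(seed)
    out = []
    for _, row in frame.iterrows():
        perm = list(rng.permutation(n_genes))
        pos_in_perm = {frame.columns[g]: perm.index(g) for g in range(n_genes)}
        ordered = sorted(frame.columns,
                         key=lambda g: (-row[g], pos_in_perm[g]))
        auc = 0
        hits = 0
        for i in range(k):
            if ordered[i] in members:
                hits += 1
            auc += hits
        out.append(auc / max_auc)
    return np.array(out)


def naive_ssgsea(frame: pd.DataFrame, genes, tau: float,
                 normalize: bool) -> np.ndarray:
    """Literal running-sum walk: descending rank order, index tie-break."""
    members = set(genes) & set(frame.columns)
    n_genes = len(frame.columns)
    s = len(members)
    out = []
    for _, row in frame.iterrows():
        ranks = dict(zip(frame.columns, average_rank([row[g]
                                                      for g in frame.columns])))
        index_of = {g: i for i, g in enumerate(frame.columns)}
        walk = sorted(frame.columns, key=lambda g: (-ranks[g], index_of[g]))
        w_total = sum(ranks[g] ** tau for g in walk if g in members)
        p_in = p_out = 0.0
        score = 0.0
        for g in walk:
            if g in members:
                p_in += ranks[g] ** tau / w_total
            else:
                p_out += 1.0 / (n_genes - s)
            score += p_in - p_out
        out.append(score)
    out = np.array(out)
    if normalize:
        span = out.max() - out.min()
        if span > 0:
            out = out / span
    return out


def naive_cohens_d(x, y) -> float:
    n1, n2 = len(x), len(y)
    m1 = sum(x) / n1
    m2 = sum(y) / n2
    v1 = sum((v - m1) ** 2 for v in x) / (n1 - 1)
    v2 = sum((v - m2) ** 2 for v in y) / (n2 - 1)
    pooled = math.sqrt(((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2))
    return (m1 - m2) / pooled


def naive_consensus(calls_by_method: dict, min_agree: int = 2) -> list[str]:
    methods = list(calls_by_method)
    n = len(calls_by_method[methods[0]])
    out = []
    for i in range(n):
        votes = [calls_by_method[m][i] for m in methods]
        if votes.count("up") >= min_agree:
            out.append("up")
        elif votes.count("down") >= min_agree:
            out.append("down")
        else:
            out.append("neutral")
    return out
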