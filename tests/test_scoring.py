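import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import sigscore as ss
from sigscore.scoring import _Workspace, _ssgsea_raw

from .oracles import (naive_aucell, naive_jasmine, naive_scse, naive_ssgsea)


class TestJasmineMeanRank:
    def test_top_gene_scores_one(self):
        cell = pd.Series({"a": 5.0, "b": 4.0, "c": 3.0, "d": 2.0, "e": 1.0})
        assert ss.jasmine_mean_rank(cell, ["a"]) == 1.0

    def test_full_signature_is_midrank(self):
        cell = pd.Series({f"g{i}": float(i + 1) for i in range(5)})
        # sum of ranks 1..N over m=N genes -> (N+1)/(2N)
        assert ss.jasmine_mean_rank(cell, list(cell.index)) == pytest.approx(0.6)

    def test_hand_enumeration_with_dropout(self):
        cell = pd.Series({"g1": 5.0, "g2": 3.0, "g3": 0.0, "g4": 1.0})
        # expressed: g4 rank 1, g2 rank 2, g1 rank 3; N=3, m=2
        assert ss.jasmine_mean_rank(cell, ["g2", "g4"]) == pytest.approx(0.5)

    def test_fully_dropped_signature_scores_zero(self):
        cell = pd.Series({"g1": 2.0, "g2": 0.0})
        assert ss.jasmine_mean_rank(cell, ["g2"]) == 0.0

    def test_all_zero_cell_rejected(self):
        with pytest.raises(ValueError, match="no expressed"):
            ss.jasmine_mean_rank(pd.Series({"a": 0.0, "b": 0.0}), ["a"])


class TestContingency:
    def test_fully_expressed_signature_large_universe(self):
        values = np.zeros(10_000)
        values[:4000] = 1.0  # cell expresses 4000 genes incl. the signature
        genes = [f"g{i}" for i in range(10_000)]
        cell = pd.Series(values, index=genes)
        counts = ss.contingency(cell, genes[:20])
        # a+b+c+d must cover the 10,000-gene universe: d = 10000-20-3980
        assert counts == ss.ContingencyCounts(20, 0, 3980, 6000)
        assert sum(counts) == 10_000

    def test_fully_dropped_signature(self):
        cell = pd.Series({"a": 1.0, "b": 0.0, "c": 0.0})
        counts = ss.contingency(cell, ["b", "c"])
        assert (counts.a, counts.b) == (0, 2)

    def test_matches_bruteforce_tabulation(self):
        rng = np.random.default_rng(13)
        genes = [f"g{i}" for i in range(60)]
        cell = pd.Series(rng.poisson(0.7, 60).astype(float), index=genes)
        sig = set(rng.choice(genes, 17, replace=False))
        counts = ss.contingency(cell, sig)
        a = sum(1 for g in genes if g in sig and cell[g] > 0)
        b = sum(1 for g in genes if g in sig and cell[g] == 0)
        c = sum(1 for g in genes if g not in sig and cell[g] > 0)
        d = sum(1 for g in genes if g not in sig and cell[g] == 0)
        assert counts == ss.ContingencyCounts(a, b, c, d)
        assert counts.a + counts.b == len(sig)
        assert sum(counts) == len(genes)


class TestEnrichment:
    def test_balanced_table_is_one(self):
        assert ss.enrichment_or(ss.ContingencyCounts(10, 10, 100, 100)) == 1.0

    def test_zero_b_replaced_by_one(self):
        value = ss.enrichment_or(ss.ContingencyCounts(20, 0, 480, 9500))
        assert value == pytest.approx(20 * 9500 / 480)

    def test_or_arithmetic(self):
        value = ss.enrichment_or(ss.ContingencyCounts(30, 70, 500, 9400))
        assert value == pytest.approx(282000 / 35000)

    def test_degenerate_cell_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            ss.enrichment_or(ss.ContingencyCounts(5, 0, 0, 10))

    def test_lr_equal_proportions_is_one(self):
        assert ss.enrichment_lr(ss.ContingencyCounts(30, 70, 300, 700)) == 1.0

    def test_lr_fraction_ratio(self):
        value = ss.enrichment_lr(ss.ContingencyCounts(30, 70, 500, 9400))
        assert value == pytest.approx(0.3 / (500 / 9900))

    def test_lr_zero_when_no_signature_expressed(self):
        assert ss.enrichment_lr(ss.ContingencyCounts(0, 30, 500, 9400)) == 0.0

    @given(st.integers(1, 50), st.integers(1, 50), st.integers(1, 500),
           st.integers(0, 500))
    def test_or_and_lr_exceed_one_together(self, a, b, c, d):
        counts = ss.ContingencyCounts(a, b, c, d)
        or_gt = ss.enrichment_or(counts) > 1
        lr_gt = ss.enrichment_lr(counts) > 1
        frac_gt = a / (a + b) > c / (c + d)
        assert or_gt == frac_gt
        assert lr_gt == frac_gt


class TestJasmineScores:
    def test_extreme_cell_scores_one(self):
        # cell c0 has every signature gene top-ranked and fully expressed;
        # genes e,f are never expressed so the odds ratio stays informative
        dense = np.array([[9.0, 8.0, 1.0, 1.0, 0.0, 0.0],
                          [1.0, 0.0, 8.0, 9.0, 0.0, 0.0],
                          [2.0, 0.0, 5.0, 5.0, 0.0, 0.0]])
        m = ss.ExpressionMatrix(dense, list("abcdef"), ["c0", "c1", "c2"],
                                "normalized")
        scores = ss.jasmine_scores(m, ["a", "b"])
        assert scores["c0"] == 1.0
        assert scores.between(0, 1).all()

    def test_constant_components_score_zero(self):
        dense = np.tile(np.array([[3.0, 2.0, 1.0]]), (3, 1))
        m = ss.ExpressionMatrix(dense, list("abc"), ["c0", "c1", "c2"],
                                "normalized")
        assert (ss.jasmine_scores(m, ["a"]) == 0.0).all()

    def test_single_cell_rejected(self):
        m = ss.ExpressionMatrix(np.array([[1.0, 2.0]]), ["a", "b"], ["c"],
                                "normalized")
        with pytest.raises(ValueError, match="2 cells"):
            ss.jasmine_scores(m, ["a"])

    def test_empty_intersection_rejected(self, small_matrix):
        with pytest.raises(ValueError, match="intersect"):
            ss.jasmine_scores(small_matrix, ["not_a_gene"])

    @pytest.mark.parametrize("variant", ["or", "lr"])
    def test_unit_interval_and_monotone_invariance(self, small_matrix,
                                                   small_signatures, variant):
        """JASMINE depends only on the zero pattern and within-cell ranks."""
        sig = small_signatures[1]
        base = ss.jasmine_scores(small_matrix, sig, variant)
        assert base.between(0, 1).all()
        dense = small_matrix.to_dense()
        for transform in (np.square, np.log1p, lambda x: 3.7 * x):
            warped = ss.ExpressionMatrix(transform(dense),
                                         small_matrix.gene_ids,
                                         small_matrix.cell_ids, "normalized")
            np.testing.assert_allclose(
                ss.jasmine_scores(warped, sig, variant), base, atol=1e-12)


class TestScse:
    def test_share_arithmetic(self):
        dense = np.array([[50.0, 950.0], [100.0, 900.0]])
        m = ss.ExpressionMatrix(dense, ["a", "b"], ["c1", "c2"], "normalized")
        scores = ss.scse_scores(m, ["a"])
        assert scores["c1"] == pytest.approx(5.0)
        assert scores["c2"] == pytest.approx(10.0)

    def test_whole_universe_gives_scale_factor(self, small_matrix):
        scores = ss.scse_scores(small_matrix, list(small_matrix.gene_ids))
        np.testing.assert_allclose(scores, 100.0)

    def test_per_cell_rescaling_invariance(self, small_matrix,
                                           small_signatures):
        dense = small_matrix.to_dense()
        scale = np.linspace(0.5, 7.0, small_matrix.n_cells)[:, None]
        warped = ss.ExpressionMatrix(dense * scale, small_matrix.gene_ids,
                                     small_matrix.cell_ids, "normalized")
        np.testing.assert_allclose(
            ss.scse_scores(warped, small_signatures[0]),
            ss.scse_scores(small_matrix, small_signatures[0]))


class TestAucell:
    def _matrix(self):
        # 10 genes with distinct descending values in one cell
        dense = np.arange(10, 0, -1, dtype=float)[None, :]
        return ss.ExpressionMatrix(dense, [f"g{i}" for i in range(1, 11)],
                                   ["c"], "normalized")

    def test_top_block_signature_scores_one(self):
        m = self._matrix()
        assert ss.aucell_scores(m, ["g1", "g2"], 0.3).iloc[0] == 1.0

    def test_signature_outside_top_k_scores_zero(self):
        m = self._matrix()
        assert ss.aucell_scores(m, ["g9", "g10"], 0.3).iloc[0] == 0.0

    def test_step_curve_enumeration(self):
        # k=3, signature at ranks 1 and 3: recovery (1,1,2), max (1,2,2)
        m = self._matrix()
        assert ss.aucell_scores(m, ["g1", "g3"], 0.3).iloc[0] == \
            pytest.approx(0.8)

    def test_rank_order_invariance(self, small_matrix, small_signatures):
        """Only within-cell rank order matters (same seed, monotone warp)."""
        base = ss.aucell_scores(small_matrix, small_signatures[0], seed=5)
        dense = small_matrix.to_dense()
        warped = ss.ExpressionMatrix(np.sqrt(dense), small_matrix.gene_ids,
                                     small_matrix.cell_ids, "normalized")
        np.testing.assert_allclose(
            ss.aucell_scores(warped, small_signatures[0], seed=5), base)


class TestSsgsea:
    def _four_gene(self):
        return ss.ExpressionMatrix(np.array([[4.0, 3.0, 2.0, 1.0]]),
                                   list("abcd"), ["c"], "normalized")

    def test_top_gene_running_sum(self):
        m = self._four_gene()
        assert ss.ssgsea_scores(m, ["a"], normalize=False).iloc[0] == \
            pytest.approx(2.0)

    def test_bottom_gene_running_sum(self):
        m = self._four_gene()
        assert ss.ssgsea_scores(m, ["d"], normalize=False).iloc[0] == \
            pytest.approx(-2.0)

    def test_storage_order_invariance_without_ties(self):
        rng = np.random.default_rng(21)
        values = rng.uniform(0.1, 10.0, 30)  # strictly positive, distinct
        genes = [f"g{i}" for i in range(30)]
        m = ss.ExpressionMatrix(values[None, :], genes, ["c"], "normalized")
        sig = ["g3", "g7", "g20"]
        base = ss.ssgsea_scores(m, sig, normalize=False).iloc[0]
        perm = rng.permutation(30)
        m2 = ss.ExpressionMatrix(values[perm][None, :],
                                 [genes[i] for i in perm], ["c"], "normalized")
        assert ss.ssgsea_scores(m2, sig, normalize=False).iloc[0] == \
            pytest.approx(base, rel=1e-12)

    def test_whole_universe_signature_rejected(self):
        m = self._four_gene()
        with pytest.raises(ValueError, match="strict subset"):
            ss.ssgsea_scores(m, list("abcd"))


class TestOracleEquivalence:
    """Every vectorized scorer equals a naive loop-based reference."""

    @pytest.mark.parametrize("variant", ["or", "lr"])
    def test_jasmine(self, small_matrix, small_signatures, variant):
        frame = small_matrix.to_frame()
        for sig in small_signatures:
            np.testing.assert_allclose(
                ss.jasmine_scores(small_matrix, sig, variant),
                naive_jasmine(frame, sig.genes, variant), atol=1e-12)

    def test_scse(self, small_matrix, small_signatures):
        frame = small_matrix.to_frame()
        for sig in small_signatures:
            np.testing.assert_allclose(
                ss.scse_scores(small_matrix, sig),
                naive_scse(frame, sig.genes), atol=1e-12)

    def test_aucell(self, small_matrix, small_signatures):
        frame = small_matrix.to_frame()
        for sig in small_signatures:
            np.testing.assert_allclose(
                ss.aucell_scores(small_matrix, sig, top_fraction=0.2, seed=3),
                naive_aucell(frame, sig.genes, 0.2, seed=3), atol=1e-12)

    @pytest.mark.parametrize("normalize", [False, True])
    def test_ssgsea(self, small_matrix, small_signatures, normalize):
        frame = small_matrix.to_frame()
        for sig in small_signatures:
            np.testing.assert_allclose(
                ss.ssgsea_scores(small_matrix, sig, normalize=normalize),
                naive_ssgsea(frame, sig.genes, 0.25, normalize), atol=1e-9)


class TestScoreCollection:
    def test_matches_single_signature_functions(self, small_matrix,
                                                small_signatures):
        coll = ss.GeneSetCollection(small_signatures)
        singles = {
            "jasmine_or": lambda s: ss.jasmine_scores(small_matrix, s, "or"),
            "jasmine_lr": lambda s: ss.jasmine_scores(small_matrix, s, "lr"),
            "scse": lambda s: ss.scse_scores(small_matrix, s),
            "aucell": lambda s: ss.aucell_scores(small_matrix, s, seed=0),
            "ssgsea": lambda s: ss.ssgsea_scores(small_matrix, s,
                                                 normalize=False),
        }
        for method, fn in singles.items():
            table = ss.score_collection(small_matrix, coll, method,
                                        normalize=False, seed=0).scores
            for sig in small_signatures:
                np.testing.assert_allclose(table.loc[sig.name], fn(sig),
                                           atol=1e-12)

    def test_ssgsea_global_range_normalization(self, small_matrix,
                                               small_signatures):
        coll = ss.GeneSetCollection(small_signatures)
        raw = ss.score_collection(small_matrix, coll, "ssgsea",
                                  normalize=False).scores
        norm = ss.score_collection(small_matrix, coll, "ssgsea",
                                   normalize=True).scores
        span = raw.to_numpy().max() - raw.to_numpy().min()
        np.testing.assert_allclose(norm, raw / span, atol=1e-12)

    def test_closed_form_matches_running_sum_oracle(self, small_matrix):
        ws = _Workspace(small_matrix)
        idx = ws.signature_index(["g01", "g05", "g30"])
        raw = _ssgsea_raw(ws, idx, 0.25)
        expected = naive_ssgsea(small_matrix.to_frame(),
                                ["g01", "g05", "g30"], 0.25, False)
        np.testing.assert_allclose(raw, expected, atol=1e-9)

    def test_unknown_method_rejected(self, small_matrix, small_signatures):
        with pytest.raises(ValueError, match="unknown method"):
            ss.score_collection(small_matrix,
                                ss.GeneSetCollection(small_signatures),
                                "gsva")

    def test_to_tsv_writes_sidecar(self, tmp_path, small_matrix,
                                   small_signatures):
        coll = ss.GeneSetCollection(small_signatures[:2])
        sm = ss.score_collection(small_matrix, coll, "scse")
        out = tmp_path / "scores.tsv"
        sm.to_tsv(out)
        assert out.exists()
        sidecar = tmp_path / "scores.tsv.params.json"
        assert "scse" in sidecar.read_text()
        back = pd.read_csv(out, sep="\t", index_col=0)
        np.testing.assert_allclose(back.to_numpy(), sm.scores.to_numpy())
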