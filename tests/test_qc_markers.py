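"""QC boundary behaviour, DE statistics and entropy-ranked signatures."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import rankdata

from hepatlas import planted_markers
from hepatlas.qc_markers import (
    de_stats,
    entropy_specificity,
    qc_filter,
    select_signatures,
)

from conftest import make_expression


class TestQcFilter:
    def test_detected_gene_window_is_inclusive(self):
        counts = np.ones((2, 5), dtype=int)
        expr = make_expression(counts, n_detected=[100, 200, 1000, 4000, 5000])
        kept = qc_filter(expr, min_cells_per_gene=0)
        assert list(kept.cell_meta["n_detected_genes"]) == [200, 1000, 4000]

    def test_mito_cut_is_strict(self):
        expr = make_expression(np.ones((2, 3), dtype=int),
                               mito=[0.05, 0.10, 0.15], n_detected=[500] * 3)
        kept = qc_filter(expr, min_cells_per_gene=0)
        assert kept.n_cells == 1
        assert kept.cell_meta["mito_fraction"].iloc[0] == 0.05

    def test_gene_filter_is_strict_over_three_cells(self):
        counts = np.zeros((2, 8), dtype=int)
        counts[0, :3] = 1  # detected in exactly 3 cells -> removed
        counts[1, :4] = 1  # detected in 4 cells -> kept
        expr = make_expression(counts, n_detected=[500] * 8)
        kept = qc_filter(expr)
        assert list(kept.gene_ids) == ["g1"]

    def test_idempotent(self, sc_expr):
        once = qc_filter(sc_expr, min_genes=0, max_genes=10**6)
        twice = qc_filter(once, min_genes=0, max_genes=10**6)
        assert np.array_equal(once.counts, twice.counts)
        assert once.gene_ids.equals(twice.gene_ids)

    def test_all_cells_removed_warns(self):
        expr = make_expression(np.ones((2, 3), dtype=int), mito=0.5)
        with pytest.warns(UserWarning, match="every cell"):
            kept = qc_filter(expr)
        assert kept.n_cells == 0


class TestDeStats:
    def test_constant_gene_is_null(self):
        counts = np.array([[5] * 12, [1] * 6 + [9] * 6])
        expr = make_expression(counts, subtype=["a"] * 6 + ["b"] * 6)
        table = de_stats(expr)
        row = table[(table.cluster == "a") & (table.gene == "g0")].iloc[0]
        assert row["avg_log2FC"] == 0.0
        assert row["p_adj"] == 1.0

    def test_statistic_matches_brute_force_rank_sum(self):
        # 6-vs-6 toy with ties: U1 = W1 - n1(n1+1)/2 from midranks; the
        # filler gene keeps library sizes equal so normalization is a
        # uniform rescale and the raw ranks carry through
        x1 = np.array([3, 7, 7, 1, 9, 4])
        x2 = np.array([2, 2, 8, 5, 6, 4])
        x = np.concatenate([x1, x2])
        counts = np.vstack([x, 20 - x])
        expr = make_expression(counts, subtype=["a"] * 6 + ["b"] * 6)
        table = de_stats(expr)
        ranks = rankdata(np.concatenate([x1, x2]))
        u1 = ranks[:6].sum() - 6 * 7 / 2
        got = table[(table.cluster == "a") & (table.gene == "g0")].iloc[0]
        assert got["statistic"] == pytest.approx(u1)

    def test_planted_marker_detected_with_expected_fold(self):
        # planted 2**3 mean ratio, 200 vs 600 cells: adj p < 0.01 and
        # avg_log2FC in [2, 4] in at least 95% of seeds
        from hepatlas import ScSimConfig, simulate_sc

        hits = 0
        n_seeds = 20
        for seed in range(n_seeds):
            cfg = ScSimConfig(n_types=4, cells_per_type=200, n_genes=400,
                              markers_per_type=5, marker_log2fc=3.0, seed=seed)
            table = de_stats(simulate_sc(cfg))
            row = table[(table.cluster == "type0")
                        & (table.gene == "gene00000")].iloc[0]
            hits += (row["p_adj"] < 0.01) and (2.0 <= row["avg_log2FC"] <= 4.0)
        assert hits >= 0.95 * n_seeds

    def test_requires_two_clusters(self):
        expr = make_expression(np.ones((2, 6), dtype=int))
        with pytest.raises(ValueError, match="clusters"):
            de_stats(expr)


class TestEntropySpecificity:
    @pytest.mark.parametrize(
        "means, expected",
        [((1, 0, 0, 0), 2.0),     # one-hot: log2 4
         ((2, 2, 2, 2), 0.0),     # uniform: maximum entropy
         ((5, 5, 0, 0), 1.0)],    # two-cluster split: 1 bit
    )
    def test_analytic_limits(self, means, expected):
        assert entropy_specificity(means) == pytest.approx(expected, abs=1e-6)

    def test_scale_invariant(self):
        v = np.array([3.0, 1.0, 0.5, 7.0])
        assert entropy_specificity(v) == pytest.approx(
            entropy_specificity(17.3 * v), abs=1e-12)

    def test_decreases_as_mass_spreads(self):
        # majorization: (8,0,0,0) > (6,2,0,0) > (4,4,0,0) > (4,2,2,0)
        chain = [(8, 0, 0, 0), (6, 2, 0, 0), (4, 4, 0, 0), (4, 2, 2, 0)]
        scores = [entropy_specificity(v) for v in chain]
        assert all(a > b for a, b in zip(scores, scores[1:]))

    def test_all_zero_returns_zero(self):
        assert entropy_specificity((0, 0, 0)) == 0.0

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(
        means=st.lists(st.floats(0.0, 1e6, allow_nan=False), min_size=2,
                       max_size=12),
        scale=st.floats(1e-3, 1e3),
    )
    def test_bounds_and_scale_invariance_hold_generally(self, means, scale):
        d = entropy_specificity(means)
        assert 0.0 <= d <= np.log2(len(means)) + 1e-9
        if sum(means) > 0:
            assert entropy_specificity([scale * m for m in means]) == \
                pytest.approx(d, abs=1e-6)

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            entropy_specificity((1, -1, 0))


class TestSelectSignatures:
    @staticmethod
    def _row(cluster="c1", gene="GENE", lfc=2.0, pct1=0.6, pct2=0.2,
             p_adj=1e-5, ent=1.0):
        import pandas as pd

        return pd.DataFrame(
            [{"cluster": cluster, "gene": gene, "avg_log2FC": lfc,
              "pct1": pct1, "pct2": pct2, "p_adj": p_adj, "entropy_diff": ent}]
        )

    def test_macrophage_rule_enforces_pct2(self):
        table = self._row(pct1=0.6, pct2=0.6)
        assert select_signatures(table, "macrophage")["c1"] == []

    def test_tcell_rule_has_no_pct_threshold(self):
        table = self._row(pct1=0.6, pct2=0.6)
        assert select_signatures(table, "tcell")["c1"] == ["GENE"]

    def test_curated_exclusion_list_applied(self):
        import pandas as pd

        table = pd.concat([self._row(gene="ALB"), self._row(gene="SPP1")])
        assert select_signatures(table, "macrophage")["c1"] == ["SPP1"]

    def test_entropy_ranking_and_top_n(self):
        import pandas as pd

        table = pd.concat([self._row(gene="A", ent=0.5),
                           self._row(gene="B", ent=2.0),
                           self._row(gene="C", ent=1.0)])
        got = select_signatures(table, "macrophage", top_n_by_entropy=2)
        assert got["c1"] == ["B", "C"]

    def test_planted_markers_recovered(self, sc_config, sc_de_table):
        sigs = select_signatures(sc_de_table, "macrophage")
        truth = planted_markers(sc_config)
        tp = sum(len(set(sigs[k]) & set(truth[k])) for k in truth)
        n_truth = sum(len(v) for v in truth.values())
        n_sel = sum(len(v) for v in sigs.values())
        assert tp / n_truth >= 0.9      # sensitivity
        assert tp / n_sel >= 0.9        # precision
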