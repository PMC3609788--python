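"""Weighted-KS GSEA: hand-checked values, oracle equivalence, calibration."""

import itertools

import numpy as np
import pytest

import mirtarget as mt
from conftest import brute_force_es, brute_force_running_sum
from mirtarget.gsea import cutoff_scan, enrichment_score, gsea_test, ranking_metric

import pandas as pd


def ranked_from(ids, metrics):
    return mt.RankedGeneList.from_scores(ids, metrics)


class TestRankingMetric:
    def test_identical_arrays_zero_metric_id_order(self):
        expr = pd.Series([10.0, 5.0, 7.0], index=pd.Index(["c", "a", "b"], name="gene_id"))
        ranked = ranking_metric(expr, expr.copy())
        assert np.allclose(ranked.metric, 0.0)
        assert list(ranked.gene_ids) == ["a", "b", "c"]

    def test_log2_ratio_value(self):
        tx = pd.Series({"g": 100.0})
        ctrl = pd.Series({"g": 400.0})
        ranked = ranking_metric(tx, ctrl)
        assert ranked.metric[0] == pytest.approx(-2.0)

    def test_input_order_invariance(self):
        idx = pd.Index(["a", "b", "c", "d"], name="gene_id")
        tx = pd.Series([1.0, 2.0, 3.0, 4.0], index=idx)
        ctrl = pd.Series([4.0, 3.0, 2.0, 1.0], index=idx)
        r1 = ranking_metric(tx, ctrl)
        perm = [2, 0, 3, 1]
        r2 = ranking_metric(tx.iloc[perm], ctrl.iloc[perm])
        assert list(r1.gene_ids) == list(r2.gene_ids)
        assert np.allclose(r1.metric, r2.metric)

    def test_duplicates_averaged_before_ratio(self):
        tx = pd.Series([2.0, 6.0], index=["g", "g"])
        ctrl = pd.Series([1.0, 1.0], index=["g", "g"])
        ranked = ranking_metric(tx, ctrl)
        assert ranked.metric[0] == pytest.approx(2.0)  # log2(4/1)

    def test_non_positive_expression_raises(self):
        with pytest.raises(ValueError, match="gbad"):
            ranking_metric(pd.Series({"gbad": 0.0}), pd.Series({"gbad": 1.0}))


class TestEnrichmentScore:
    def test_single_gene_set_at_rank_one(self):
        ranked = ranked_from(["a", "b", "c"], [3.0, 2.0, 1.0])
        es, _ = enrichment_score(ranked, {"a"})
        assert es == pytest.approx(1.0)

    def test_hand_computed_running_sum(self):
        ranked = ranked_from(["g1", "g2", "g3", "g4"], [4.0, 3.0, 2.0, 1.0])
        es, rs = enrichment_score(ranked, {"g1", "g3"}, weight_exponent=1.0)
        assert np.allclose(rs, [2 / 3, 1 / 6, 1 / 2, 0.0])
        assert es == pytest.approx(2 / 3)

    def test_degenerate_sets_raise(self):
        ranked = ranked_from(["a", "b"], [1.0, 0.5])
        with pytest.raises(ValueError):
            enrichment_score(ranked, set())
        with pytest.raises(ValueError):
            enrichment_score(ranked, {"a", "b"})

    def test_es_bounded_and_negated_on_mirror(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = int(rng.integers(4, 30))
            ids = [f"g{i}" for i in range(n)]
            met = np.sort(rng.normal(size=n))[::-1]
            k = int(rng.integers(1, n))
            gs = set(rng.choice(ids, k, replace=False))
            ranked = ranked_from(ids, met)
            es, rs = enrichment_score(ranked, gs)
            assert -1.0 <= es <= 1.0
            assert abs(es) == pytest.approx(np.max(np.abs(rs)))
            # mirror: reverse the list and flip metric signs
            mirrored = mt.RankedGeneList(gene_ids=ranked.gene_ids[::-1].copy(),
                                         metric=-ranked.metric[::-1].copy())
            es_m, _ = enrichment_score(mirrored, gs)
            assert es_m == pytest.approx(-es)

    def test_equals_brute_force_on_random_lists(self):
        rng = np.random.default_rng(42)
        for n in range(5, 13):
            ids = [f"g{i}" for i in range(n)]
            met = np.sort(rng.normal(size=n))[::-1]
            ranked = ranked_from(ids, met)
            for k in range(1, min(4, n - 1) + 1):
                for combo in itertools.combinations(range(n), k):
                    hit = np.zeros(n, dtype=bool)
                    hit[list(combo)] = True
                    es, rs = enrichment_score(ranked, {ids[i] for i in combo})
                    assert np.allclose(rs, brute_force_running_sum(met, hit))
                    assert es == pytest.approx(brute_force_es(met, hit))


class TestGseaTest:
    def test_seeded_determinism(self):
        ranked = ranked_from([f"g{i}" for i in range(40)],
                             np.linspace(2, -2, 40))
        gs = {"g1", "g5", "g9", "g30"}
        a = gsea_test(ranked, gs, n_perm=200, seed=7)
        b = gsea_test(ranked, gs, n_perm=200, seed=7)
        assert (a.nes, a.p_value, a.fdr_q) == (b.nes, b.p_value, b.fdr_q)

    def test_nes_sign_matches_es_sign(self):
        ranked = ranked_from([f"g{i}" for i in range(40)], np.linspace(2, -2, 40))
        top = gsea_test(ranked, {"g0", "g1", "g2"}, n_perm=200, seed=1)
        bottom = gsea_test(ranked, {"g37", "g38", "g39"}, n_perm=200, seed=1)
        assert top.es > 0 and top.nes > 0
        assert bottom.es < 0 and bottom.nes < 0

    def test_monte_carlo_p_matches_exhaustive_enumeration(self):
        """6-gene list, 2-gene sets: MC p within 2 SE of the exact C(6,2) null."""
        ids = [f"g{i}" for i in range(6)]
        met = np.array([3.0, 2.0, 1.0, -1.0, -2.0, -3.0])
        ranked = ranked_from(ids, met)
        gs = {"g4", "g5"}
        es_obs, _ = enrichment_score(ranked, gs)
        null = []
        for combo in itertools.combinations(range(6), 2):
            hit = np.zeros(6, dtype=bool)
            hit[list(combo)] = True
            null.append(brute_force_es(met, hit))
        null = np.array(null)
        same = null[np.sign(null) == np.sign(es_obs)]
        p_exact = np.mean(np.abs(same) >= abs(es_obs))
        res = gsea_test(ranked, gs, n_perm=10_000, seed=123)
        n_same_expected = 10_000 * len(same) / len(null)
        se = np.sqrt(p_exact * (1 - p_exact) / n_same_expected) + 1e-9
        assert res.p_value == pytest.approx(p_exact, abs=max(2 * se, 0.01))


class TestCutoffScan:
    @staticmethod
    def _enrichment_table(ids, scores):
        tab = pd.DataFrame({"score": scores}, index=pd.Index(ids, name="gene_id"))
        tab = tab.sort_values("score", ascending=False, kind="mergesort")
        tab["rank"] = np.arange(1, len(tab) + 1)
        return tab

    def test_plateau_rates_share_nes(self):
        """Adjacent rates with identical top-k sets give identical NES."""
        ids = [f"g{i}" for i in range(10)]
        tab = self._enrichment_table(ids, np.linspace(5, 1, 10))
        rng = np.random.default_rng(5)
        ranked = ranked_from(ids, np.sort(rng.normal(size=10))[::-1])
        scan = cutoff_scan(tab, ranked, None, grid=[20, 21, 22, 30], n_perm=200, seed=0)
        # 20/21/22% of 10 genes all round to k=2
        assert scan.nes_per_rate[0] == scan.nes_per_rate[1] == scan.nes_per_rate[2]

    def test_recovers_planted_target_depth(self):
        """Targets planted as the top 10% of enrichment -> optimum in [5,15]%."""
        rng = np.random.default_rng(17)
        n = 400
        ids = [f"g{i:03d}" for i in range(n)]
        targets = set(ids[:40])
        scores = np.linspace(10, 1, n)
        tab = self._enrichment_table(ids, scores)
        metric = np.where(np.isin(ids, list(targets)), rng.normal(-2, 0.3, n),
                          rng.normal(0, 0.3, n))
        ranked = mt.RankedGeneList.from_scores(ids, metric)
        scan = cutoff_scan(tab, ranked, None, grid=range(1, 51), n_perm=200, seed=4)
        assert 5 <= scan.optimum_rate <= 15
        assert scan.optimum_set <= set(ids)

    def test_optimum_is_grid_minimum(self):
        ids = [f"g{i}" for i in range(50)]
        tab = self._enrichment_table(ids, np.linspace(5, 1, 50))
        rng = np.random.default_rng(2)
        ranked = mt.RankedGeneList.from_scores(ids, rng.normal(size=50))
        scan = cutoff_scan(tab, ranked, None, grid=range(5, 100, 5), n_perm=200, seed=9)
        valid = ~np.isnan(scan.nes_per_rate)
        assert scan.nes_per_rate[valid].min() == scan.results[scan.optimum_rate].nes
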