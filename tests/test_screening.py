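"""Screening triage: hit calling, common downregulation, panel frequencies."""

import numpy as np
import pandas as pd
import pytest

import mirtarget as mt
from conftest import make_panel


class TestFunctionalHits:
    def test_no_suppression_gives_empty_set(self, toy_growth):
        flat = mt.ScreenMatrix(values=toy_growth.values * 0 + 1.0, roles=toy_growth.roles)
        assert mt.functional_hits(flat) == set()

    def test_toy_threshold_counting(self, toy_growth):
        thr = mt.ScreenThresholds(growth_ratio_cut=0.8, min_hit_lines=4)
        assert mt.functional_hits(toy_growth, thr) == {"miR-A", "miR-B"}

    def test_cut_is_strict(self, toy_growth):
        vals = toy_growth.values.copy()
        vals.loc["miR-A"] = 0.8  # exactly at the cut in every line -> not a hit
        sm = mt.ScreenMatrix(values=vals, roles=toy_growth.roles)
        assert "miR-A" not in mt.functional_hits(sm)

    def test_missing_values_raise_with_names(self, toy_growth):
        vals = toy_growth.values.copy()
        vals.loc["miR-B", "L1"] = np.nan
        sm = mt.ScreenMatrix(values=vals, roles=toy_growth.roles)
        with pytest.raises(ValueError, match="miR-B"):
            mt.functional_hits(sm)

    def test_monotone_in_thresholds(self, toy_growth):
        base = mt.functional_hits(toy_growth, mt.ScreenThresholds(0.8, 4))
        looser_cut = mt.functional_hits(toy_growth, mt.ScreenThresholds(0.9, 4))
        fewer_lines = mt.functional_hits(toy_growth, mt.ScreenThresholds(0.8, 3))
        assert base <= looser_cut
        assert base <= fewer_lines


class TestCommonlyDownregulated:
    def test_equal_to_reference_is_empty(self):
        panel = make_panel({"m1": [100.0] * 6})
        assert mt.commonly_downregulated(panel) == set()

    def test_boundary_strictly_below_half(self):
        panel = make_panel({
            "m-in": [49, 40, 30, 45, 20, 10],
            "m-out": [51, 40, 30, 45, 20, 10],   # one line misses the strict cut
            "m-edge": [50, 40, 30, 45, 20, 10],  # exactly half: strict < excludes
        })
        assert mt.commonly_downregulated(panel) == {"m-in"}

    def test_reference_summary_is_min_of_references(self):
        lines = [f"L{i}" for i in range(1, 7)]
        values = pd.DataFrame({"R1": [100.0], "R2": [60.0],
                               **{c: [29.0] for c in lines}}, index=["m1"])
        roles = {"R1": "normal_reference", "R2": "normal_reference",
                 **{c: "cell_line" for c in lines}}
        sm = mt.ScreenMatrix(values=values, roles=roles)
        # must be below half of BOTH references: 29 < 30 = 60/2 passes
        assert mt.commonly_downregulated(sm) == {"m1"}
        sm.values.loc["m1", lines] = 31.0  # below 50 but not below 30
        assert mt.commonly_downregulated(sm) == set()

    def test_unquantified_line_disqualifies(self):
        panel = make_panel({"m1": [10, 10, 10, 10, 10, np.nan]})
        assert mt.commonly_downregulated(panel) == set()

    def test_no_reference_raises(self, toy_growth):
        with pytest.raises(ValueError, match="reference"):
            mt.commonly_downregulated(toy_growth)

    def test_monotone_in_fold(self):
        panel = make_panel({"m1": [24, 24, 24, 24, 24, 24]})
        assert mt.commonly_downregulated(panel, mt.ScreenThresholds(downregulation_fold=2)) \
            >= mt.commonly_downregulated(panel, mt.ScreenThresholds(downregulation_fold=5))


def test_candidate_intersection():
    assert mt.candidate_ts_mirnas({"a", "b", "c"}, {"b", "c", "d"}) == {"b", "c"}
    assert mt.candidate_ts_mirnas({"a"}, {"b"}) == set()


class TestPanelFrequency:
    def test_tumors_equal_pairs_give_zero(self):
        panel = make_panel({"m1": [100.0] * 6},
                           tn_ratios={"m1": [(80.0, 80.0)] * 4})
        freq = mt.panel_frequency(panel)
        assert freq.loc["m1", "tumor_frequency"] == 0.0

    def test_half_frequency_fails_strict_cut(self):
        # T/N ratios 0.3, 0.4, 0.9, 1.2 -> two of four pairs below 0.5
        tn = [(30.0, 100.0), (40.0, 100.0), (90.0, 100.0), (120.0, 100.0)]
        panel = make_panel({"m1": [10.0] * 6}, tn_ratios={"m1": tn})
        freq = mt.panel_frequency(panel)
        assert freq.loc["m1", "tumor_frequency"] == pytest.approx(0.5)
        assert not freq.loc["m1", "passes"]  # 0.5 is not > 0.5

    def test_missing_pair_reduces_denominator(self):
        tn = [(30.0, 100.0), (40.0, 100.0), (np.nan, 100.0)]
        panel = make_panel({"m1": [10.0] * 6}, tn_ratios={"m1": tn})
        freq = mt.panel_frequency(panel)
        assert freq.loc["m1", "tumor_frequency"] == pytest.approx(1.0)

    def test_unpaired_tumor_raises(self):
        panel = make_panel({"m1": [10.0] * 6}, tn_ratios={"m1": [(30.0, 100.0)]})
        panel.roles["N0"] = "cell_line"  # orphan the tumor sample
        with pytest.raises(ValueError, match="unpaired"):
            mt.panel_frequency(panel)


def test_zero_noise_screen_recovers_planted_set_exactly():
    cfg = mt.SimulationConfig(growth_noise_sd=0.0, array_noise_sd=0.0, rng_seed=9)
    sim = mt.simulate_screen(cfg)
    hits = mt.functional_hits(sim.growth)
    down = mt.commonly_downregulated(sim.panel)
    assert mt.candidate_ts_mirnas(hits, down) == sim.truth.true_ts_mirna_ids
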