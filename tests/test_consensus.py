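import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from multiscreen.chem_io import TargetConfig
from multiscreen.consensus import (
    DockingEnergyTable,
    combined_probability,
    docking_active,
    docking_probability,
    fuse,
)

probs = st.floats(0.0, 1.0, allow_nan=False)


class TestDockingProbability:
    def test_reference_ligand_worked_example(self):
        # quinone-reductase table: ligand -36, best compound -137
        assert docking_probability(-36.0, -137.0) == pytest.approx(0.26, abs=0.005)

    def test_best_scorer_gets_exactly_one(self):
        assert docking_probability(-137.0, -137.0) == 1.0

    def test_inos_ligand_ratio(self):
        assert docking_probability(-59.0, -178.0) == pytest.approx(0.3315, abs=5e-5)

    def test_monotone_in_score(self):
        e_mlig = -150.0
        scores = np.linspace(-150, -10, 30)
        p = [docking_probability(s, e_mlig) for s in scores]
        assert np.all(np.diff(p) < 0)  # less negative score, smaller probability

    def test_nonbinding_pose_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            assert docking_probability(5.0, -100.0) == 0.0

    def test_inconsistent_table_errors(self):
        with pytest.raises(ValueError, match="negative"):
            docking_probability(-50.0, 10.0)
        with pytest.raises(ValueError, match="inconsistent"):
            docking_probability(-200.0, -100.0)


class TestDockingActive:
    def test_better_than_reference_is_active(self):
        assert docking_active(-137.0, -36.0)

    def test_tie_is_inactive(self):
        assert not docking_active(-36.0, -36.0)

    def test_flag_equivalent_to_probability_comparison(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            scores = -rng.uniform(10, 200, 12)
            e_inib = -rng.uniform(10, 200)
            e_mlig = min(scores.min(), e_inib)  # keep ratios within [0, 1]
            lig_prob = docking_probability(e_inib, e_mlig)
            for s in scores:
                assert docking_active(s, e_inib) == (
                    docking_probability(s, e_mlig) > lig_prob
                )


class TestCombinedProbability:
    def test_zero_esp_is_arithmetic_mean(self):
        assert combined_probability(0.4, 0.6, esp=0.0) == pytest.approx(0.5)

    def test_full_esp_weights_ligand_probability_double(self):
        assert combined_probability(0.3, 0.6, esp=1.0) == pytest.approx(0.5)

    @given(p=probs, esp=probs)
    @settings(max_examples=100, derandomize=True)
    def test_equal_inputs_are_a_fixed_point(self, p, esp):
        assert combined_probability(p, p, esp) == pytest.approx(p)

    @given(prob_dc=probs, p_activity=probs, esp=probs)
    @settings(max_examples=200, derandomize=True)
    def test_convex_combination_bounds(self, prob_dc, p_activity, esp):
        comb = combined_probability(prob_dc, p_activity, esp)
        lo, hi = sorted((prob_dc, p_activity))
        assert lo - 1e-12 <= comb <= hi + 1e-12

    def test_ligand_weight_increases_with_esp(self):
        # weight on p_activity is (1+esp)/(2+esp): 1/2 at esp=0, 2/3 at esp=1
        weights = [
            combined_probability(0.0, 1.0, esp) for esp in np.linspace(0, 1, 11)
        ]
        assert np.all(np.diff(weights) > 0)
        assert weights[0] == pytest.approx(0.5)
        assert weights[-1] == pytest.approx(2 / 3)

    def test_out_of_range_inputs_error(self):
        with pytest.raises(ValueError, match="outside"):
            combined_probability(1.2, 0.5, 0.5)


class TestDockingEnergyTable:
    def test_e_mlig_is_table_minimum_and_best_prob_is_one(self):
        table = DockingEnergyTable(
            "T", {"a": -120.0, "b": -90.0, "c": -150.0}, e_inib=-100.0)
        assert table.e_mlig == -150.0
        assert docking_probability(table.entries["c"], table.e_mlig) == 1.0

    def test_nonnegative_best_score_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            DockingEnergyTable("T", {"a": 5.0, "b": 10.0}, e_inib=-50.0)


class TestFuse:
    ids = ["a", "b"]
    p_act = {"a": 0.8, "b": 0.3}
    dom = {"a": True, "b": False}

    def table(self):
        return DockingEnergyTable("X", {"a": -150.0, "b": -80.0}, e_inib=-100.0)

    def test_combined_target_gets_fused_probability(self):
        cfg = TargetConfig("X")
        recs = fuse(self.ids, cfg, p_activity=self.p_act, docking=self.table(),
                    in_domain=self.dom, esp=0.8)
        assert recs[0].prob_comb == pytest.approx(
            combined_probability(1.0, 0.8, 0.8))
        assert recs[1].in_domain is False

    def test_qsar_only_target_keeps_p_activity(self):
        cfg = TargetConfig("X", has_docking=False)
        recs = fuse(self.ids, cfg, p_activity=self.p_act, in_domain=self.dom)
        assert recs[0].prob_comb is None
        assert recs[0].p_activity == 0.8 and recs[0].prob_dc is None

    def test_docking_only_target_keeps_prob_dc(self):
        cfg = TargetConfig("X", has_qsar=False)
        recs = fuse(self.ids, cfg, docking=self.table())
        assert recs[0].prob_dc == 1.0
        assert recs[0].p_activity is None and recs[0].prob_comb is None

    def test_missing_model_inputs_error(self):
        with pytest.raises(ValueError, match="docking"):
            fuse(self.ids, TargetConfig("X"), p_activity=self.p_act, esp=0.5)
        with pytest.raises(ValueError, match="esp"):
            fuse(self.ids, TargetConfig("X"), p_activity=self.p_act,
                 docking=self.table())
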