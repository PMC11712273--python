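"""Scenario composition, sweeps and the full factorial."""

import numpy as np
import pytest

from spareshare import PolicySpec, factorial_run, run_scenario, sweep_policy
from spareshare.scenarios import SWEEP_COLUMNS


class TestRunScenario:
    def test_sharing_equal_composition(self, t4):
        out = run_scenario(t4, PolicySpec("sharing", "equal", "grassland", 40.0))
        assert out.gain_in_occupancy == pytest.approx(0.24)
        np.testing.assert_allclose(out.delta_food, np.full(41, -150.0))
        assert out.leakage_npv > 0
        assert out.spared_area_ha == pytest.approx(40.0)

    def test_sparing_cost_min_composition(self, t4):
        out = run_scenario(t4, PolicySpec("sparing", "cost_min", "grassland", 0.05))
        assert out.gain_in_occupancy == pytest.approx(0.3 * 500 / 700)
        np.testing.assert_allclose(out.delta_food, np.zeros(41), atol=1e-9)
        assert out.leakage_npv == pytest.approx(0.0, abs=1e-9)
        assert out.spared_area_ha == pytest.approx(500 / 7)

    def test_three_compartment_composition(self, t4):
        out = run_scenario(t4, PolicySpec("sparing3c", "cost_min", "grassland", 0.05))
        pure = run_scenario(t4, PolicySpec("sparing", "cost_min", "grassland", 0.05))
        assert out.spared_area_ha == pytest.approx(pure.spared_area_ha, rel=1e-12)
        assert out.gain_in_occupancy == pytest.approx(4 / 21)
        assert out.gain_in_occupancy < pure.gain_in_occupancy
        np.testing.assert_allclose(out.delta_food, np.full(41, 2.5))
        assert out.lowyield_area_ha == pytest.approx(out.spared_area_ha / 3, rel=1e-9)

    def test_selection_and_richness_maps_consistent(self, t4):
        out = run_scenario(t4, PolicySpec("sharing", "cost_min", "grassland", 40.0))
        np.testing.assert_array_equal(out.selection_map, [1, 0, 0, 0])
        assert out.richness_map.sum() == pytest.approx(out.gain_in_occupancy, abs=1e-12)

    @pytest.mark.parametrize(
        "policy",
        [
            PolicySpec("rewilding", "equal", "grassland", 1.0),
            PolicySpec("sharing", "cheapest", "grassland", 1.0),
            PolicySpec("sharing", "equal", "moorland", 1.0),
            PolicySpec("sharing", "equal", "grassland", 1e9),
            PolicySpec("sparing", "equal", "grassland", -0.01),
        ],
    )
    def test_invalid_policies_rejected(self, t4, policy):
        with pytest.raises(ValueError):
            run_scenario(t4, policy)


class TestSweepPolicy:
    def test_equal_sparing_closed_form_curve(self, t4):
        grid = [0.01, 0.02, 0.03, 0.04, 0.05]
        table = sweep_policy(t4, "sparing", "equal", "grassland", grid)
        expected = [400 * g / (1 + g) for g in grid]
        np.testing.assert_allclose(table["spared_area_ha"], expected, rtol=1e-12)

    def test_single_point_sweep_matches_run(self, t4):
        table = sweep_policy(t4, "sharing", "equal", "grassland", [40.0])
        out = run_scenario(t4, PolicySpec("sharing", "equal", "grassland", 40.0))
        assert len(table) == 1
        row = table.iloc[0]
        assert row["gain_in_occupancy"] == pytest.approx(out.gain_in_occupancy)
        assert row["leakage_npv"] == pytest.approx(out.leakage_npv)

    def test_sharing_gain_curve(self, t4):
        table = sweep_policy(t4, "sharing", "equal", "grassland", [0.0, 40.0])
        np.testing.assert_allclose(table["gain_in_occupancy"], [0.0, 0.24], atol=1e-12)

    def test_column_contract(self, t4):
        table = sweep_policy(t4, "sparing", "equal", "grassland", [0.05])
        assert list(table.columns) == SWEEP_COLUMNS

    def test_toy_sparing_dominance(self, t4):
        grid = [0.01, 0.03, 0.05]
        gains = {
            rule: sweep_policy(t4, "sparing", rule, "grassland", grid)["gain_in_occupancy"].to_numpy()
            for rule in ("equal", "cost_min", "biodiv_max")
        }
        assert (gains["biodiv_max"] >= gains["cost_min"] - 1e-12).all()
        assert (gains["cost_min"] >= gains["equal"] - 1e-12).all()


class TestFactorialRun:
    def test_row_count_and_determinism(self, t4):
        sharing = [20.0, 40.0]
        uplift = [0.02, 0.05]
        a = factorial_run(t4, sharing, uplift)
        b = factorial_run(t4, sharing, uplift)
        assert len(a) == 18 * 2
        assert a.equals(b)

    def test_spared_area_identity_between_sparing_variants(self, t4):
        table = factorial_run(t4, [40.0], [0.05]).set_index(["strategy", "rule", "habitat"])
        for rule in ("equal", "cost_min", "biodiv_max"):
            for habitat in ("grassland", "woodland"):
                pure = table.loc[("sparing", rule, habitat), "spared_area_ha"]
                three_c = table.loc[("sparing3c", rule, habitat), "spared_area_ha"]
                assert three_c == pytest.approx(pure, abs=1e-12)

    def test_leakage_signs_by_strategy(self, t4):
        table = factorial_run(t4, [40.0], [0.05])
        sharing = table[table.strategy == "sharing"]
        sparing = table[table.strategy != "sharing"]
        assert (sharing["leakage_npv"] > 0).all()
        np.testing.assert_allclose(sparing["leakage_npv"], 0.0, atol=1e-9)

    def test_rows_ordered_lexicographically(self, t4):
        table = factorial_run(t4, [20.0, 40.0], [0.02, 0.05])
        keys = list(zip(table.strategy, table.rule, table.habitat, table.parameter))
        assert keys == sorted(keys)
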