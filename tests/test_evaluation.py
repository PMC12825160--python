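"""Metrics, the 36-scenario grid, and the Monte Carlo driver."""

import numpy as np
import pandas as pd
import pytest

from hdmediate import (
    bias,
    build_scenario_grid,
    run_monte_carlo,
    sensitivity,
    specificity,
    summarize,
)


class TestMetrics:
    @pytest.mark.parametrize(
        "selected,true,expected",
        [({1, 2}, {1, 2, 3, 4}, 0.5), (set(), {1, 2}, 0.0), ({5, 6}, {5, 6}, 1.0)],
    )
    def test_sensitivity(self, selected, true, expected):
        assert sensitivity(selected, true) == expected

    def test_sensitivity_empty_truth_raises(self):
        with pytest.raises(ValueError):
            sensitivity({1}, set())

    @pytest.mark.parametrize(
        "selected,true,p,expected",
        [
            (set(), {0, 1}, 10, 1.0),
            (set(range(2, 10)), {0, 1}, 10, 0.0),
            ({0, 4}, {0, 1, 2, 3}, 200, 195 / 196),
        ],
    )
    def test_specificity(self, selected, true, p, expected):
        assert specificity(selected, true, p) == pytest.approx(expected)

    def test_specificity_all_true_raises(self):
        with pytest.raises(ValueError):
            specificity(set(), set(range(5)), 5)

    @pytest.mark.parametrize(
        "estimates,truth,expected",
        [([5.2, 5.6], 5.4, 0.0), ([0, 0, 0], 0.04, -0.04), ([1.7], 1.7, 0.0)],
    )
    def test_bias(self, estimates, truth, expected):
        assert bias(estimates, truth) == pytest.approx(expected)

    def test_bias_empty_raises(self):
        with pytest.raises(ValueError):
            bias([], 0.0)


class TestScenarioGrid:
    def test_cardinality_and_structure(self):
        grid = build_scenario_grid(200, base_seed=0)
        assert len(grid.scenarios) == 36
        for cfg in grid:
            assert cfg.correlated == (cfg.scenario_id <= 18)
            block_pos = (cfg.scenario_id - 1) % 18
            assert cfg.beta == (0.1 if block_pos < 9 else 0.3)
        assert grid[1].correlated and grid[1].beta == 0.1
        assert not grid[36].correlated and grid[36].beta == 0.3
        # scenarios 25 and 34: smallest n, 10% true (the p > n cells)
        assert grid[25].n == 250 and grid[25].prop_true == 0.10
        assert grid[34].n == 250 and grid[34].prop_true == 0.10

    def test_determinism(self):
        g1 = build_scenario_grid(400, base_seed=5)
        g2 = build_scenario_grid(400, base_seed=5)
        assert g1.scenarios == g2.scenarios

    def test_p_level_too_small(self):
        with pytest.raises(ValueError):
            build_scenario_grid(1)


class TestRunMonteCarlo:
    def test_single_row_cardinality(self):
        grid = build_scenario_grid(40, base_seed=2)
        rows = run_monte_carlo([grid[20]], n_reps=1, methods=("MITM",))
        assert len(rows) == 1
        assert rows.loc[0, "method"] == "MITM"

    def test_bitwise_determinism(self):
        grid = build_scenario_grid(40, base_seed=2)
        sub = [grid[1], grid[20]]
        a = run_monte_carlo(sub, n_reps=3, methods=("MITM",))
        b = run_monte_carlo(sub, n_reps=3, methods=("MITM",))
        pd.testing.assert_frame_equal(a, b)

    def test_cie_bias_structurally_absent_when_correlated(self):
        grid = build_scenario_grid(40, base_seed=2)
        corr_ids = [1, 10, 18]
        rows = run_monte_carlo([grid[i] for i in corr_ids], n_reps=2,
                               methods=("MITM",))
        assert rows["cie_bias"].isna().all()
        assert rows["cie_bias_all"].isna().all()

    def test_metric_bounds(self):
        grid = build_scenario_grid(40, base_seed=2)
        rows = run_monte_carlo([grid[10], grid[28]], n_reps=3,
                               methods=("MITM", "HIMA"))
        ok = rows[~rows["failed"]]
        assert ok["sensitivity"].between(0, 1).all()
        assert ok["specificity"].between(0, 1).all()

    def test_unknown_method_rejected(self):
        grid = build_scenario_grid(40, base_seed=2)
        with pytest.raises(ValueError):
            run_monte_carlo([grid[1]], n_reps=1, methods=("MAGIC",))


class TestSummarize:
    def _rows(self, sens_values):
        return pd.DataFrame(
            {
                "scenario_id": 19, "method": "MITM",
                "replicate": range(len(sens_values)),
                "tie_est": 0.3, "tie_true": 0.4,
                "cie_bias": 0.0, "cie_bias_all": 0.0,
                "sensitivity": sens_values, "specificity": 1.0,
                "n_selected": 2, "failed": False,
            }
        )

    def test_identical_rows_zero_sd(self):
        s = summarize(self._rows([0.5, 0.5, 0.5]))
        assert s.loc[0, "sensitivity_sd"] == 0.0
        assert s.loc[0, "tie_bias"] == pytest.approx(-0.1)

    def test_single_row_mean(self):
        s = summarize(self._rows([0.25]))
        assert s.loc[0, "sensitivity_mean"] == 0.25

    def test_sample_sd_convention(self):
        s = summarize(self._rows([0.0, 1.0]))
        assert s.loc[0, "sensitivity_mean"] == 0.5
        assert s.loc[0, "sensitivity_sd"] == pytest.approx(np.sqrt(0.5))

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            summarize(pd.DataFrame())
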