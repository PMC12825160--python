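"""Data-generating process: correlation matrices, datasets, estimands."""

import numpy as np
import pytest

from hdmediate import (
    CorrelationModel,
    ScenarioConfig,
    make_correlation_matrix,
    simulate_dataset,
    true_effects,
)


class TestScenarioConfig:
    def test_n_true_round_half_up(self):
        cfg = ScenarioConfig(0, 250, 200, 0.02, 0.1, False)
        assert cfg.n_true == 4
        assert ScenarioConfig(0, 250, 250, 0.05, 0.1, False).n_true == 13  # 12.5 up

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(n=5),  # n too small
            dict(beta=-0.1),
            dict(prop_true=1.5),
            dict(prop_true=0.001),  # n_true = 0
            dict(scenario_id=3, correlated=False),  # id 1-18 must be correlated
            dict(scenario_id=20, correlated=True),
        ],
    )
    def test_invalid_configs_raise(self, kwargs):
        base = dict(scenario_id=0, n=250, p=200, prop_true=0.05, beta=0.1,
                    correlated=False)
        base.update(kwargs)
        if "correlated" in kwargs and kwargs["correlated"]:
            base["correlated"] = True
        with pytest.raises(ValueError):
            ScenarioConfig(**base)


class TestCorrelationMatrix:
    def test_p1_is_identity(self):
        assert np.array_equal(make_correlation_matrix(1, 42).matrix, [[1.0]])

    def test_small_matrix_invariants(self):
        cm = make_correlation_matrix(3, 5)
        m = cm.matrix
        assert m.shape == (3, 3)
        assert np.allclose(m, m.T)
        assert np.allclose(np.diag(m), 1.0)
        assert np.linalg.eigvalsh(m)[0] > 0

    def test_p200_range_and_definiteness(self):
        # oracle: full eigendecomposition + elementwise scan
        cm = make_correlation_matrix(200, 11, target_range=(-0.42, 0.45))
        off = cm.matrix[np.triu_indices(200, 1)]
        assert off.min() > -0.45 and off.max() < 0.48
        assert np.linalg.eigvalsh(cm.matrix)[0] > 0
        # the generator is tuned so realized extremes approach the target
        assert off.min() < -0.30 and off.max() > 0.35

    def test_deterministic(self):
        a = make_correlation_matrix(50, 3).matrix
        b = make_correlation_matrix(50, 3).matrix
        assert np.array_equal(a, b)

    def test_invalid_p(self):
        with pytest.raises(ValueError):
            make_correlation_matrix(0, 1)

    def test_validation_rejects_non_pd(self):
        bad = np.array([[1.0, 0.99], [0.99, 1.0]])
        bad[0, 1] = bad[1, 0] = 1.5
        with pytest.raises(ValueError):
            CorrelationModel(bad, 0)


class TestSimulateDataset:
    def test_beta_zero_null(self, null_config):
        ds = simulate_dataset(null_config, None, 0)
        assert ds.true_tie == 0.0
        # true-mediator columns distributionally identical to the rest
        assert abs(ds.M[:, ds.true_idx].mean() - ds.M[:, 10:].mean()) < 0.2

    def test_mediator_slopes_large_n(self, big_independent):
        # oracle: direct least squares of each column on E
        ds = big_independent
        X = np.column_stack([np.ones(ds.n), ds.E])
        slopes = np.linalg.lstsq(X, ds.M, rcond=None)[0][1]
        assert np.allclose(slopes[ds.true_idx], 0.3, atol=0.02)
        non_true = np.setdiff1d(np.arange(ds.p), ds.true_idx)
        assert np.allclose(slopes[non_true], 0.0, atol=0.02)

    def test_direct_effect_large_n(self, big_independent):
        # coefficient of E in O ~ E + true mediators + confounders is 0.8
        ds = big_independent
        X = np.column_stack([np.ones(ds.n), ds.E, ds.M[:, ds.true_idx], ds.C])
        coef = np.linalg.lstsq(X, ds.O, rcond=None)[0]
        assert coef[1] == pytest.approx(0.8, abs=0.02)

    def test_bitwise_determinism(self, null_config):
        a = simulate_dataset(null_config, None, 3)
        b = simulate_dataset(null_config, None, 3)
        assert np.array_equal(a.M, b.M) and np.array_equal(a.O, b.O)
        c = simulate_dataset(null_config, None, 4)
        assert not np.array_equal(a.M, c.M)

    def test_corr_mismatch_raises(self):
        cfg = ScenarioConfig(0, 100, 30, 0.1, 0.1, True)
        corr = make_correlation_matrix(20, 0)
        with pytest.raises(ValueError):
            simulate_dataset(cfg, corr, 0)
        with pytest.raises(ValueError):
            simulate_dataset(cfg, None, 0)

    def test_sample_correlation_converges(self):
        # correlated case, beta=0: sample corr of M -> corr.matrix
        cfg = ScenarioConfig(0, 50_000, 50, 0.04, 0.0, True)
        corr = make_correlation_matrix(50, 9)
        ds = simulate_dataset(cfg, corr, 0)
        dev = np.abs(np.corrcoef(ds.M.T) - corr.matrix).max()
        assert dev < 0.03

    def test_mean_shift_preserves_covariance(self):
        # residualizing the exposure out of shifted columns recovers the
        # unshifted covariance structure
        cfg1 = ScenarioConfig(0, 20_000, 20, 0.1, 0.3, True, base_seed=5)
        cfg0 = ScenarioConfig(0, 20_000, 20, 0.1, 0.0, True, base_seed=5)
        corr = make_correlation_matrix(20, 5)
        ds1 = simulate_dataset(cfg1, corr, 0)
        ds0 = simulate_dataset(cfg0, corr, 0)
        X = np.column_stack([np.ones(ds1.n), ds1.E])
        resid = ds1.M - X @ np.linalg.lstsq(X, ds1.M, rcond=None)[0]
        dev = np.abs(np.cov(resid.T) - np.cov(ds0.M.T)).max()
        assert dev < 0.05


class TestTrueEffects:
    @pytest.mark.parametrize(
        "p,prop,beta,expected_tie,expected_ntrue",
        [
            (600, 0.10, 0.3, 5.4, 60),
            (200, 0.02, 0.1, 0.04, 4),
            (200, 0.05, 0.0, 0.0, 10),
        ],
    )
    def test_closed_form(self, p, prop, beta, expected_tie, expected_ntrue):
        cfg = ScenarioConfig(0, 500, p, prop, beta, False)
        tie, cie = true_effects(cfg)
        assert tie == pytest.approx(expected_tie)
        assert len(cie) == expected_ntrue
        assert np.allclose(cie, beta**2)

    def test_correlation_does_not_change_estimand(self):
        ind = ScenarioConfig(0, 500, 100, 0.05, 0.3, False)
        cor = ScenarioConfig(0, 500, 100, 0.05, 0.3, True)
        assert true_effects(ind)[0] == true_effects(cor)[0]


class TestExportRoundTrip:
    def test_frame_round_trip(self, small_independent):
        ds = small_independent
        frame = ds.to_frame()
        assert list(frame.columns[:3]) == ["C_1", "C_2", "E"]
        assert frame.columns[-1] == "O"
        back = type(ds).from_frame(frame, true_idx=ds.true_idx, beta=ds.beta)
        assert np.array_equal(back.M, ds.M)
        assert np.array_equal(back.O, ds.O)
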