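"""HIMA: SIS screening, MCP thresholding/fitting, joint significance."""

import numpy as np
import pytest
from sklearn.linear_model import Lasso

from hdmediate import ScenarioConfig, simulate_dataset
from hdmediate.hima import (
    Hima,
    default_screen_size,
    hima_mediate,
    mcp_fit,
    mcp_threshold,
    sis_screen,
)


class TestSisScreen:
    def test_keeps_all_when_p_small(self):
        rng = np.random.default_rng(0)
        M = rng.standard_normal((50, 8))
        res = sis_screen(M, rng.standard_normal(50), d=20)
        assert len(res.kept) == 8

    def test_exact_copy_ranks_first(self):
        rng = np.random.default_rng(1)
        M = rng.standard_normal((100, 12))
        O = M[:, 7].copy()
        res = sis_screen(M, O, d=3)
        assert res.ranking[0] == 7
        # oracle: direct correlation computation
        cors = np.abs([np.corrcoef(M[:, j], O)[0, 1] for j in range(12)])
        assert np.argsort(-cors)[0] == 7

    def test_zero_variance_column_ranks_last(self):
        rng = np.random.default_rng(2)
        M = rng.standard_normal((60, 5))
        M[:, 2] = 1.0
        res = sis_screen(M, rng.standard_normal(60), d=5)
        assert res.ranking[-1] == 2
        assert res.statistic[2] == 0.0

    def test_default_screen_size_formula(self):
        # floor(2n / ln n) at n=500 is 160
        assert default_screen_size(500, p=300, n_confounders=2) == 160
        assert default_screen_size(500, p=100, n_confounders=2) == 100  # capped at p
        assert default_screen_size(30, p=300, n_confounders=2) == 17  # floor(60/3.401)


class TestMcpThreshold:
    @pytest.mark.parametrize(
        "z,lam,gamma,expected",
        [
            (1.0, 0.5, 3.0, 0.75),  # interior firm-threshold region
            (2.0, 0.5, 3.0, 2.0),  # beyond gamma*lambda: unpenalised
            (0.3, 0.5, 3.0, 0.0),  # dead zone
            (-1.0, 0.5, 3.0, -0.75),
            (1.0, 0.0, 3.0, 1.0),
        ],
    )
    def test_closed_form(self, z, lam, gamma, expected):
        assert mcp_threshold(z, lam, gamma) == pytest.approx(expected)

    def test_gamma_at_most_one_raises(self):
        with pytest.raises(ValueError):
            mcp_threshold(1.0, 0.5, 1.0)

    def test_matches_grid_minimization(self):
        # oracle: grid search of 0.5 (z - t)^2 + MCP penalty(t)
        def penalty(t, lam, gamma):
            a = abs(t)
            return lam * a - a**2 / (2 * gamma) if a <= gamma * lam \
                else gamma * lam**2 / 2

        lattice = np.linspace(-4, 4, 80_001)
        for z in (-2.2, -0.9, 0.2, 0.6, 1.4, 3.1):
            for lam in (0.1, 0.5, 1.0):
                for gamma in (1.5, 3.0, 10.0):
                    vals = 0.5 * (z - lattice) ** 2 + np.array(
                        [penalty(t, lam, gamma) for t in lattice]
                    )
                    t_star = lattice[np.argmin(vals)]
                    assert mcp_threshold(z, lam, gamma) == pytest.approx(
                        t_star, abs=1e-3
                    )


class TestMcpFit:
    def test_orthogonal_null_signal(self):
        rng = np.random.default_rng(3)
        X = np.linalg.qr(rng.standard_normal((200, 5)))[0] * np.sqrt(200)
        y = rng.standard_normal(200)
        y -= X @ np.linalg.lstsq(X, y, rcond=None)[0]  # orthogonal to columns
        fit = mcp_fit(X, y)
        assert np.allclose(fit.coefficients, 0.0, atol=1e-8)

    def test_orthogonal_design_support_recovery(self):
        rng = np.random.default_rng(4)
        X = np.linalg.qr(rng.standard_normal((2000, 2)))[0] * np.sqrt(2000)
        y = 1.0 * X[:, 0] + 0.05 * rng.standard_normal(2000)
        fit = mcp_fit(X, y)
        assert fit.support.tolist() == [0]
        assert fit.coefficients[0] == pytest.approx(1.0, abs=0.05)

    def test_large_gamma_is_lasso(self):
        # MCP -> Lasso limit; oracle = scikit-learn coordinate descent
        rng = np.random.default_rng(5)
        X = rng.standard_normal((300, 15))
        X = (X - X.mean(0)) / X.std(0)
        y = X[:, :3] @ np.array([1.0, -0.5, 0.8]) + rng.standard_normal(300)
        y -= y.mean()
        fit = mcp_fit(X, y, lambda_grid=np.geomspace(1.0, 0.1, 30), gamma=1e6)
        ref = Lasso(alpha=fit.lambda_, fit_intercept=False, tol=1e-12,
                    max_iter=100_000).fit(X, y).coef_
        assert np.allclose(fit.coefficients, ref, atol=1e-4)

    def test_tiny_lambda_is_ols(self):
        rng = np.random.default_rng(6)
        X = rng.standard_normal((100, 6))
        y = rng.standard_normal(100)
        fit = mcp_fit(X, y, lambda_grid=np.array([1e-3, 1e-10]))
        ref = np.linalg.lstsq(X, y, rcond=None)[0]
        assert np.allclose(fit.coefficients, ref, atol=1e-6)

    def test_invalid_inputs(self):
        X = np.eye(4)
        y = np.ones(4)
        with pytest.raises(ValueError):
            mcp_fit(X, y, gamma=0.5)
        with pytest.raises(ValueError):
            mcp_fit(X, y, lambda_grid=np.array([0.1, 0.2]))  # not decreasing


class TestHimaMediate:
    def test_noiseless_identifiability(self):
        # y exactly linear in 2 mediators, mediators exactly linear in E
        rng = np.random.default_rng(7)
        n, p = 300, 10
        E = rng.standard_normal(n)
        C = rng.standard_normal((n, 2))
        M = rng.standard_normal((n, p)) * 0.4
        M[:, 3] = 0.9 * E + 0.3 * rng.standard_normal(n)
        M[:, 6] = -0.7 * E + 0.5 * rng.standard_normal(n)
        O = 2.0 * M[:, 3] + 1.5 * M[:, 6]  # outcome exactly linear, no noise
        ds = type("DS", (), {"O": O, "M": M, "E": E, "C": C})()
        res = hima_mediate(ds, alpha=0.05)
        assert set(res.selected.tolist()) == {3, 6}
        det = res.details
        assert det.loc[3, "b_coef"] == pytest.approx(2.0, abs=1e-6)
        assert det.loc[6, "b_coef"] == pytest.approx(1.5, abs=1e-6)

    def test_pipeline_monotonicity(self, small_independent):
        res = hima_mediate(small_independent)
        screen = res.extras["screen"]
        support = res.extras["support"]
        assert set(res.selected.tolist()) <= set(support.tolist())
        assert set(support.tolist()) <= set(screen.kept.tolist())

    def test_recovers_true_mediators_easy_setting(self, small_independent):
        res = hima_mediate(small_independent)
        assert set(res.selected.tolist()) == set(small_independent.true_idx.tolist())
        assert np.allclose(res.cie, 0.09, atol=0.05)

    def test_explicit_d_respected(self, small_independent):
        res = hima_mediate(small_independent, d=12)
        assert len(res.extras["screen"].kept) == 12
        with pytest.raises(ValueError):
            Hima.from_dataset(small_independent).fit(d=10_000)
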