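"""B-spline basis construction and stochastic multiple imputation."""

import numpy as np
import pytest

from dlopanel import BSplineImputer, multiply_impute
from dlopanel.impute import build_basis, fit_spline, impute_once


class TestBasis:
    def test_partition_of_unity(self):
        weeks = np.arange(1, 98, dtype=float)
        basis = build_basis(weeks, K=10)
        assert np.allclose(basis.sum(axis=1), 1.0, atol=1e-12)

    def test_column_count_is_K_plus_degree_plus_1(self):
        weeks = np.arange(1, 98, dtype=float)
        assert build_basis(weeks, K=5).shape == (97, 9)
        assert build_basis(weeks, K=10).shape == (97, 14)
        assert build_basis(weeks, K=1, degree=1).shape == (97, 3)

    def test_linear_hat_basis_interpolates(self):
        # degree 1, one interior knot at 2: columns are hat functions
        basis = build_basis(np.array([1.0, 2.0, 3.0]), K=1, degree=1)
        assert np.allclose(basis, np.eye(3), atol=1e-12)

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            build_basis(np.arange(1, 10, dtype=float), K=0)
        with pytest.raises(ValueError):
            build_basis(np.array([1.0, 2.0]), K=2)  # too few distinct weeks


class TestFitSpline:
    def test_exact_cubic_has_zero_residual(self):
        t = np.arange(1, 31, dtype=float)
        values = 0.2 + 0.01 * t - 0.003 * t**2 + 0.0001 * t**3
        values[[3, 7, 12, 20]] = np.nan
        fit = fit_spline(values, K=4)
        assert fit.resid_sd < 1e-8
        grid_pred = fit.predict(np.arange(1, 31))
        truth = 0.2 + 0.01 * t - 0.003 * t**2 + 0.0001 * t**3
        assert np.allclose(grid_pred, truth, atol=1e-7)

    def test_constant_series_predicted_exactly(self):
        values = np.full(40, 0.5)
        values[10:20:2] = np.nan
        fit = fit_spline(values, K=5)
        assert np.allclose(fit.predict(np.arange(1, 41)), 0.5, atol=1e-9)

    def test_noise_sd_recovered(self):
        # ~5 knots per oscillation period: lack-of-fit negligible, so the
        # residual SD estimates the measurement-noise SD
        rng = np.random.default_rng(3)
        t = np.arange(1, 201, dtype=float)
        values = 0.5 + 0.1 * np.sin(2 * np.pi * t / 40) + rng.normal(0, 0.02, 200)
        fit = fit_spline(values, K=25)
        assert abs(fit.resid_sd - 0.02) / 0.02 < 0.15

    def test_K_reduced_with_warning_when_data_sparse(self):
        values = np.full(50, np.nan)
        values[[0, 6, 13, 20, 27, 34, 41, 49]] = 0.5
        with pytest.warns(UserWarning, match="K reduced"):
            fit = fit_spline(values, K=15)
        assert fit.K < 15
        assert fit.n_basis < fit.t_max

    def test_too_few_points_rejected(self):
        values = np.full(10, np.nan)
        values[[0, 5, 9]] = 0.3
        with pytest.raises(ValueError, match=">= 4"):
            fit_spline(values, K=3)

    def test_quantile_knots_lie_inside_observed_range(self):
        values = np.full(60, np.nan)
        values[np.arange(0, 60, 3)] = np.sin(np.arange(0, 60, 3) / 5.0)
        fit = fit_spline(values, K=6)
        assert (fit.knot_locations > 1).all()
        assert (fit.knot_locations < 60).all()
        assert np.all(np.diff(fit.knot_locations) > 0)


class TestImputeOnce:
    def test_observed_entries_untouched(self, gappy_sine_panel):
        person = gappy_sine_panel.persons[0]
        values = gappy_sine_panel.person_values(person)
        fit = fit_spline(values, K=8, person_id=person)
        out = impute_once(fit, values, np.random.default_rng(0))
        obs = ~np.isnan(values)
        assert np.array_equal(out[obs], values[obs])
        assert not np.isnan(out).any()

    def test_monte_carlo_mean_matches_deterministic_prediction(self):
        rng = np.random.default_rng(5)
        t = np.arange(1, 61, dtype=float)
        values = 0.5 + 0.1 * np.sin(2 * np.pi * t / 40) + rng.normal(0, 0.02, 60)
        values[29] = np.nan
        fit = fit_spline(values, K=6)
        draws = np.array(
            [impute_once(fit, values, np.random.default_rng(i))[29] for i in range(10_000)]
        )
        pred = fit.predict([30])[0]
        draw_se = draws.std(ddof=1) / np.sqrt(len(draws))
        assert abs(draws.mean() - pred) < 3 * draw_se

    def test_draw_variance_at_least_residual_variance(self):
        rng = np.random.default_rng(6)
        t = np.arange(1, 61, dtype=float)
        values = 0.5 + 0.1 * np.sin(2 * np.pi * t / 40) + rng.normal(0, 0.02, 60)
        values[29] = np.nan
        fit = fit_spline(values, K=6)
        draws = np.array(
            [impute_once(fit, values, np.random.default_rng(i))[29] for i in range(2_000)]
        )
        # total draw variance = parameter variance + residual variance
        assert draws.var(ddof=1) > 0.8 * fit.resid_sd**2

    def test_coef_draw_only_collapses_as_noise_vanishes(self):
        # exact cubic: resid_sd ~ 0 and coef_cov ~ 0, so completions coincide
        t = np.arange(1, 41, dtype=float)
        values = 0.3 + 0.002 * t**2 - 0.00003 * t**3
        values[[5, 15, 25]] = np.nan
        fit = fit_spline(values, K=4)
        a = impute_once(fit, values, np.random.default_rng(1))
        b = impute_once(fit, values, np.random.default_rng(2))
        assert np.allclose(a, b, atol=1e-6)

    def test_clip_bounds_imputed_values_only(self):
        rng = np.random.default_rng(11)
        values = np.full(60, np.nan)
        values[::2] = rng.normal(0.01, 0.05, 30)  # noisy series hugging 0
        miss = np.isnan(values)
        fit = fit_spline(values, K=3)
        raw = impute_once(fit, values, np.random.default_rng(0))
        assert (raw[miss] < 0).any()  # unclipped draws do cross the bound
        out = impute_once(fit, values, np.random.default_rng(0), clip=True)
        assert (out[miss] >= 0).all() and (out[miss] <= 1).all()
        assert np.array_equal(out[~miss], values[~miss])  # observed untouched


class TestMultipleImputation:
    def test_m_panels_identical_grid_distinct_fillins(self, gappy_sine_panel):
        imputed = multiply_impute(gappy_sine_panel, K=8, m=5, seed=1)
        assert imputed.m == 5
        miss = gappy_sine_panel.frame["value"].isna().to_numpy()
        filled = np.stack([p.frame["value"].to_numpy()[miss] for p in imputed.panels])
        # observed part shared, missing part varies between imputations
        for p in imputed.panels:
            assert p.is_complete
            vals = p.frame["value"].to_numpy()
            assert np.array_equal(
                vals[~miss], gappy_sine_panel.frame["value"].to_numpy()[~miss]
            )
        assert (filled.std(axis=0) > 0).all()

    def test_reproducible_given_seed(self, gappy_sine_panel):
        a = multiply_impute(gappy_sine_panel, K=8, m=3, seed=9)
        b = multiply_impute(gappy_sine_panel, K=8, m=3, seed=9)
        c = multiply_impute(gappy_sine_panel, K=8, m=3, seed=10)
        assert all(x == y for x, y in zip(a.panels, b.panels))
        assert any(x != y for x, y in zip(a.panels, c.panels))

    def test_person_subsets_reuse_identical_streams(self, gappy_sine_panel):
        # leave-one-person-out reruns must reuse the retained persons'
        # imputations exactly (per-person label-keyed streams)
        full = multiply_impute(gappy_sine_panel, K=8, m=3, seed=4)
        keep = gappy_sine_panel.persons[1:]
        sub = multiply_impute(gappy_sine_panel.subset(keep), K=8, m=3, seed=4)
        for pf, ps in zip(full.panels, sub.panels):
            assert pf.subset(keep) == ps

    def test_between_imputation_spread_grows_with_knots(self, gappy_sine_panel):
        # coefficient-draw variance only: the residual draw is K-independent
        # while the parameter spread grows with basis size
        miss = gappy_sine_panel.frame["value"].isna().to_numpy()
        spread = {}
        for K in (5, 8, 10, 15):
            imputed = multiply_impute(
                gappy_sine_panel, K=K, m=20, seed=2, coef_draw_only=True
            )
            filled = np.stack(
                [p.frame["value"].to_numpy()[miss] for p in imputed.panels]
            )
            spread[K] = float(filled.var(axis=0, ddof=1).mean())
        assert spread[5] < spread[8] < spread[10] < spread[15]

    def test_estimator_params_roundtrip(self):
        imp = BSplineImputer(n_knots=7, m=4, random_state=3)
        params = imp.get_params()
        assert params["n_knots"] == 7 and params["m"] == 4
        imp.set_params(n_knots=9)
        assert imp.get_params()["n_knots"] == 9

    def test_transform_requires_fit(self, gappy_sine_panel):
        with pytest.raises(RuntimeError, match="not fitted"):
            BSplineImputer().transform(gappy_sine_panel)
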