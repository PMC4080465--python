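"""Multilevel oscillator model: solver cross-checks, recovery, periods."""

import numpy as np
import pandas as pd
import pytest

from dlopanel import (
    DampedOscillatorModel,
    NonOscillatoryError,
    fit_model1,
    fit_model2,
    period_of_oscillation,
    period_weeks_rounded,
)
from dlopanel._reml import fit_lmm_two_slopes


def _random_slope_data(
    seed,
    n_groups=30,
    n_per=60,
    beta=(-0.5, 0.3),
    re_cov=((0.04, 0.01), (0.01, 0.0225)),
    sigma=0.5,
):
    """Derivative-table-shaped data with known random-slope structure."""
    rng = np.random.default_rng(seed)
    re_cov = np.asarray(re_cov)
    chol = np.linalg.cholesky(re_cov)
    rows = []
    for g in range(n_groups):
        b = chol @ rng.standard_normal(2)
        x = rng.standard_normal(n_per)
        xdot = rng.standard_normal(n_per)
        y = (
            (beta[0] + b[0]) * x
            + (beta[1] + b[1]) * xdot
            + rng.normal(0, sigma, n_per)
        )
        rows.append(
            pd.DataFrame(
                {
                    "person": f"G{g:03d}",
                    "center_week": np.arange(1, n_per + 1),
                    "x": x,
                    "xdot": xdot,
                    "xddot": y,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


class TestSolverOracle:
    def test_matches_statsmodels_mixedlm(self):
        sm = pytest.importorskip("statsmodels.api")
        derivs = _random_slope_data(0)
        ours = fit_model1(derivs)
        X = derivs[["x", "xdot"]].to_numpy()
        ref = sm.MixedLM(
            derivs["xddot"].to_numpy(),
            X,
            groups=derivs["person"].to_numpy(),
            exog_re=X,
        ).fit(reml=True)
        assert np.allclose(
            [ours.mu_eta, ours.mu_zeta], ref.fe_params, atol=1e-5
        )
        assert np.allclose(
            [ours.fixed["mu_eta"]["se"], ours.fixed["mu_zeta"]["se"]],
            ref.bse_fe,
            rtol=1e-3,
        )
        assert abs(ours.resid_sd - np.sqrt(ref.scale)) < 1e-4
        ref_cov = np.asarray(ref.cov_re)  # already in response units
        assert abs(ours.sd_eta - np.sqrt(ref_cov[0, 0])) < 1e-3
        assert abs(ours.sd_zeta - np.sqrt(ref_cov[1, 1])) < 1e-3

    def test_parameters_recovered_from_known_generator(self):
        derivs = _random_slope_data(1, n_groups=80, n_per=120)
        fit = fit_model1(derivs)
        assert abs(fit.mu_eta + 0.5) < 0.05
        assert abs(fit.mu_zeta - 0.3) < 0.05
        assert abs(fit.sd_eta - 0.2) / 0.2 < 0.5
        assert abs(fit.resid_sd - 0.5) / 0.5 < 0.05
        assert fit.converged

    def test_null_data_gives_null_effects(self):
        rng = np.random.default_rng(2)
        derivs = pd.DataFrame(
            {
                "person": np.repeat([f"G{i}" for i in range(20)], 40),
                "center_week": np.tile(np.arange(1, 41), 20),
                "x": rng.standard_normal(800),
                "xdot": rng.standard_normal(800),
                "xddot": rng.standard_normal(800),
            }
        )
        fit = fit_model1(derivs)
        for name in ("mu_eta", "mu_zeta"):
            assert abs(fit.fixed[name]["t"]) < 3.5

    def test_diagonal_covariance_forces_zero_correlation(self):
        derivs = _random_slope_data(3)
        y = derivs["xddot"].to_numpy()
        Z = derivs[["x", "xdot"]].to_numpy()
        res = fit_lmm_two_slopes(y, Z, Z, derivs["person"].to_numpy(), diagonal=True)
        assert res.re_corr == 0.0
        assert res.diagonal

    def test_permutation_invariance(self):
        derivs = _random_slope_data(4, n_groups=12, n_per=30)
        fit_a = fit_model1(derivs)
        shuffled = derivs.sample(frac=1.0, random_state=99).reset_index(drop=True)
        fit_b = fit_model1(shuffled)
        assert abs(fit_a.mu_eta - fit_b.mu_eta) < 1e-8
        assert abs(fit_a.mu_zeta - fit_b.mu_zeta) < 1e-8


class TestOscillatorRecovery:
    def test_exact_oscillator_derivatives_recover_eta(self):
        # per-person closed-form derivative triples of a pure oscillator
        rng = np.random.default_rng(5)
        rows = []
        for p in range(25):
            eta = rng.normal(-0.0245, 0.001)
            omega = np.sqrt(-eta)
            phase = rng.uniform(0, 2 * np.pi)
            t = np.arange(1, 81, dtype=float)
            x = 0.1 * np.sin(omega * t + phase)
            rows.append(
                pd.DataFrame(
                    {
                        "person": f"P{p:02d}",
                        "center_week": t,
                        "x": x,
                        "xdot": 0.1 * omega * np.cos(omega * t + phase),
                        "xddot": eta * x + rng.normal(0, 1e-5, len(t)),
                    }
                )
            )
        fit = fit_model1(pd.concat(rows, ignore_index=True))
        assert abs(fit.mu_eta + 0.0245) < 0.001
        assert abs(fit.mu_zeta) < 0.001

    def test_person_effects_structure(self):
        derivs = _random_slope_data(6)
        fit = fit_model1(derivs)
        pe = fit.person_effects
        assert list(pe.columns) == ["person", "eta", "zeta"]
        assert len(pe) == fit.n_persons == 30
        # BLUPs shrink toward the fixed effect: person means bracket it
        assert pe["eta"].min() < fit.mu_eta < pe["eta"].max()
        assert abs(pe["eta"].mean() - fit.mu_eta) < 0.05


def _covariate_moderated_data(seed, n_groups, b01=0.02):
    """Model-2 generator: eta_p = mu_eta + b01 * I_p + noise."""
    rng = np.random.default_rng(seed)
    rows, covars = [], []
    for g in range(n_groups):
        I_p = rng.normal(0.443, 0.167)
        S_p = rng.normal(0.0015, 0.0018)
        eta_p = -0.03 + b01 * I_p + rng.normal(0, 0.001)
        zeta_p = rng.normal(0, 0.002)
        x = rng.standard_normal(50)
        xdot = rng.standard_normal(50)
        y = eta_p * x + zeta_p * xdot + rng.normal(0, 0.01, 50)
        pid = f"P{g:03d}"
        rows.append(
            pd.DataFrame(
                {
                    "person": pid,
                    "center_week": np.arange(1, 51),
                    "x": x,
                    "xdot": xdot,
                    "xddot": y,
                }
            )
        )
        covars.append({"person": pid, "intercept": I_p, "slope": S_p})
    return pd.concat(rows, ignore_index=True), pd.DataFrame(covars)


class TestModel2:
    def test_planted_covariate_effect_recovered(self):
        derivs, covars = _covariate_moderated_data(7, n_groups=300)
        fit = fit_model2(derivs, covars)
        assert fit.model == 2
        assert set(fit.fixed) == {"mu_eta", "mu_zeta", "b01", "b02", "b11", "b12"}
        assert abs(fit.fixed["b01"]["est"] - 0.02) / 0.02 < 0.15
        assert abs(fit.fixed["b01"]["t"]) > 2

    def test_person_effects_use_linear_predictor(self):
        derivs, covars = _covariate_moderated_data(8, n_groups=40)
        fit = fit_model2(derivs, covars)
        # person-level eta = mu_eta + b01*I + b02*S + BLUP; check the fixed
        # part arithmetic through the stored covariates
        f = fit.fixed
        lin = (
            f["mu_eta"]["est"]
            + f["b01"]["est"] * covars["intercept"].to_numpy()
            + f["b02"]["est"] * covars["slope"].to_numpy()
        )
        blup = fit.person_effects["eta"].to_numpy() - lin
        assert abs(blup.mean()) < 0.005  # BLUPs roughly centred

    def test_missing_covariates_rejected(self):
        derivs, covars = _covariate_moderated_data(9, n_groups=10)
        with pytest.raises(ValueError, match="requires per-person covariates"):
            DampedOscillatorModel(model=2).fit(derivs)
        with pytest.raises(ValueError, match="missing covariates"):
            fit_model2(derivs, covars.iloc[:-1])


class TestPeriodArithmetic:
    def test_printed_estimate_examples(self):
        assert round(period_of_oscillation(-0.0269, -0.0008).lambda_weeks, 1) == 38.3
        assert period_weeks_rounded(-0.0247, 0.0002) == 40
        assert period_weeks_rounded(-0.0124) == 56
        assert period_weeks_rounded(-0.0175) == 47

    def test_undamped_formula(self):
        est = period_of_oscillation(-0.0245)
        assert np.isclose(est.lambda_weeks, 2 * np.pi / np.sqrt(0.0245))

    def test_period_strictly_decreasing_in_frequency_magnitude(self):
        etas = -np.linspace(0.001, 0.1, 50)
        periods = [period_of_oscillation(e).lambda_weeks for e in etas]
        assert all(a > b for a, b in zip(periods, periods[1:]))

    def test_non_oscillatory_raises(self):
        with pytest.raises(NonOscillatoryError):
            period_of_oscillation(0.01)
        with pytest.raises(NonOscillatoryError):
            period_of_oscillation(-0.0001, 0.5)  # overdamped

    def test_damping_lengthens_period(self):
        undamped = period_of_oscillation(-0.0245, 0.0).lambda_weeks
        damped = period_of_oscillation(-0.0245, -0.1).lambda_weeks
        assert damped > undamped
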