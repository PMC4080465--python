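"""Multilevel damped-linear-oscillator fits and period arithmetic.

The oscillator model regresses the estimated acceleration on the estimated
displacement and velocity, with person-specific coefficients:

    xddot_pt = eta_p * x_pt + zeta_p * xdot_pt + v_pt,
    eta_p  = mu_eta  [+ b01 I_p + b02 S_p] + u_eta_p,
    zeta_p = mu_zeta [+ b11 I_p + b12 S_p] + u_zeta_p,

i.e. a linear mixed model with fixed effects on x and xdot, correlated
random slopes per person, and — deliberately — no fixed or random
intercept: the series are detrended residuals, centred by construction.
Model 1 omits the bracketed covariate terms; Model 2 includes the
per-person trend intercept I_p and slope S_p as (uncentered) moderators of
both coefficients.

A fitted frequency eta < 0 (with eta + zeta^2/4 < 0) implies oscillation
with period lambda = 2*pi / sqrt(-(eta + zeta^2/4)) weeks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from ._reml import LMMResult, fit_lmm_two_slopes

__all__ = [
    "DLOFit",
    "PeriodEstimate",
    "NonOscillatoryError",
    "DampedOscillatorModel",
    "fit_model1",
    "fit_model2",
    "period_of_oscillation",
    "period_weeks_rounded",
]

_MODEL2_NAMES = ("mu_eta", "mu_zeta", "b01", "b02", "b11", "b12")


@dataclass
class DLOFit:
    """Fixed effects, random-effect structure and metadata of one fit."""

    model: int
    fixed: dict  # name -> {"est", "se", "t"}
    sd_eta: float
    sd_zeta: float
    corr: float
    resid_sd: float
    person_effects: pd.DataFrame  # person, eta, zeta (fixed part + BLUP)
    converged: bool
    covariance: str  # "unstructured" | "diagonal"
    n_rows: int
    n_persons: int
    criterion: float = field(default=float("nan"))

    @property
    def mu_eta(self) -> float:
        return self.fixed["mu_eta"]["est"]

    @property
    def mu_zeta(self) -> float:
        return self.fixed["mu_zeta"]["est"]

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "fixed": self.fixed,
            "random": {
                "sd_eta": self.sd_eta,
                "sd_zeta": self.sd_zeta,
                "corr": self.corr,
            },
            "resid_sd": self.resid_sd,
            "converged": self.converged,
            "covariance": self.covariance,
            "n_rows": self.n_rows,
            "n_persons": self.n_persons,
        }


class DampedOscillatorModel(BaseEstimator):
    """Multilevel damped-oscillator estimator.

    Parameters
    ----------
    model : {1, 2}
        1: fixed effects on x and xdot only.  2: adds the person-level
        covariates (trend intercept and slope) as moderators of both.
    reml : bool, default True
        Restricted maximum likelihood.

    Attributes (after ``fit``)
    --------------------------
    result_ : DLOFit
    mu_eta_, mu_zeta_ : float
        Fixed frequency (1/week^2) and damping (1/week) effects.
    """

    def __init__(self, model: int = 1, reml: bool = True):
        self.model = model
        self.reml = reml

    def fit(self, derivs: pd.DataFrame, covariates: pd.DataFrame | None = None):
        """Fit on a derivative table (person, center_week, x, xdot, xddot).

        For model 2, ``covariates`` must hold one row per person with
        columns person, intercept, slope.
        """
        if self.model not in (1, 2):
            raise ValueError("model must be 1 or 2")
        y = derivs["xddot"].to_numpy(dtype=float)
        x = derivs["x"].to_numpy(dtype=float)
        xdot = derivs["xdot"].to_numpy(dtype=float)
        groups = derivs["person"].to_numpy()
        Z = np.column_stack([x, xdot])
        if self.model == 1:
            X = Z
            names = _MODEL2_NAMES[:2]
            cov_lookup = None
        else:
            if covariates is None:
                raise ValueError("model 2 requires per-person covariates")
            cov = covariates.set_index("person")
            missing = [p for p in pd.unique(groups) if p not in cov.index]
            if missing:
                raise ValueError(f"missing covariates for persons: {missing}")
            I = cov.loc[groups, "intercept"].to_numpy(dtype=float)
            S = cov.loc[groups, "slope"].to_numpy(dtype=float)
            X = np.column_stack([x, xdot, x * I, x * S, xdot * I, xdot * S])
            names = _MODEL2_NAMES
            cov_lookup = cov
        res = fit_lmm_two_slopes(y, X, Z, groups, reml=self.reml)
        covariance = "unstructured"
        if not np.isfinite(res.re_corr) or abs(res.re_corr) > 0.999:
            warnings.warn(
                "singular random-effects covariance; refit with diagonal "
                "covariance"
            )
            res = fit_lmm_two_slopes(y, X, Z, groups, reml=self.reml, diagonal=True)
            covariance = "diagonal"
        if not res.converged:
            warnings.warn("oscillator mixed-model fit did not converge")
        self.result_ = self._as_dlofit(res, names, covariance, cov_lookup)
        self.mu_eta_ = self.result_.mu_eta
        self.mu_zeta_ = self.result_.mu_zeta
        return self

    def _as_dlofit(self, res: LMMResult, names, covariance, cov_lookup) -> DLOFit:
        fixed = {}
        for name, est, se in zip(names, res.beta, res.beta_se):
            fixed[name] = {"est": float(est), "se": float(se), "t": float(est / se)}
        # per-person coefficients: fixed linear predictor + BLUP
        eta_fix = np.full(res.n_groups, fixed["mu_eta"]["est"])
        zeta_fix = np.full(res.n_groups, fixed["mu_zeta"]["est"])
        if self.model == 2:
            I = cov_lookup.loc[res.group_labels, "intercept"].to_numpy(dtype=float)
            S = cov_lookup.loc[res.group_labels, "slope"].to_numpy(dtype=float)
            eta_fix = eta_fix + fixed["b01"]["est"] * I + fixed["b02"]["est"] * S
            zeta_fix = zeta_fix + fixed["b11"]["est"] * I + fixed["b12"]["est"] * S
        person_effects = pd.DataFrame(
            {
                "person": res.group_labels,
                "eta": eta_fix + res.blups[:, 0],
                "zeta": zeta_fix + res.blups[:, 1],
            }
        )
        return DLOFit(
            model=self.model,
            fixed=fixed,
            sd_eta=float(res.re_sd[0]),
            sd_zeta=float(res.re_sd[1]),
            corr=res.re_corr,
            resid_sd=res.sigma,
            person_effects=person_effects,
            converged=res.converged,
            covariance=covariance,
            n_rows=res.n_rows,
            n_persons=res.n_groups,
            criterion=res.criterion,
        )


def fit_model1(derivs: pd.DataFrame, reml: bool = True) -> DLOFit:
    """Fit the oscillator model without covariates."""
    return DampedOscillatorModel(model=1, reml=reml).fit(derivs).result_


def fit_model2(
    derivs: pd.DataFrame, covars: pd.DataFrame, reml: bool = True
) -> DLOFit:
    """Fit the oscillator model with trend intercept/slope covariates."""
    return DampedOscillatorModel(model=2, reml=reml).fit(derivs, covars).result_


class NonOscillatoryError(ValueError):
    """eta + zeta^2/4 >= 0: no real oscillation period exists."""

    def __init__(self, eta: float, zeta: float):
        self.eta = eta
        self.zeta = zeta
        super().__init__(
            f"non-oscillatory parameters eta={eta}, zeta={zeta}: "
            f"eta + zeta^2/4 = {eta + zeta**2 / 4} >= 0"
        )


@dataclass(frozen=True)
class PeriodEstimate:
    """Oscillation period (weeks) with the generating parameters echoed."""

    lambda_weeks: float
    eta: float
    zeta: float


def period_of_oscillation(eta: float, zeta: float = 0.0) -> PeriodEstimate:
    """Period lambda = 2*pi / sqrt(-(eta + zeta^2/4)) in weeks."""
    disc = eta + zeta**2 / 4.0
    if disc >= 0:
        raise NonOscillatoryError(eta, zeta)
    return PeriodEstimate(
        lambda_weeks=float(2.0 * np.pi / np.sqrt(-disc)), eta=eta, zeta=zeta
    )


def period_weeks_rounded(eta: float, zeta: float = 0.0) -> int:
    """Period rounded to the nearest whole week."""
    return int(round(period_of_oscillation(eta, zeta).lambda_weeks))
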