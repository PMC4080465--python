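"""Per-person linear detrending.

Each person's completed series is regressed on week by ordinary least
squares, y_pt = I_p + S_p * t + e_pt.  The residuals e_pt carry the
within-person fluctuations the oscillator model is fit to; the intercepts
I_p and slopes S_p double as person-level covariates for the
covariate-extended oscillator model.  Weeks enter uncentered (t = 1..T_p),
so I_p is the week-0 extrapolate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .panel import PanelSeries

__all__ = ["DetrendResult", "LinearDetrender", "linear_detrend"]


@dataclass
class DetrendResult:
    """Residual panel plus per-person trend coefficients and diagnostics."""

    residuals: PanelSeries
    covariates: pd.DataFrame  # person, intercept, slope, r2, resid_sd


class LinearDetrender(BaseEstimator, TransformerMixin):
    """Remove each person's OLS linear trend from a complete panel.

    ``transform`` returns a :class:`DetrendResult`; the residuals sum to
    zero and are orthogonal to week within every person (OLS projection).
    """

    def fit(self, panel: PanelSeries, y=None) -> "LinearDetrender":
        return self

    def transform(self, panel: PanelSeries) -> DetrendResult:
        if not panel.is_complete:
            raise ValueError("panel must be complete (impute first)")
        values = panel.frame["value"].to_numpy()
        persons = panel.persons
        lengths = panel.t_max.loc[persons].to_numpy()
        if (lengths < 3).any():
            short = [p for p, n in zip(persons, lengths) if n < 3]
            raise ValueError(f"persons with < 3 weeks: {short}")
        offsets = np.concatenate([[0], np.cumsum(lengths)])
        resid = np.empty_like(values)
        rows = []
        for i, person in enumerate(persons):
            y = values[offsets[i] : offsets[i + 1]]
            t = np.arange(1, len(y) + 1, dtype=float)
            tbar, ybar = t.mean(), y.mean()
            tc = t - tbar
            slope = float(tc @ (y - ybar) / (tc @ tc))
            intercept = float(ybar - slope * tbar)
            e = y - intercept - slope * t
            resid[offsets[i] : offsets[i + 1]] = e
            sse = float(e @ e)
            sst = float((y - ybar) @ (y - ybar))
            rows.append(
                {
                    "person": person,
                    "intercept": intercept,
                    "slope": slope,
                    "r2": 1.0 - sse / sst if sst > 0 else 0.0,
                    "resid_sd": np.sqrt(sse / (len(y) - 2)) if len(y) > 2 else 0.0,
                }
            )
        return DetrendResult(
            residuals=panel.with_values(resid),
            covariates=pd.DataFrame(rows),
        )


def linear_detrend(panel: PanelSeries) -> DetrendResult:
    """OLS-detrend every person of a complete panel (see LinearDetrender)."""
    return LinearDetrender().fit(panel).transform(panel)
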