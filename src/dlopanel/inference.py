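"""Combining estimates: Rubin's rules across imputations and the
leave-one-person-out jackknife.

Rubin's rules pool m completed-data fits of the same parameter: the pooled
estimate is the mean, and the pooled variance T = W + (1 + 1/m) B adds the
average within-imputation variance W to the inflated between-imputation
variance B.  The jackknife reruns the entire analysis N times, deleting one
person each time, and turns the spread of the replicate estimates into a
standard error SE_JK = sqrt(((N-1)/N) * sum (theta_(-p) - theta_bar)^2);
the reported t is the full-sample estimate divided by SE_JK.
"""

from __future__ import annotations

import warnings
from collections.abc import Callable, Mapping
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import PanelSeries

__all__ = [
    "PooledEstimates",
    "JackknifeResult",
    "rubin_pool",
    "pool_fits",
    "jackknife",
]


@dataclass
class PooledEstimates:
    """Rubin-pooled estimates, one row per parameter.

    ``table`` columns: est, within, between, total, se, t, df, m.
    """

    table: pd.DataFrame
    m: int

    def __getitem__(self, param: str) -> pd.Series:
        return self.table.loc[param]

    def to_dict(self) -> dict:
        return {p: row.to_dict() for p, row in self.table.iterrows()}


def _pool_one(est: np.ndarray, var: np.ndarray, nu_com: float) -> dict:
    m = len(est)
    qbar = est.mean()
    wbar = var.mean()
    b = est.var(ddof=1) if m > 1 else 0.0
    total = wbar + (1.0 + 1.0 / m) * b
    se = np.sqrt(total)
    if b > 0:
        r = (1.0 + 1.0 / m) * b / wbar if wbar > 0 else np.inf
        nu_large = (m - 1) * (1.0 + 1.0 / r) ** 2 if np.isfinite(r) else m - 1.0
        if np.isfinite(nu_com):
            # Barnard-Rubin small-sample adjustment
            lam = (1.0 + 1.0 / m) * b / total
            nu_obs = (nu_com + 1.0) / (nu_com + 3.0) * nu_com * (1.0 - lam)
            df = 1.0 / (1.0 / nu_large + 1.0 / nu_obs)
        else:
            df = nu_large
    else:
        df = np.inf
    return {
        "est": qbar,
        "within": wbar,
        "between": b,
        "total": total,
        "se": se,
        "t": qbar / se if se > 0 else np.nan,
        "df": df,
        "m": m,
    }


def rubin_pool(
    estimates: Mapping[str, np.ndarray] | np.ndarray,
    variances: Mapping[str, np.ndarray] | np.ndarray,
    nu_com: float = np.inf,
) -> PooledEstimates:
    """Pool m estimates (and their squared SEs) per parameter.

    Parameters
    ----------
    estimates, variances : mapping or array
        Either parameter-name -> length-m arrays, or a single length-m
        array each (pooled under parameter name "theta").
    nu_com : float
        Complete-data degrees of freedom for the Barnard-Rubin df
        adjustment; infinite (default) gives the classical large-sample df.
    """
    if not isinstance(estimates, Mapping):
        estimates = {"theta": np.asarray(estimates, dtype=float)}
        variances = {"theta": np.asarray(variances, dtype=float)}
    rows = {}
    m_seen = set()
    for name, est in estimates.items():
        est = np.asarray(est, dtype=float)
        var = np.asarray(variances[name], dtype=float)
        if est.shape != var.shape:
            raise ValueError(f"{name}: estimates and variances differ in length")
        if len(est) < 2:
            raise ValueError(f"{name}: need m >= 2 imputations")
        if (var < 0).any():
            raise ValueError(f"{name}: negative variances")
        rows[name] = _pool_one(est, var, nu_com)
        m_seen.add(len(est))
    if len(m_seen) != 1:
        raise ValueError("parameters pooled over differing numbers of imputations")
    return PooledEstimates(table=pd.DataFrame(rows).T, m=m_seen.pop())


def pool_fits(fits: list) -> PooledEstimates:
    """Pool the fixed effects of a list of :class:`~dlopanel.model.DLOFit`."""
    names = list(fits[0].fixed)
    est = {n: np.array([f.fixed[n]["est"] for f in fits]) for n in names}
    var = {n: np.array([f.fixed[n]["se"] ** 2 for f in fits]) for n in names}
    return rubin_pool(est, var)


@dataclass
class JackknifeResult:
    """Leave-one-person-out resampling summary, one row per parameter.

    ``table`` columns: est (full sample), mean_replicate, se_jk, t_jk, n.
    ``replicates``: parameter -> length-N array of theta_(-p).
    """

    table: pd.DataFrame
    replicates: dict
    n: int

    def __getitem__(self, param: str) -> pd.Series:
        return self.table.loc[param]


def jackknife(
    pipeline: Callable[[PanelSeries], Mapping[str, float]],
    panel: PanelSeries,
) -> JackknifeResult:
    """Jackknife the statistics returned by ``pipeline`` over persons.

    ``pipeline`` maps a panel to a parameter-name -> estimate mapping and
    must be deterministic (carry its own fixed seeds).  Persons are deleted
    *before* the pipeline runs, so per-person imputation streams keyed on
    person labels make the replicates reuse the full-sample imputations of
    the retained persons.
    """
    persons = panel.persons
    n_all = len(persons)
    if n_all < 3:
        raise ValueError("jackknife needs at least 3 persons")
    full = dict(pipeline(panel))
    reps = {name: [] for name in full}
    n_failed = 0
    for leave_out in persons:
        keep = [p for p in persons if p != leave_out]
        try:
            est = pipeline(panel.subset(keep))
        except Exception as exc:  # noqa: BLE001 - replicate failures are data-driven
            n_failed += 1
            warnings.warn(f"jackknife replicate without {leave_out!r} failed: {exc}")
            continue
        for name in reps:
            reps[name].append(float(est[name]))
    n = n_all - n_failed
    if n_failed:
        warnings.warn(f"{n_failed} jackknife replicate(s) dropped; N adjusted to {n}")
    rows = {}
    replicates = {}
    for name, values in reps.items():
        theta = np.asarray(values, dtype=float)
        theta_bar = theta.mean()
        se = float(np.sqrt((n - 1) / n * np.sum((theta - theta_bar) ** 2)))
        rows[name] = {
            "est": full[name],
            "mean_replicate": theta_bar,
            "se_jk": se,
            "t_jk": full[name] / se if se > 0 else np.nan,
            "n": n,
        }
        replicates[name] = theta
    return JackknifeResult(table=pd.DataFrame(rows).T, replicates=replicates, n=n)
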