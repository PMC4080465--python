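"""Per-person B-spline stochastic regression imputation.

Each person's observed occasions are fit by least squares on a cubic
B-spline basis with ``K`` interior knots over their weekly grid (placed at
quantiles of the observed weeks by default, so every knot interval is
supported by data).  Missing occasions are then filled by *stochastic* regression
imputation: a coefficient vector is drawn from the fitted sampling
distribution N(coef, sigma^2 (B'B)^-1) and an independent residual
N(0, sigma^2) is added, so the completed series carries both parameter and
residual uncertainty.  Repeating the draw m times yields the multiply
imputed panels that downstream fits combine with Rubin's rules.

The number of knots is the bias/variance dial: few knots oversmooth and
damp the within-person fluctuations, many knots chase noise and inject
spurious high-frequency variance — exactly the trade-off the simulation
study quantifies.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline
from sklearn.base import BaseEstimator, TransformerMixin

from .panel import PanelSeries

__all__ = [
    "SplineFit",
    "ImputedPanel",
    "BSplineImputer",
    "build_basis",
    "fit_spline",
    "impute_once",
    "multiply_impute",
]


def _design(weeks: np.ndarray, interior: np.ndarray, degree: int,
            lo: float, hi: float) -> np.ndarray:
    knots = np.concatenate([[lo] * (degree + 1), interior, [hi] * (degree + 1)])
    return BSpline.design_matrix(weeks, knots, degree, extrapolate=False).toarray()


def build_basis(weeks: np.ndarray, K: int, degree: int = 3) -> np.ndarray:
    """B-spline design matrix over the given week grid.

    ``K`` interior knots are placed equally spaced strictly inside
    ``[min(weeks), max(weeks)]``; boundary knots are repeated degree+1
    times, giving ``K + degree + 1`` basis columns.  Rows sum to one
    (partition of unity).
    """
    weeks = np.asarray(weeks, dtype=float)
    if K < 1:
        raise ValueError("K must be >= 1")
    lo, hi = weeks.min(), weeks.max()
    if len(np.unique(weeks)) < degree + 1:
        raise ValueError("need at least degree+1 distinct weeks")
    interior = np.linspace(lo, hi, K + 2)[1:-1]
    return _design(weeks, interior, degree, lo, hi)


def _interior_knots(obs_weeks: np.ndarray, t_max: int, K: int,
                    placement: str) -> np.ndarray:
    """Interior knot positions strictly inside (1, t_max).

    "quantile" places knots at quantiles of the *observed* weeks so every
    knot interval contains data — with gappy schedules this keeps the
    least-squares problem identified (equally spaced knots can leave whole
    basis functions unsupported by observations, making coefficient draws
    arbitrarily wild).  "equal" spaces them uniformly over the span.
    """
    if placement == "equal":
        interior = np.linspace(1.0, float(t_max), K + 2)[1:-1]
    elif placement == "quantile":
        qs = np.linspace(0.0, 1.0, K + 2)[1:-1]
        interior = np.unique(np.quantile(obs_weeks, qs))
        interior = interior[(interior > 1.0) & (interior < t_max)]
    else:
        raise ValueError(f"unknown knot placement {placement!r}")
    return interior


@dataclass
class SplineFit:
    """Least-squares B-spline fit for one person's observed occasions."""

    person_id: object
    K: int
    degree: int
    knot_locations: np.ndarray
    coef_mean: np.ndarray
    coef_cov: np.ndarray
    resid_sd: float
    t_max: int
    grid_basis: np.ndarray = field(default=None, repr=False)
    coef_factor: np.ndarray = field(default=None, repr=False)

    @property
    def n_basis(self) -> int:
        return len(self.coef_mean)

    def _factor(self) -> np.ndarray:
        # PSD square root of coef_cov (coef_cov = F @ F.T)
        if self.coef_factor is None:
            eigval, eigvec = np.linalg.eigh(self.coef_cov)
            self.coef_factor = eigvec * np.sqrt(np.clip(eigval, 0.0, None))
        return self.coef_factor

    def predict(self, weeks: np.ndarray) -> np.ndarray:
        """Deterministic spline prediction at the given weeks."""
        return self.grid_basis[np.asarray(weeks, dtype=int) - 1] @ self.coef_mean


def fit_spline(
    values: np.ndarray,
    K: int,
    degree: int = 3,
    person_id: object = None,
    knot_placement: str = "quantile",
) -> SplineFit:
    """Fit one person's spline on the observed entries of ``values``.

    Parameters
    ----------
    values : ndarray
        The person's series on the grid 1..T_p, NaN = missing.
    K : int
        Requested number of interior knots; reduced stepwise (with a
        warning) while the observed design is rank deficient or leaves no
        residual degrees of freedom.
    knot_placement : {"quantile", "equal"}
        Interior knots at quantiles of the observed weeks (default; keeps
        every knot interval supported by data) or equally spaced over the
        person's span.
    """
    values = np.asarray(values, dtype=float)
    t_max = len(values)
    obs = ~np.isnan(values)
    n_obs = int(obs.sum())
    if n_obs < 4:
        raise ValueError(f"person {person_id!r}: needs >= 4 observed points")
    obs_weeks = np.flatnonzero(obs) + 1.0
    grid = np.arange(1, t_max + 1, dtype=float)
    k = K
    while k >= 1:
        interior = _interior_knots(obs_weeks, t_max, k, knot_placement)
        basis = _design(grid, interior, degree, 1.0, float(t_max))
        B = basis[obs]
        n_cols = B.shape[1]
        if n_obs > n_cols and np.linalg.matrix_rank(B) == n_cols:
            break
        k -= 1
    else:
        raise ValueError(
            f"person {person_id!r}: no feasible spline basis (n_obs={n_obs})"
        )
    if k < K:
        warnings.warn(
            f"person {person_id!r}: K reduced from {K} to {k} "
            f"(n_obs={n_obs})",
            stacklevel=2,
        )
    y = values[obs]
    btb = B.T @ B
    btb_inv = np.linalg.inv(btb)
    coef = btb_inv @ (B.T @ y)
    resid = y - B @ coef
    df = n_obs - n_cols
    sigma2 = float(resid @ resid) / df
    return SplineFit(
        person_id=person_id,
        K=k,
        degree=degree,
        knot_locations=interior,
        coef_mean=coef,
        coef_cov=sigma2 * btb_inv,
        resid_sd=float(np.sqrt(sigma2)),
        t_max=t_max,
        grid_basis=basis,
    )


def impute_once(
    fit: SplineFit,
    values: np.ndarray,
    rng: np.random.Generator,
    *,
    clip: bool = False,
    coef_draw_only: bool = False,
) -> np.ndarray:
    """One stochastic completion of a person's series.

    Draws coef* ~ N(coef_mean, coef_cov), predicts the missing weeks and
    adds N(0, resid_sd^2) residual noise (unless ``coef_draw_only``).
    Observed entries are returned untouched.
    """
    values = np.asarray(values, dtype=float)
    miss = np.isnan(values)
    out = values.copy()
    if not miss.any():
        return out
    # PSD-safe coefficient draw (coef_cov can be numerically singular)
    coef = fit.coef_mean + fit._factor() @ rng.standard_normal(fit.n_basis)
    pred = fit.grid_basis[miss] @ coef
    if not coef_draw_only and fit.resid_sd > 0:
        pred = pred + rng.normal(0.0, fit.resid_sd, size=miss.sum())
    if clip:
        pred = np.clip(pred, 0.0, 1.0)
    out[miss] = pred
    return out


@dataclass
class ImputedPanel:
    """m completed panels sharing the observed entries of the input."""

    m: int
    panels: list
    provenance: dict

    def __iter__(self):
        return iter(self.panels)


def _person_key(person) -> int:
    # order-independent per-person stream key (stable across person subsets,
    # which makes leave-one-person-out reruns reuse identical imputations)
    return zlib.crc32(str(person).encode("utf-8"))


class BSplineImputer(BaseEstimator, TransformerMixin):
    """Per-person B-spline stochastic multiple imputation.

    Parameters
    ----------
    n_knots : int, default 10
        Interior knots K per person (reduced automatically when a person
        has too few observations).
    degree : int, default 3
        Spline degree (cubic by default).
    m : int, default 10
        Number of completed datasets.
    knot_placement : {"quantile", "equal"}, default "quantile"
        Interior knots at observed-week quantiles (keeps the least-squares
        problem identified under gappy schedules) or equally spaced.
    clip : bool, default False
        Clip imputed values to [0, 1].
    coef_draw_only : bool, default False
        Omit the residual draw (coefficient uncertainty only).
    random_state : int, default 0
        Master seed; per-(imputation, person) substreams are derived from
        it so results do not depend on person order or panel subsetting.

    Attributes
    ----------
    fits_ : dict
        person -> :class:`SplineFit` after :meth:`fit`.
    """

    def __init__(
        self,
        n_knots: int = 10,
        degree: int = 3,
        m: int = 10,
        knot_placement: str = "quantile",
        clip: bool = False,
        coef_draw_only: bool = False,
        random_state: int = 0,
    ):
        self.n_knots = n_knots
        self.degree = degree
        self.m = m
        self.knot_placement = knot_placement
        self.clip = clip
        self.coef_draw_only = coef_draw_only
        self.random_state = random_state

    def fit(self, panel: PanelSeries, y=None) -> "BSplineImputer":
        self.fits_ = {
            person: fit_spline(
                panel.person_values(person),
                self.n_knots,
                self.degree,
                person_id=person,
                knot_placement=self.knot_placement,
            )
            for person in panel.persons
        }
        return self

    def transform(self, panel: PanelSeries) -> ImputedPanel:
        if not hasattr(self, "fits_"):
            raise RuntimeError("BSplineImputer is not fitted")
        panels = []
        all_values = panel.frame["value"].to_numpy()
        persons = panel.persons
        lengths = panel.t_max.loc[persons].to_numpy()
        offsets = np.concatenate([[0], np.cumsum(lengths)])
        for j in range(self.m):
            values = all_values.copy()
            for i, person in enumerate(persons):
                v = all_values[offsets[i] : offsets[i + 1]]
                rng = np.random.default_rng(
                    np.random.SeedSequence(
                        self.random_state, spawn_key=(j, _person_key(person))
                    )
                )
                values[offsets[i] : offsets[i + 1]] = impute_once(
                    self.fits_[person],
                    v,
                    rng,
                    clip=self.clip,
                    coef_draw_only=self.coef_draw_only,
                )
            panels.append(panel.with_values(values))
        return ImputedPanel(
            m=self.m,
            panels=panels,
            provenance={
                "K": self.n_knots,
                "degree": self.degree,
                "knot_placement": self.knot_placement,
                "seed": self.random_state,
                "clip": self.clip,
                "coef_draw_only": self.coef_draw_only,
            },
        )


def multiply_impute(
    panel: PanelSeries, K: int, m: int = 10, seed: int = 0, **kwargs
) -> ImputedPanel:
    """Fit per-person splines and produce m stochastic completions."""
    imputer = BSplineImputer(n_knots=K, m=m, random_state=seed, **kwargs)
    return imputer.fit(panel).transform(panel)
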