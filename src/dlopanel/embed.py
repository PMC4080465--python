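"""Time-delay embedding and local derivative estimation (GLLA / GOLD).

A person's residual series is cut into consecutive windows of D
observations (lag tau between columns).  Each window is mapped to estimates
of the displacement and its first two time derivatives at the window
centre by a D x 3 weight matrix W:

    [x, xdot, xddot] = window @ W.

GLLA takes W = L (L'L)^-1 where column j of the loading matrix L holds
(offset * tau * dt)^j / j! for the symmetric integer offsets
-(D-1)/2 .. (D-1)/2.  W'L = I, so the estimates are exact for any series
quadratic in time, but under white measurement noise the displacement and
second-derivative errors are correlated (the (0,2) entry of
(L'L)^-1 is nonzero), which biases downstream frequency estimates.

GOLD removes that correlation.  Both desired properties — unbiasedness for
quadratics (W'L = I) and uncorrelated derivative errors (W'W diagonal) —
cannot hold for a W whose columns lie in the column space of L (there the
solution of W'L = I is unique and equals the GLLA W), so GOLD adds a
correction in the orthogonal complement: the direction u of the degree-4
discrete orthogonal polynomial on the offset grid.  Writing
g = [(L'L)^-1]_{02}, the displacement and acceleration columns receive
+sqrt(|g|) u and -sign(g) sqrt(|g|) u; u is orthogonal to every quadratic,
so W'L = I is untouched, while the (x, xddot) error covariance cancels
exactly.  The first-derivative weights coincide with GLLA by parity.
This needs D >= 5 (at D = 3 the complement of span(L) is empty).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from sklearn.base import BaseEstimator, TransformerMixin

from .panel import PanelSeries

__all__ = [
    "EmbedSpec",
    "WeightMatrix",
    "Embedding",
    "TimeDelayDerivatives",
    "glla_weights",
    "gold_weights",
    "time_delay_embed",
    "estimate_derivatives",
]


@dataclass(frozen=True)
class EmbedSpec:
    """Embedding geometry: dimension D, lag tau (weeks), sampling step dt."""

    D: int
    tau: int = 1
    dt: float = 1.0

    def __post_init__(self):
        if self.D < 3 or self.D % 2 == 0:
            raise ValueError("D must be odd and >= 3")
        if self.tau < 1:
            raise ValueError("tau must be >= 1")

    @property
    def window_span(self) -> int:
        """Weeks covered by one window minus one: (D-1)*tau."""
        return (self.D - 1) * self.tau

    @property
    def offsets(self) -> np.ndarray:
        h = (self.D - 1) // 2
        return np.arange(-h, h + 1)


@dataclass(frozen=True)
class WeightMatrix:
    """Loading matrix L and derivative weights W for one embedding spec."""

    method: str  # "glla" | "gold"
    L: np.ndarray  # D x 3
    W: np.ndarray  # D x 3
    spec: EmbedSpec


def _loading_matrix(spec: EmbedSpec) -> np.ndarray:
    t = spec.offsets * spec.tau * spec.dt
    return np.column_stack([np.ones_like(t), t, t**2 / 2.0])


@lru_cache(maxsize=64)
def _weights_cached(method: str, D: int, tau: int, dt: float) -> WeightMatrix:
    spec = EmbedSpec(D, tau, dt)
    L = _loading_matrix(spec)
    gram_inv = np.linalg.inv(L.T @ L)
    W = L @ gram_inv
    if method == "gold":
        if D < 5:
            raise ValueError("GOLD requires D >= 5")
        # degree-4 discrete orthogonal polynomial on the offset grid
        v = spec.offsets.astype(float)
        powers = np.vander(v, 5, increasing=True)  # 1, v, .., v^4
        q, _ = np.linalg.qr(powers)
        u = q[:, 4]
        g = gram_inv[0, 2]
        s = np.sqrt(abs(g))
        W = W.copy()
        W[:, 0] += s * u
        W[:, 2] -= np.sign(g) * s * u
    for arr in (L, W):
        arr.setflags(write=False)
    return WeightMatrix(method=method, L=L, W=W, spec=spec)


def glla_weights(spec: EmbedSpec) -> WeightMatrix:
    """GLLA weights W = L (L'L)^-1 (exact for quadratics)."""
    return _weights_cached("glla", spec.D, spec.tau, spec.dt)


def gold_weights(spec: EmbedSpec) -> WeightMatrix:
    """GOLD weights: W'L = I and W'W diagonal (uncorrelated errors)."""
    return _weights_cached("gold", spec.D, spec.tau, spec.dt)


@dataclass
class Embedding:
    """Stacked per-person delay windows with row labels."""

    matrix: np.ndarray  # n_rows x D
    person: np.ndarray  # n_rows row labels
    center_week: np.ndarray  # n_rows window-centre weeks
    spec: EmbedSpec
    n_excluded: int = 0


def time_delay_embed(residuals: PanelSeries, spec: EmbedSpec) -> Embedding:
    """Build the stacked delay-embedding matrix of a complete residual panel.

    Rows are consecutive length-D windows (columns lag tau apart) within a
    single person; persons shorter than the window span + 1 are excluded
    with a warning count.  Row labels carry the person and the centre week
    of each window.
    """
    if not residuals.is_complete:
        raise ValueError("residual panel must be complete")
    values = residuals.frame["value"].to_numpy()
    persons = residuals.persons
    lengths = residuals.t_max.loc[persons].to_numpy()
    offsets = np.concatenate([[0], np.cumsum(lengths)])
    span = spec.window_span
    mats, labels, centers = [], [], []
    n_excluded = 0
    for i, person in enumerate(persons):
        T = lengths[i]
        if T < span + 1:
            n_excluded += 1
            continue
        y = values[offsets[i] : offsets[i + 1]]
        win = sliding_window_view(y, span + 1)[:, :: spec.tau]
        mats.append(win)
        n_rows = T - span
        labels.append(np.repeat(person, n_rows))
        centers.append(np.arange(1 + span // 2, 1 + span // 2 + n_rows))
    if not mats:
        raise ValueError("no person long enough for the requested embedding")
    if n_excluded:
        import warnings

        warnings.warn(f"{n_excluded} person(s) too short for D={spec.D}; excluded")
    return Embedding(
        matrix=np.concatenate(mats, axis=0),
        person=np.concatenate(labels),
        center_week=np.concatenate(centers),
        spec=spec,
        n_excluded=n_excluded,
    )


def estimate_derivatives(embedded: Embedding, weights: WeightMatrix) -> pd.DataFrame:
    """Apply the weight matrix to every window: Y = X^D W.

    Returns the derivative table with columns person, center_week, x,
    xdot, xddot (one row per window).
    """
    if embedded.matrix.shape[1] != weights.W.shape[0]:
        raise ValueError(
            f"embedding dimension {embedded.matrix.shape[1]} != weight rows "
            f"{weights.W.shape[0]}"
        )
    Y = embedded.matrix @ weights.W
    return pd.DataFrame(
        {
            "person": embedded.person,
            "center_week": embedded.center_week,
            "x": Y[:, 0],
            "xdot": Y[:, 1],
            "xddot": Y[:, 2],
        }
    )


class TimeDelayDerivatives(BaseEstimator, TransformerMixin):
    """Transformer: complete residual panel -> derivative table.

    Parameters
    ----------
    dim : int, default 11
        Embedding dimension D (odd; >= 5 for GOLD).
    tau : int, default 1
        Lag in weeks between adjacent window columns.
    dt : float, default 1.0
        Sampling interval in weeks.
    method : {"gold", "glla"}, default "gold"
    """

    def __init__(self, dim: int = 11, tau: int = 1, dt: float = 1.0,
                 method: str = "gold"):
        self.dim = dim
        self.tau = tau
        self.dt = dt
        self.method = method

    def _weights(self) -> WeightMatrix:
        spec = EmbedSpec(self.dim, self.tau, self.dt)
        if self.method == "gold":
            return gold_weights(spec)
        if self.method == "glla":
            return glla_weights(spec)
        raise ValueError(f"unknown method {self.method!r}")

    def fit(self, residuals: PanelSeries, y=None) -> "TimeDelayDerivatives":
        self._weights()  # validate parameters eagerly
        return self

    def transform(self, residuals: PanelSeries) -> pd.DataFrame:
        w = self._weights()
        return estimate_derivatives(time_delay_embed(residuals, w.spec), w)
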