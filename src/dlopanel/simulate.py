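"""Synthetic damped-linear-oscillator panels with study-like missingness.

Generates the latent process

    x_p(t) = A0 * exp(zeta_p * t / 2) * sin(omega_p * t + delta_p),
    omega_p = sqrt(-(eta_p + zeta_p**2 / 4)),

which solves the damped linear oscillator  x'' = eta*x + zeta*x'  for the
oscillatory regime ``eta + zeta**2/4 < 0`` (with zeta = 0 it reduces to the
undamped sine ``A0*sin(t*sqrt(-eta) + delta)``).  Person-level heterogeneity
enters through Gaussian random effects on eta and zeta, a uniform phase, and
per-person linear trends; the observed score is

    y_pt = I_p + S_p * t + x_p(t) + measurement noise

at the scheduled occasions and missing elsewhere.

Observation schedules emulate a cohort measured roughly biweekly at first
and irregularly later: a fixed number of observed occasions (default 40)
inside a person-specific total span (default 77-97 weeks), i.e. about 50%
missingness on the weekly grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import PanelSeries

__all__ = [
    "DLOParams",
    "ObservationSchedule",
    "generate_schedule",
    "simulate_panel",
]


@dataclass
class DLOParams:
    """Population parameters of the oscillator generator.

    eta_mean/eta_sd : mean and SD of the person frequency parameters
        (1/week^2); must keep the population in the oscillatory regime.
    zeta_mean/zeta_sd : mean and SD of the damping parameters (1/week).
    amplitude : A0, oscillation amplitude in score units.
    noise_sd : SD of additive measurement noise (score units).
    trend_intercept_mean/sd, trend_slope_mean/sd : person-level linear
        trend I_p + S_p*t; defaults mirror the memory-updating cohort's
        empirical moments (mean intercept 0.443, SD 0.167; mean slope
        0.0015/week, SD 0.0018).
    """

    eta_mean: float = -0.0245
    eta_sd: float = 0.0001
    zeta_mean: float = 0.0
    zeta_sd: float = 0.0
    amplitude: float = 0.1
    noise_sd: float = 0.02
    trend_intercept_mean: float = 0.443
    trend_intercept_sd: float = 0.167
    trend_slope_mean: float = 0.0015
    trend_slope_sd: float = 0.0018

    def __post_init__(self):
        if not self.eta_mean < 0:
            raise ValueError("eta_mean must be negative (oscillatory regime)")
        if not self.eta_mean + self.zeta_mean**2 / 4 < 0:
            raise ValueError("eta_mean + zeta_mean^2/4 must be negative")
        for name in ("eta_sd", "zeta_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class ObservationSchedule:
    """Design of the observation pattern on the weekly grid."""

    n_persons: int = 112
    n_observed: int = 40
    total_weeks_range: tuple[int, int] = (77, 97)
    pattern: str = "biweekly-then-irregular"

    def __post_init__(self):
        lo, hi = self.total_weeks_range
        if lo > hi or lo < 1:
            raise ValueError("invalid total_weeks_range")
        if self.n_observed > lo:
            raise ValueError("n_observed exceeds the minimum total span")
        if self.pattern not in ("biweekly-then-irregular", "uniform-random"):
            raise ValueError(f"unknown pattern {self.pattern!r}")


def _person_rng(seed: int, person_index: int, *stream) -> np.random.Generator:
    # per-person streams keyed by index so adding persons never reshuffles
    # earlier ones
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(person_index, *stream))
    )


def _one_mask(schedule: ObservationSchedule, rng: np.random.Generator) -> np.ndarray:
    lo, hi = schedule.total_weeks_range
    span = int(rng.integers(lo, hi + 1))
    n_obs = schedule.n_observed
    if n_obs > span:
        raise ValueError("infeasible schedule: n_observed > span")
    if n_obs == span:
        return np.ones(span, dtype=bool)
    if schedule.pattern == "uniform-random":
        weeks = {1, span}
        pool = rng.permutation(np.arange(2, span))
        for w in pool:
            if len(weeks) >= n_obs:
                break
            weeks.add(int(w))
    else:
        # ~first half of occasions on a biweekly grid with +/-1 jitter,
        # remainder scattered over the tail of the span
        n_early = min(n_obs // 2, (span + 1) // 2)
        base = 1 + 2 * np.arange(n_early)
        jitter = rng.choice([-1, 0, 1], size=n_early, p=[0.15, 0.7, 0.15])
        early = np.clip(base + jitter, 1, span)
        weeks = {1, span}
        weeks.update(int(w) for w in early)
        tail_start = int(base[-1]) + 2 if n_early else 2
        pool = rng.permutation(np.arange(max(2, tail_start), span))
        for w in pool:
            if len(weeks) >= n_obs:
                break
            weeks.add(int(w))
        # top up from anywhere if the tail was too short
        if len(weeks) < n_obs:
            pool = rng.permutation(np.arange(2, span))
            for w in pool:
                if len(weeks) >= n_obs:
                    break
                weeks.add(int(w))
    mask = np.zeros(span, dtype=bool)
    mask[np.array(sorted(weeks)) - 1] = True
    assert mask.sum() == n_obs
    return mask


def generate_schedule(
    schedule: ObservationSchedule, seed: int
) -> list[np.ndarray]:
    """Per-person boolean observation masks on the weekly grid.

    Week 1 and the final week T_p are always observed; the mask length is
    the person's total span, drawn uniformly from ``total_weeks_range``.
    Deterministic given ``seed``.
    """
    return [
        _one_mask(schedule, _person_rng(seed, p, 1))
        for p in range(schedule.n_persons)
    ]


def latent_trajectory(
    t: np.ndarray, eta: float, zeta: float, amplitude: float, phase: float
) -> np.ndarray:
    """Closed-form damped oscillator path at times ``t`` (weeks)."""
    disc = eta + zeta**2 / 4.0
    if disc >= 0:
        raise ValueError(f"non-oscillatory parameters: eta={eta}, zeta={zeta}")
    omega = np.sqrt(-disc)
    return amplitude * np.exp(zeta * t / 2.0) * np.sin(omega * t + phase)


def simulate_panel(
    params: DLOParams,
    schedule: ObservationSchedule,
    seed: int,
) -> tuple[PanelSeries, pd.DataFrame]:
    """Simulate an oscillator panel plus the per-person truth record.

    Returns
    -------
    panel : PanelSeries
        Scores at the scheduled occasions, missing elsewhere.
    truth : pandas.DataFrame
        One row per person: eta, zeta, phase, intercept, slope, t_max,
        n_obs and the count of non-oscillatory draws that were resampled.
    """
    masks = generate_schedule(schedule, seed)
    blocks, records = [], []
    for p, mask in enumerate(masks):
        rng = _person_rng(seed, p, 0)
        resampled = 0
        while True:
            eta = rng.normal(params.eta_mean, params.eta_sd)
            zeta = rng.normal(params.zeta_mean, params.zeta_sd)
            if eta + zeta**2 / 4.0 < 0:
                break
            resampled += 1
            if resampled == 1:
                warnings.warn(
                    f"person {p}: non-oscillatory draw resampled", stacklevel=2
                )
        phase = rng.uniform(0.0, 2.0 * np.pi)
        intercept = rng.normal(params.trend_intercept_mean, params.trend_intercept_sd)
        slope = rng.normal(params.trend_slope_mean, params.trend_slope_sd)
        span = len(mask)
        t = np.arange(1, span + 1, dtype=float)
        latent = latent_trajectory(t, eta, zeta, params.amplitude, phase)
        y = intercept + slope * t + latent
        if params.noise_sd > 0:
            y = y + rng.normal(0.0, params.noise_sd, size=span)
        values = np.where(mask, y, np.nan)
        pid = f"P{p + 1:03d}"
        blocks.append(
            pd.DataFrame({"person": pid, "week": np.arange(1, span + 1), "value": values})
        )
        records.append(
            {
                "person": pid,
                "eta": eta,
                "zeta": zeta,
                "phase": phase,
                "intercept": intercept,
                "slope": slope,
                "t_max": span,
                "n_obs": int(mask.sum()),
                "n_resampled": resampled,
            }
        )
    panel = PanelSeries(pd.concat(blocks, ignore_index=True), validate=False)
    return panel, pd.DataFrame(records)
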