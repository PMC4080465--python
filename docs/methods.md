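# Methods notes

This document records the statistical model, the default parameter
choices, and the numerical decisions in the implementation, with the
reasoning behind each.

## 1. Model and assumptions

The observed score of person `p` at week `t` is decomposed as

```
y_pt = I_p + S_p * t + x_p(t) + eps_pt,        eps_pt ~ N(0, sigma_eps²)
```

with a person-specific linear trend and a latent oscillation `x_p(t)`
obeying the damped linear oscillator `x'' = eta_p x + zeta_p x'`. In the
oscillatory regime (`eta_p + zeta_p²/4 < 0`) the solution is

```
x_p(t) = A0 * exp(zeta_p t / 2) * sin(omega_p t + delta_p),
omega_p = sqrt(-(eta_p + zeta_p²/4)),
```

so the oscillation period is `lambda_p = 2*pi / omega_p` weeks.

Assumptions the chain relies on:

- The trend is linear in time over the observed span (per-person OLS
  detrending; weeks enter uncentered, `t = 1..T_p`).
- Missingness is ignorable given the person's own observed series (the
  B-spline imputation model conditions only on time).
- Within-person residual dynamics are stationary enough for a single
  `(eta_p, zeta_p)` per person.
- The derivative-estimation window (`D` weeks) is short relative to the
  oscillation period; see attenuation below.

## 2. Parameters, units, defaults

| Parameter | Meaning | Unit | Default | Why |
|---|---|---|---|---|
| `eta_mean`, `eta_sd` | population frequency parameter | 1/week² | −0.0245, 1e−4 | ~40.1-week period, matching the motivating cohort's scale |
| `zeta_mean`, `zeta_sd` | damping | 1/week | 0, 0 | undamped default; damping estimated, not assumed |
| `amplitude` (A0) | oscillation amplitude | score units | 0.1 | ~10% of a proportion-correct scale |
| `noise_sd` | measurement noise SD | score units | 0.02 | small relative to amplitude (SNR 5) |
| `trend_intercept_mean/sd` | person trend intercept | score units | 0.443, 0.167 | empirical cohort moments |
| `trend_slope_mean/sd` | person trend slope | score/week | 0.0015, 0.0018 | empirical cohort moments |
| `n_persons` | cohort size | — | 112 | study design |
| `n_observed` | observed occasions per person | — | 40 | study design (~50% missing) |
| `total_weeks_range` | per-person span | weeks | (77, 97) | study design |
| `K` | interior spline knots | — | 10 | the bias/variance dial examined by the study |
| `degree` | spline degree | — | 3 | cubic, the standard default |
| `m` | imputations | — | 10 | conventional for ~50% missingness |
| `D` | embedding dimension | weeks | 11 | window ≈ quarter period at `lambda ≈ 40` |
| `tau`, `dt` | embedding lag, sampling step | weeks | 1, 1 | weekly grid |
| `method` | derivative weights | — | `gold` | uncorrelated derivative errors (below) |

## 3. Generator realism and limits

The simulator reproduces the *structure* of a weekly cohort design:
week 1 and the final week always observed, roughly biweekly measurement
early (with ±1-week jitter), irregular scattered occasions later. It does
not model attrition, retest effects, non-Gaussian noise, or
time-varying dynamics. The amplitude/noise defaults are choices, not
estimates; the Monte-Carlo bias/RMSE surface is qualitatively stable to
them but individual cell means (especially strongly oversmoothed cells
such as `K=5`) shift quantitatively with amplitude and noise.

## 4. Numerical choices

### Quantile knot placement (deviation worth knowing about)

Interior knots default to *quantiles of each person's observed weeks*
rather than equal spacing over the span (`knot_placement="equal"` keeps
the latter available). With ~50% gappy schedules and `K = 15`, equally
spaced knots can leave entire cubic basis functions supported on
unobserved stretches; the per-person least-squares problem is then
effectively unidentified, coefficient draws explode (observed coefficient
SDs up to 5·10⁴ on a [0,1]-scale outcome), and rare replicates dominate
Monte-Carlo means. Quantile placement guarantees every knot interval
contains data, which keeps the design full-rank and the coefficient draws
bounded; it is also the convention of standard spline regression tooling
(for example R's `splines::bs` with `df`). When the requested `K` still
leaves the design rank-deficient (very sparse persons), `K` is reduced
stepwise with a warning.

### GOLD weight construction

Both weight families map a length-`D` window to `(x, x', x'')` via a
`D×3` matrix `W` built from the loading matrix `L` with columns
`1, t, t²/2` at the symmetric window offsets. GLLA is the least-squares
projection `W = L (LᵀL)⁻¹`, exact for quadratics (`WᵀL = I`) but with
correlated displacement/acceleration errors under white noise (the (0,2)
entry of `(LᵀL)⁻¹` is nonzero). Requiring *both* `WᵀL = I` and `WᵀW`
diagonal is impossible for `W` inside the column space of `L` (there the
solution of `WᵀL = I` is unique). The implementation therefore adds a
correction in the orthogonal complement: the degree-4 discrete orthogonal
polynomial direction `u` on the offset grid, scaled so the (x, x'')
error covariance cancels exactly. `u` is orthogonal to every quadratic,
so unbiasedness is untouched; the first-derivative column is unchanged.
This requires `D ≥ 5` (at `D = 3` the complement of span(L) is empty),
which is enforced.

Attenuation: on a pure sine of angular frequency `omega`, symmetric
filters scale each derivative column by its cosine transfer, so the
recovered `x''/x` ratio is `(w₂ᵀc)/(w₀ᵀc)` with `c = cos(omega·offsets)`
— always below `omega²` in magnitude and increasingly so for wider
windows. This is the mechanism behind the decreasing frequency-magnitude
estimates at larger `D`, and it provides the closed-form oracle used in
the recovery tests.

### Profiled REML solver

The mixed model (two correlated random slopes, no intercepts) is fit by a
dedicated profiled-REML routine (`dlopanel._reml`): per-person 2×2
sufficient statistics, Woodbury identities for the per-person marginal
precision, closed-form profiling of the fixed effects and the residual
variance, and L-BFGS-B over the three Cholesky parameters of the scaled
random-effect covariance, from four deterministic starting points. A
general-purpose mixed-model implementation (statsmodels `MixedLM`) needs
~2.5 s per fit on the 112-person problem; the resampling and Monte-Carlo
layers require thousands of fits, so the specialized solver (~2 ms per
fit) is used in production and statsmodels is retained as an independent
cross-check in the test suite. If the fitted random-effect correlation is
singular (|corr| > 0.999), the model is refit with a diagonal covariance
and the result flagged.

### Stochastic imputation details

For each person, coefficient draws come from
`N(coef_hat, sigma_hat² (BᵀB)⁻¹)` via a PSD eigenvalue square root
(the covariance can be numerically singular), plus an independent
`N(0, sigma_hat²)` residual per missing week. Per-(imputation, person)
random substreams are keyed by the imputation index and a hash of the
person label, so imputations do not depend on person order or on which
other persons are present — leave-one-person-out reruns reuse the
retained persons' imputations exactly, which is what makes the jackknife
measure sampling variability rather than imputation churn.

### Seeds

All derived seeds are produced through `numpy.random.SeedSequence` spawn
keys and masked to < 2³¹ where they are exposed as integers. Within a
Monte-Carlo replication, all knot conditions share the same simulated
panel and missingness.

### Pooling and jackknife conventions

Rubin's rules use total variance `T = W̄ + (1 + 1/m) B` with the
classical large-sample degrees of freedom by default (a finite
complete-data `nu_com` switches on the small-sample adjustment). The
jackknife standard error is
`sqrt(((N−1)/N) * Σ (theta_(−p) − theta_bar)²)` and the reported `t` is
the *full-sample* estimate divided by that SE. Bias in the Monte-Carlo
study is `mean(estimate) − true`.

The two `t` statistics (model-based pooled vs jackknife) agree closely
when genuine person heterogeneity dominates the uncertainty. In
near-homogeneous cohorts (person frequency SD ≪ noise-induced apparent
spread) they diverge: the jackknife SE tracks the true sampling SD of the
pooled estimate (verified against Monte-Carlo replication SDs), while the
model-based SE — driven by variance components that absorb noise-induced
apparent slope heterogeneity — runs several times larger, i.e.
conservative.

## 5. Problem sizes

The shipped defaults are desk-scale: 100 Monte-Carlo replications (not
1000) for the acceptance targets, and reduced replication counts /
grid subsets inside the test suite so the whole suite runs in minutes on
one CPU. These sizes are this package's own choices; the cell means they
produce carry Monte-Carlo SEs of roughly 1e−5 to 1e−4, small relative to
the between-cell differences of interest.

## 6. Limitations

- The imputation model is a per-person smoother; it borrows no strength
  across persons and will oversmooth genuinely high-frequency dynamics
  when `K` is small relative to the number of oscillation cycles.
- Quantile knot placement makes the `K=5` oversmoothing milder than an
  equal-spacing implementation would produce, so strongly oversmoothed
  cells of the bias surface are generator- and placement-sensitive.
- The oscillator model assumes one frequency per person; mixtures or
  drifting frequencies are outside scope.
- Derivative estimates at window edges are unavailable (each person
  loses `D − 1` weeks of rows), which slightly favours mid-series
  dynamics.
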