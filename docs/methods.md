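# Methods

`dlnmkit` implements a two-stage analysis of daily hospital admissions and
particulate matter across multiple cities: city-level distributed lag
non-linear models (DLNMs) under a quasi-Poisson likelihood, a QAIC-driven
joint search over covariate subsets and basis hyperparameters, reduction of
the fitted exposure-lag coefficient block to relative-risk summaries, and
fixed-effect multivariate meta-analysis pooling cities into one surface.
This note records the model, the conventions chosen where the design was
genuinely open, the synthetic study conditions, and known limitations.

## The city-level model

For one city, one disease and one pollutant, daily counts Y_t follow

    log E(Y_t) = α + cb(x, t)' β + γ' M_t + δ' S_t,     V(Y_t) = φ E(Y_t)

where `cb(x, t)` is the cross-basis row for the pollutant series x at day
t, M_t the subset of the five meteorological covariates retained by model
selection (average temperature °C, relative humidity %, wind speed m/s,
diurnal temperature range °C, precipitation mm, all entering linearly), and
S_t the first K = 6 Fourier harmonic pairs of an annual cycle (period
m = 365 days), giving 12 seasonal columns. The quasi-Poisson variance
assumption leaves point estimates identical to Poisson maximum likelihood
and rescales the covariance by the Pearson dispersion
φ = χ²_Pearson / (n − p).

### Cross-basis construction

The exposure-lag-response surface f(x, l) is parameterized as a tensor
product of two natural cubic spline bases: a predictor basis R with df_p
columns over the concentration axis and a lag basis C with df_l columns
over lags 0..L. The design row for day t is

    cb(x, t)_(j,k) = Σ_{l=0..L} R(x_{t−l})_j · C(l)_k ,

df_p · df_l columns, predictor index outermost. Days 0..L−1 (incomplete
lag history) are dropped from fitting, never imputed.

Spline conventions, fixed once and used everywhere:

* interior knots equally spaced between boundary knots; boundary knots at
  the observed min/max of the fitting-period exposure (predictor axis) and
  at 0 and L (lag axis);
* the predictor basis carries no intercept column (the GLM intercept
  absorbs the constant; an intercept there would make the design
  rank-deficient);
* the lag basis **contains** a constant column counted inside df_l (the
  remaining df_l − 1 columns are a natural spline over 0..L). An
  interceptless natural spline on the lag axis vanishes identically at
  lag 0 — every basis column is zero at the left boundary knot — which
  would hard-wire the same-day effect f(x, 0) = 0. The constant column
  does not collide with the GLM intercept because its cross-basis columns
  Σ_l R(x_{t−l})_j still vary with t;
* lag knots are equally spaced on the untransformed lag scale (no log-lag
  transform);
* the natural spline basis is built as cubic B-splines projected onto the
  null space of the second-derivative constraints at the two boundary
  knots (the construction used by R's `splines::ns`; the two agree
  elementwise for equally spaced knots). Evaluation outside the boundary
  knots extends linearly and is legitimate but extrapolatory;
* df = 1 degenerates to a single linear column; df_l = 1 (used only with
  L = 0) degenerates to the constant.

### QAIC and model selection

Candidates are every covariate subset (2⁵ = 32) crossed with the
hyperparameter grid L ∈ {7..31}, df_p ∈ {2..5}, df_l ∈ {2..5} — 12 800
models per search by default. Ranking uses

    QAIC = −2 · loglik_Poisson / φ_ref + 2p

with these conventions, fixed because the one-line definition "the AIC for
quasi-Poisson" does not pin them down:

* φ_ref is the Pearson dispersion of the **most complex** candidate (all
  five covariates, largest L, df_p, df_l in the grid), shared across all
  candidates of one search so their QAICs are on a common scale — standard
  quasi-likelihood model-selection practice;
* p counts every estimated regression coefficient including the intercept;
  φ is not counted;
* the Poisson log-likelihood includes its normalizing term, so QAIC at
  φ_ref = 1 is exactly AIC;
* all candidates are fit on one common window — days with full lag history
  for the **largest** L in the grid — even though smaller-L candidates
  could use more days; likelihoods over different responses are not
  comparable;
* near-perfect fits floor φ at 1e−8 (with a warning) so QAIC stays finite
  in degenerate toy problems.

Selection applies the parsimony rule: among candidates with
ΔQAIC = QAIC_i − QAIC_min < 2, the simplest wins, simplicity ordered by
(fewer covariates, smaller df_p + df_l, smaller L, lower QAIC, enumeration
order). Only the first key is the substantive rule; the rest are
deterministic tie-breaks. Covariate subsets and hyperparameters are
optimized jointly (the full cross product), the literal reading of a
best-subset search tuned per subset. The search is a pure function of
(panel, grid, seasonal spec); candidates failing numerically are excluded
with the reason logged rather than aborting the search.

The two-stage design optimizes on a reference city only; all other cities
are re-fit at the frozen (covariate subset, L, df_p, df_l). When a
pre/post period split is requested, each period is a fully independent
analysis (selection redone per period) — the conservative choice; sharing
hyperparameters across periods is possible by freezing manually.

### Quasi-Poisson fitting

IRLS is delegated to `statsmodels` GLM with the Poisson family
(convergence: relative deviance change < 1e−9, ≤ 100 iterations,
deterministic initialization); the module adds strict input validation
(integer non-negative counts, full-column-rank design with collinear
columns named via pivoted QR), Pearson dispersion, the dispersion-scaled
covariance, and QAIC. The test suite checks coefficients and standard
errors against an independently written damped Newton–Raphson scorer.

## Relative-risk reduction

All summaries are linear functionals c'β of the cross-basis block, so
se = √(c' V c) by the delta method and 95% limits are Wald on the log
scale (z = 1.96). With lag-basis rows C(l) and predictor basis R:

* overall cumulative curve: c(x) = R(x) ⊗ Σ_l C(l), referenced by
  subtracting c(x_ref), so RR(x_ref) = 1 with zero-width CI **exactly**
  (by construction, not within tolerance);
* exposure-lag surface: per-cell contrast R(x) ⊗ C(l) − R(x_ref) ⊗ C(l),
  exported as a long table (x, lag, rr, ci); summing its log-RR over
  integer lags reproduces the cumulative curve to numerical precision;
* extreme contrasts: per-lag RR of the 90th and 10th percentile
  concentration versus the median (type-7 linear-interpolation quantiles),
  the reference value being the reference city's median over the fitting
  period.

The default evaluation grid is 100 equally spaced points over the observed
exposure range of the reference city.

## Meta-analysis

Fixed-effect multivariate pooling of the cross-basis blocks:
β_pool = (Σ V_j⁻¹)⁻¹ Σ V_j⁻¹ β_j and V_pool = (Σ V_j⁻¹)⁻¹, with the
multivariate Cochran Q reported as a heterogeneity diagnostic. Only the
cross-basis block is pooled — covariate and seasonal coefficients are
city-specific nuisances — which is what requires identical hyperparameters
across cities. Inversions use Cholesky solves; study covariances with
condition number above 1e12 are rejected with the study named. No
random-effects estimator is provided.

## Synthetic study conditions

The generator emulates the merged daily panel and fixes the conditions all
recovery tests run under:

* 3 cities, 4 years of daily data (2016–2019), baseline ≈ 15 admissions
  per city-day with a ±0.2 log-scale spread across cities;
* log-rate seasonality of two annual harmonics (amplitudes 0.15, 0.05) and
  a linear temperature effect of −0.005 per °C;
* pollutant: mean 45 μg/m³, winter-peaking seasonal amplitude 15 μg/m³,
  AR(1) coefficient 0.7 with stationary sd 8 μg/m³, floored at 1 μg/m³;
  exposure history before day 0 is padded with the process mean so row
  counts are deterministic;
* meteorology: independent seasonal sinusoids plus Gaussian noise; DTR is
  generated as simulated daily maximum minus minimum temperature (a
  half-range applied symmetrically around the mean), hence non-negative by
  construction;
* counts: negative binomial with size μ/(φ−1) so that V(Y) = φμ exactly,
  matching the quasi-Poisson variance contract; φ = 1.2 by default,
  degenerating to Poisson at φ = 1;
* truth surface: f(x, l) = g(x)·w(l) with g an inverted-U quadratic
  peaking at 40 μg/m³ (amplitude 0.15, half-width 35 μg/m³, referenced to
  zero at x_ref = 45 μg/m³) and w a geometric decay (ratio 0.7) over lags
  0..14 normalized to sum to one — so the true overall cumulative log RR
  is exactly g(x) − g(x_ref), closed form for every oracle. Baseline rates
  are chosen for statistical power at desk scale, not calibrated to any
  city's admission volume.

What the generator does **not** emulate: day-of-week and holiday patterns,
reporting artefacts, spatially correlated exposure across cities,
measurement error in the pollutant, epidemic dynamics, or correlated
meteorology (covariates are independent by design, so passing recovery
tests does not certify behaviour under strong confounder collinearity).

### Recovery experiment and its summary

The parameter-recovery check runs the full two-stage pipeline per
replicate at a reduced search grid (lags {14}, df {4}, covariate
candidates {temperature, humidity}), 200 replicates for the effect
surface and 100 for the null surface, evaluating the pooled cumulative
curve on 25 equally spaced points between the 1st and 99th exposure
percentiles. The summary statistic is the **aggregate pointwise
coverage** — the fraction of (replicate, grid point) pairs whose 95% CI
covers the truth. A per-grid-point minimum is deliberately not used: at
the grid point adjacent to the reference concentration the Wald CI width
vanishes by construction (the curve is pinned to zero at x_ref) while the
natural-spline approximation bias of the quadratic truth does not, so
coverage exactly there dips below nominal no matter how much data is
available. This is a known degeneracy of reference-anchored spline
curves, not an estimation defect; away from that point coverage is at or
above nominal.

## Numerical choices and degenerate inputs

* Convergence and rank failures raise typed errors naming the offending
  columns; validation never silently drops rows.
* Constant exposure series: the cross-basis remains defined (boundary
  widened by ±0.5) though any fit on it is singular; degenerate quantile
  contrasts (all-equal series) are errors.
* Input tables are strict CSV with ISO dates; calendar gaps are errors
  listing the missing dates, with optional linear interpolation for gaps
  ≤ 2 days behind an explicit flag.
* All randomness flows from a single integer seed through
  `numpy.random.default_rng`; identical configuration implies bit-identical
  panels and byte-identical output tables.

## Limitations

* Single-pollutant models only; PM10 and PM2.5 are collinear and never
  co-included.
* No offsets, zero-inflation, autoregressive residual corrections, or
  GEE-style robust variances.
* Fixed-effect pooling assumes one common surface across cities; the Q
  statistic flags, but does not correct for, heterogeneity.
* Wald intervals can under-cover immediately adjacent to the reference
  concentration (see above) and in the extrapolation region beyond the
  observed exposure range.
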