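# dlnmkit

Two-stage distributed lag non-linear modelling (DLNM) of daily hospital
admissions and particulate matter, for environmental-epidemiology analysts
who need the whole chain — basis construction, quasi-Poisson fitting, model
selection, relative-risk reduction and cross-city pooling — as tested,
reusable Python rather than a one-off script.

## What it computes

For each city, daily counts of admissions for one disease are regressed on
a pollutant (PM₁₀ or PM₂.₅, μg/m³) through a bi-dimensional *cross-basis*
that represents the effect jointly over concentration and lags 0..L:

    log E(Y_t) = α + cb(x, t)'β + γ'M_t + δ'S_t,    V(Y_t) = φ E(Y_t)

with natural cubic splines (df_p over concentration, df_l over lag,
equally spaced knots), up to five linear meteorological covariates M_t
(temperature, humidity, wind, diurnal temperature range, precipitation),
and six Fourier harmonic pairs S_t for annual seasonality (m = 365).

The covariate subset and the hyperparameters (L ∈ 7..31 days, df_p and
df_l ∈ 2..5) are chosen by a best-subset × grid search ranked by QAIC
(the quasi-Poisson analogue of AIC), with the parsimony rule that among
models within 2 QAIC units of the optimum the simplest wins. The search
runs once on a reference city; remaining cities are re-fit at the frozen
settings, and their cross-basis coefficient blocks are pooled by
fixed-effect multivariate meta-analysis. Pooled (or city-level) blocks are
reduced to:

* the overall cumulative exposure-response curve, RR(x) versus the
  reference city's median concentration, summed over the full lag window;
* the full exposure-lag RR surface as a long-format table;
* per-lag RRs of the 90th/10th percentile concentration versus the median.

All uncertainty is delta-method Wald on the log-RR scale. See
`docs/methods.md` for conventions and assumptions.

Because real claims/air-quality databases of this kind are
access-restricted, the package ships a synthetic-data module that
generates multi-city panels with a *known* exposure-lag-response surface
(an inverted-U in concentration times a geometric lag decay), so every
stage is validated by parameter recovery.

## Worked example

```python
import numpy as np
from dlnmkit import (SimConfig, simulate_panel, SearchGrid, optimize,
                     fit_frozen, StudyEstimate, fixed_effect_mvmeta,
                     overall_cumulative)

cfg = SimConfig(seed=1)                      # 3 cities, 2016-2019, daily
panel, truth = simulate_panel(cfg)
grid = SearchGrid(max_lags=(7, 14), df_p_values=(3, 4), df_l_values=(3, 4),
                  covariates=("tavg", "rh"))
cities = list(dict.fromkeys(panel["city"]))
ref = panel[panel["city"] == cities[0]].reset_index(drop=True)
best, table = optimize(ref, grid)            # stage 1: QAIC search
print(f"selected: covariates={best.covariate_mask} L={best.max_lag} "
      f"df_p={best.df_p} df_l={best.df_l} QAIC={best.qaic:.1f}")

studies, cb_ref = [], None
for city in cities:                          # stage 2: frozen fits
    fit, cb = fit_frozen(panel[panel["city"] == city].reset_index(drop=True), best)
    cb_ref = cb_ref or cb
    beta, vcov = fit.block("crossbasis")
    studies.append(StudyEstimate(label=city, beta=beta, vcov=vcov))
pooled = fixed_effect_mvmeta(studies)
print(f"pooled {pooled.n_studies} cities, Q={pooled.q_statistic:.2f}")

x = ref["x"].to_numpy()
curve = overall_cumulative(pooled, cb_ref, [20.0, 40.0, 60.0, 80.0],
                           x_ref=float(np.median(x)))
print(curve.table[["x", "rr", "rr_low", "rr_high"]].round(3).to_string(index=False))
```

Output:

```
selected: covariates=('tavg',) L=7 df_p=3 df_l=4 QAIC=6561.8
pooled 3 cities, Q=34.77
   x    rr  rr_low  rr_high
20.0 0.954   0.900    1.012
40.0 0.998   0.984    1.013
60.0 0.948   0.910    0.988
80.0 0.808   0.679    0.962
```

Each `rr` is the cumulative relative risk of admission at that
concentration versus the median (~45 μg/m³), summed over lags 0..7; the
true generating surface at those points is RR = 0.955, 1.003, 0.955,
0.825 — inside every interval. The selected model kept temperature (the
only covariate the generator gives a real effect) and dropped humidity.

The same pipeline is scriptable from the shell:

```
dlnmkit simulate --out data/ --cities 3 --seed 1
dlnmkit run --simulate --cities seoul,busan,daegu --max-lags 7,14 --dfs 3,4 \
            --out results_run/ --seed 1
```

which writes `qaic_table.csv`, `association_overall.csv`,
`association_surface.csv`, `extreme_effects.csv`, per-city and pooled
estimates as JSON, and a run manifest. `optimize`, `fit`, `meta` and
`effects` subcommands expose the individual stages.

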