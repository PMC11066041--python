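"""Two-stage orchestration: reference-city optimization, frozen per-city
fits, meta-pooling, and tabular relative-risk outputs.

Stage one runs the QAIC search on the reference city (the first city in
the configuration) and freezes the selected covariate subset and
hyperparameters.  Stage two re-fits every remaining city at those frozen
settings, pools the cross-basis blocks by fixed-effect multivariate
meta-analysis, and reduces both the pooled estimate and each city fit to
overall-cumulative, surface and extreme-contrast tables.  Each (period,
disease) stratum is analyzed independently; a manifest records successes
and failures so partial runs remain usable.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import association as assoc
from .basis import CrossBasis
from .meta_pool import StudyEstimate, fixed_effect_mvmeta
from .model_selection import CandidateModel, SearchGrid, fit_frozen, optimize
from .panel_io import PeriodSplit, read_panel, split_periods
from .qp_glm import QPFit
from .synthetic_data import SimConfig, simulate_panel, write_panel_tables

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Everything one two-stage run needs; the first city is the reference."""

    cities: tuple[str, ...]
    diseases: tuple[str, ...] = ("synthetic",)
    pollutant: str = "pm10"
    admissions_path: str | None = None
    airquality_path: str | None = None
    meteorology_path: str | None = None
    simulate: bool = False
    sim_config: SimConfig | None = None
    split: PeriodSplit | None = None
    grid: SearchGrid = field(default_factory=SearchGrid)
    seasonal_harmonics: int = 6
    seasonal_period: float = 365.0
    exposure_grid_size: int = 100
    quantile_levels: tuple[float, float, float] = (0.10, 0.50, 0.90)
    output_dir: str = "dlnmkit_out"
    seed: int = 0

    def __post_init__(self):
        if not self.cities:
            raise ValueError("at least one city (the reference) is required")
        if self.seasonal_harmonics < 1:
            raise ValueError("need at least one seasonal harmonic")

    @property
    def reference_city(self) -> str:
        return self.cities[0]


def _fit_payload(fit: QPFit, cb: CrossBasis, best: CandidateModel) -> dict:
    beta, vcov = fit.block("crossbasis")
    return {
        "hyperparameters": {
            "max_lag": best.max_lag, "df_p": best.df_p, "df_l": best.df_l,
            "covariates": list(best.covariate_mask),
        },
        "exposure_range": list(cb.exposure_range),
        "dispersion": fit.dispersion,
        "n_obs": fit.n_obs,
        "crossbasis_beta": beta.tolist(),
        "crossbasis_vcov": vcov.tolist(),
        "coefficients": fit.coefficients.tolist(),
    }


def _qaic_table(shells) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "covariates": "+".join(c.covariate_mask) or "(none)",
            "max_lag": c.max_lag, "df_p": c.df_p, "df_l": c.df_l,
            "qaic": c.qaic, "n_params": c.n_params,
            "failure": c.failure or "",
        }
        for c in shells
    ])


def analyze_stratum(
    panels: dict[str, pd.DataFrame], config: RunConfig
) -> dict:
    """Run both stages on per-city panels of one (period, disease) stratum.

    Returns a bundle with the selected model, QAIC table, per-city fits,
    the pooled estimate, and the three association tables computed from the
    pooled estimate with the reference city's median concentration as
    x_ref.
    """
    ref_city = config.reference_city
    best, shells = optimize(
        panels[ref_city], config.grid,
        config.seasonal_harmonics, config.seasonal_period,
    )
    log.info("selected: covariates=%s L=%d df_p=%d df_l=%d QAIC=%.2f",
             best.covariate_mask, best.max_lag, best.df_p, best.df_l, best.qaic)

    fits: dict[str, tuple[QPFit, CrossBasis]] = {}
    for city in config.cities:
        fits[city] = fit_frozen(
            panels[city], best, config.seasonal_harmonics,
            config.seasonal_period,
        )
    studies = []
    for city, (fit, _) in fits.items():
        beta, vcov = fit.block("crossbasis")
        studies.append(StudyEstimate(label=city, beta=beta, vcov=vcov))
    pooled = fixed_effect_mvmeta(studies)

    ref_exposure = panels[ref_city]["x"].to_numpy(dtype=float)
    x_ref = float(np.median(ref_exposure))
    cb_ref = fits[ref_city][1]
    grid = assoc.default_grid(ref_exposure, config.exposure_grid_size)
    overall = assoc.overall_cumulative(pooled, cb_ref, grid, x_ref)
    surface = assoc.exposure_lag_surface(
        pooled, cb_ref, grid[:: max(1, len(grid) // 25)], x_ref=x_ref
    )
    extremes = assoc.extreme_effects(
        pooled, cb_ref, ref_exposure, config.quantile_levels
    )
    return {
        "selected": best, "qaic_table": _qaic_table(shells), "fits": fits,
        "pooled": pooled, "x_ref": x_ref, "overall": overall,
        "surface": surface, "extremes": extremes,
    }


def _load_panels(config: RunConfig, disease: str) -> dict[str, pd.DataFrame]:
    panels = {}
    for city in config.cities:
        panels[city] = read_panel(
            config.admissions_path, config.airquality_path,
            config.meteorology_path, city=city, disease=disease,
            pollutant=config.pollutant,
        )
    return panels


def run_two_stage(config: RunConfig) -> dict:
    """Full pipeline: inputs (or simulation) -> per-stratum results on disk.

    Writes, per (period, disease) stratum under ``output_dir``:
    qaic_table.csv, association_overall.csv, association_surface.csv,
    extreme_effects.csv, estimates.json (per-city and pooled coefficient
    blocks), and a run-level manifest.json echoing the configuration.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.simulate:
        sim = config.sim_config or SimConfig(
            n_cities=len(config.cities), seed=config.seed
        )
        sim = dataclasses.replace(sim, n_cities=len(config.cities),
                                  seed=config.seed)
        full_panel, _ = simulate_panel(sim)
        rename = dict(zip(sim.city_names(), config.cities))
        full_panel["city"] = full_panel["city"].map(rename)
        sim_dir = out / "simulated_input"
        write_panel_tables(full_panel, sim_dir, config=sim,
                           disease=config.diseases[0],
                           pollutant=config.pollutant)
        config = dataclasses.replace(
            config,
            admissions_path=str(sim_dir / "admissions.csv"),
            airquality_path=str(sim_dir / "airquality.csv"),
            meteorology_path=str(sim_dir / "meteorology.csv"),
        )

    manifest = {"config": _config_echo(config), "strata": []}
    results = {}
    for disease in config.diseases:
        panels = _load_panels(config, disease)
        strata: dict[str, dict[str, pd.DataFrame]] = {}
        if config.split is not None:
            pre, post = {}, {}
            for city, p in panels.items():
                pre[city], post[city] = split_periods(p, config.split)
            strata["pre"], strata["post"] = pre, post
        else:
            strata["all"] = panels

        for period, period_panels in strata.items():
            key = f"{period}_{disease}"
            stratum_dir = out / key
            entry = {"period": period, "disease": disease, "status": "ok"}
            try:
                res = analyze_stratum(period_panels, config)
            except Exception as exc:  # noqa: BLE001 - stratum isolation
                entry["status"] = "failed"
                entry["error"] = f"{type(exc).__name__}: {exc}"
                log.error("stratum %s failed: %s", key, entry["error"])
                manifest["strata"].append(entry)
                continue
            stratum_dir.mkdir(parents=True, exist_ok=True)
            res["qaic_table"].to_csv(stratum_dir / "qaic_table.csv",
                                     index=False)
            res["overall"].table.to_csv(
                stratum_dir / "association_overall.csv", index=False)
            res["surface"].table.to_csv(
                stratum_dir / "association_surface.csv", index=False)
            res["extremes"].table.to_csv(
                stratum_dir / "extreme_effects.csv", index=False)
            best = res["selected"]
            estimates = {
                "selected": {
                    "covariates": list(best.covariate_mask),
                    "max_lag": best.max_lag, "df_p": best.df_p,
                    "df_l": best.df_l, "qaic": best.qaic,
                },
                "x_ref": res["x_ref"],
                "cities": {
                    city: _fit_payload(fit, cb, best)
                    for city, (fit, cb) in res["fits"].items()
                },
                "pooled": {
                    "beta": res["pooled"].beta_pooled.tolist(),
                    "vcov": res["pooled"].vcov_pooled.tolist(),
                    "q_statistic": res["pooled"].q_statistic,
                    "n_studies": res["pooled"].n_studies,
                },
            }
            (stratum_dir / "estimates.json").write_text(
                json.dumps(estimates, indent=2))
            entry["selected"] = estimates["selected"]
            entry["n_city_fits"] = len(res["fits"])
            manifest["strata"].append(entry)
            results[key] = res
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return {"manifest": manifest, "results": results, "output_dir": str(out)}


def _config_echo(config: RunConfig) -> dict:
    echo = dataclasses.asdict(config)
    for k, v in echo.items():
        if isinstance(v, tuple):
            echo[k] = list(v)
    return json.loads(json.dumps(echo, default=str))
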