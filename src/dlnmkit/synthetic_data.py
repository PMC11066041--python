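"""Synthetic multi-city daily panels with a known exposure-lag-response truth.

The generator emulates the merged daily panel an air-pollution time-series
study works from: for each city, several years of daily admission counts,
a seasonal autocorrelated particulate-matter series (μg/m³) and five
meteorological covariates (average temperature, relative humidity, wind
speed, diurnal temperature range, precipitation).  Counts are overdispersed
(variance phi * mean) and their log-rate contains a known nonlinear,
lag-distributed contribution of the pollutant, so every downstream stage —
cross-basis fitting, QAIC selection, reduction to relative risks, pooling —
can be tested by parameter recovery without any external data.

The default ground-truth surface is a product form f(x, l) = g(x) * w(l):
an inverted-U in concentration peaking near 40 μg/m³ (the shape reported
for particulate matter and respiratory admissions) times a geometric decay
over lags normalized to sum to one, so the overall cumulative log relative
risk at concentration x is exactly g(x) - g(x_ref).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

MET_COLUMNS = ("tavg", "rh", "wind", "dtr", "precip")


@dataclass(frozen=True)
class TrueSurface:
    """Known exposure-lag-response surface f(x, l) on the log-RR scale.

    ``family`` names the parameterization; the default "quadratic_geometric"
    is g(x) * w(l) with g an inverted-U quadratic and w a geometric lag
    decay normalized so that sum_l w(l) = 1.  ``f(x_ref, l) = 0`` for all l
    by construction.
    """

    family: str = "quadratic_geometric"
    amplitude: float = 0.15
    center: float = 40.0
    halfwidth: float = 35.0
    lag_decay: float = 0.7
    max_lag: int = 14
    x_ref: float = 45.0

    def _g(self, x):
        s = 1.0 - ((np.asarray(x, dtype=float) - self.center) / self.halfwidth) ** 2
        s_ref = 1.0 - ((self.x_ref - self.center) / self.halfwidth) ** 2
        return self.amplitude * (s - s_ref)

    def lag_weights(self) -> np.ndarray:
        """w(l), l = 0..max_lag, geometric decay summing to 1."""
        w = self.lag_decay ** np.arange(self.max_lag + 1, dtype=float)
        return w / w.sum()

    def f(self, x, l) -> np.ndarray:
        """Log-RR contribution of exposure x at lag l (vectorized)."""
        if self.family == "null":
            return np.zeros(np.broadcast(np.asarray(x), np.asarray(l)).shape)
        w = self.lag_weights()
        return self._g(x) * w[np.asarray(l, dtype=int)]

    def cumulative(self, x) -> np.ndarray:
        """Overall cumulative log RR vs x_ref: sum over lags 0..max_lag."""
        if self.family == "null":
            return np.zeros(np.shape(np.asarray(x, dtype=float)))
        return self._g(x)

    @staticmethod
    def null(max_lag: int = 14, x_ref: float = 45.0) -> "TrueSurface":
        """A surface that is identically zero (no pollutant effect)."""
        return TrueSurface(family="null", amplitude=0.0, max_lag=max_lag,
                           x_ref=x_ref)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated multi-city panel.

    Defaults describe a desk-scale but realistic setting: three cities,
    four years of daily data, ~15 admissions per city-day, mild annual
    seasonality in the log rate, a seasonal AR(1) pollutant around
    45 μg/m³, overdispersion 1.2, and the inverted-U times geometric-decay
    truth above.
    """

    n_cities: int = 3
    start_date: str = "2016-01-01"
    end_date: str = "2019-12-31"
    baseline_log_rate: tuple[float, ...] | None = None  # alpha_j per city
    default_log_rate: float = float(np.log(15.0))
    city_log_rate_spread: float = 0.2
    seasonal_amplitudes: tuple[float, ...] = (0.15, 0.05)  # per harmonic, log scale
    covariate_effects: dict[str, float] = field(
        default_factory=lambda: {"tavg": -0.005}
    )
    pollutant_mean: float = 45.0
    pollutant_seasonal_amplitude: float = 15.0
    pollutant_ar: float = 0.7
    pollutant_sd: float = 8.0
    overdispersion: float = 1.2
    surface: TrueSurface = field(default_factory=TrueSurface)
    seed: int = 0

    def __post_init__(self):
        if self.overdispersion < 1.0:
            raise ValueError(
                f"overdispersion must be >= 1, got {self.overdispersion}"
            )
        if not (0.0 <= self.pollutant_ar < 1.0):
            raise ValueError(
                f"AR(1) coefficient must lie in [0, 1), got {self.pollutant_ar}"
            )
        n_days = (
            pd.Timestamp(self.end_date) - pd.Timestamp(self.start_date)
        ).days + 1
        if n_days < self.surface.max_lag + 1:
            raise ValueError(
                f"date range of {n_days} days shorter than the lag window "
                f"({self.surface.max_lag + 1} days)"
            )

    def city_names(self) -> list[str]:
        return [f"city{j:02d}" for j in range(self.n_cities)]

    def alphas(self) -> np.ndarray:
        if self.baseline_log_rate is not None:
            if len(self.baseline_log_rate) != self.n_cities:
                raise ValueError("one baseline log rate per city required")
            return np.asarray(self.baseline_log_rate, dtype=float)
        # deterministic spread around the default rate
        offsets = np.linspace(
            -self.city_log_rate_spread, self.city_log_rate_spread, self.n_cities
        ) if self.n_cities > 1 else np.zeros(1)
        return self.default_log_rate + offsets


def _pollutant_series(cfg: SimConfig, n: int, rng: np.random.Generator,
                      n_pad: int) -> np.ndarray:
    """Seasonal + AR(1) pollutant, padded with n_pad pre-period days.

    The pre-period history is held at the process mean so the first panel
    day has a complete lag window; the series is floored at 1 μg/m³ to
    stay positive.
    """
    t = np.arange(-n_pad, n)
    # winter peak: cosine maximal at day-of-year ~ 15
    seasonal = cfg.pollutant_seasonal_amplitude * np.cos(
        2.0 * np.pi * (t - 15) / 365.25
    )
    ar = np.zeros(n_pad + n)
    eps = rng.normal(0.0, cfg.pollutant_sd, size=n_pad + n)
    innov_scale = np.sqrt(1.0 - cfg.pollutant_ar**2)
    for i in range(1, n_pad + n):
        ar[i] = cfg.pollutant_ar * ar[i - 1] + innov_scale * eps[i]
    x = cfg.pollutant_mean + seasonal + ar
    x[:n_pad] = cfg.pollutant_mean  # stationary-mean padding
    return np.maximum(x, 1.0)


def _meteorology(n: int, rng: np.random.Generator) -> pd.DataFrame:
    """Independent seasonal sinusoids plus noise for the five covariates.

    DTR is daily tmax minus tmin: a half-range is simulated and applied
    symmetrically around the average temperature, so dtr >= 0 always.
    """
    t = np.arange(n)
    doy = 2.0 * np.pi * t / 365.25
    tavg = 12.0 - 11.0 * np.cos(doy) + rng.normal(0, 3.0, n)
    half_range = np.abs(4.0 + 1.5 * np.cos(doy) + rng.normal(0, 1.2, n)) / 2.0
    tmax = tavg + half_range
    tmin = tavg - half_range
    dtr = tmax - tmin
    rh = np.clip(65.0 + 10.0 * np.sin(doy) + rng.normal(0, 8.0, n), 0.0, 100.0)
    wind = np.maximum(2.5 + 0.5 * np.sin(doy) + rng.normal(0, 0.8, n), 0.1)
    wet = rng.random(n) < 0.3
    precip = np.where(wet, rng.exponential(8.0, n), 0.0)
    return pd.DataFrame(
        {"tavg": tavg, "rh": rh, "wind": wind, "dtr": dtr, "precip": precip}
    )


def _draw_counts(mu: np.ndarray, phi: float,
                 rng: np.random.Generator) -> np.ndarray:
    """Counts with mean mu and variance ~ phi*mu.

    Negative binomial with size = mu / (phi - 1) has variance
    mu + mu^2/size = phi*mu; at phi = 1 this degenerates to Poisson.
    """
    if phi <= 1.0 + 1e-12:
        return rng.poisson(mu)
    size = mu / (phi - 1.0)
    return rng.negative_binomial(size, size / (size + mu))


def simulate_panel(config: SimConfig) -> tuple[pd.DataFrame, TrueSurface]:
    """Simulate the merged multi-city daily panel.

    Returns a DataFrame with one row per (city, date) and columns
    ``city, date, y, x, tavg, rh, wind, dtr, precip``, plus the
    ground-truth surface.  Identical config (including seed) gives
    bit-identical output.
    """
    surf = config.surface
    dates = pd.date_range(config.start_date, config.end_date, freq="D")
    n = len(dates)
    L = surf.max_lag
    alphas = config.alphas()
    w = surf.lag_weights() if surf.family != "null" else np.zeros(L + 1)

    rng = np.random.default_rng(config.seed)
    frames = []
    for j, city in enumerate(config.city_names()):
        x_pad = _pollutant_series(config, n, rng, n_pad=L)
        met = _meteorology(n, rng)
        # lag-distributed pollutant contribution on the log scale
        if surf.family == "null":
            lag_term = np.zeros(n)
        else:
            g = surf._g(x_pad)
            lag_term = np.convolve(g, w, mode="full")[L : L + n]
        t = np.arange(n)
        seasonal = np.zeros(n)
        for k, amp in enumerate(config.seasonal_amplitudes, start=1):
            seasonal += amp * np.cos(2.0 * np.pi * k * t / 365.0)
        cov_term = np.zeros(n)
        for name, gamma in config.covariate_effects.items():
            cov_term += gamma * met[name].to_numpy()
        mu = np.exp(alphas[j] + lag_term + cov_term + seasonal)
        y = _draw_counts(mu, config.overdispersion, rng)
        frame = pd.DataFrame({"city": city, "date": dates, "y": y,
                              "x": x_pad[L:]})
        frames.append(pd.concat([frame, met], axis=1))
    panel = pd.concat(frames, ignore_index=True)
    return panel, surf


def write_panel_tables(
    panel: pd.DataFrame,
    out_dir,
    config: SimConfig | None = None,
    disease: str = "synthetic",
    pollutant: str = "pm10",
) -> dict[str, Path]:
    """Write the three-table CSV layout plus a JSON truth sidecar.

    The layout matches what :mod:`dlnmkit.panel_io` reads: admissions
    (date, city, disease, count), air quality (date, city, pollutant,
    value) and meteorology (date, city, tavg, rh, wind, dtr, precip).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    panel = panel.reset_index(drop=True)
    date_str = pd.to_datetime(panel["date"]).dt.strftime("%Y-%m-%d")

    adm = pd.DataFrame({"date": date_str, "city": panel["city"],
                        "disease": disease, "count": panel["y"]})
    air = pd.DataFrame({"date": date_str, "city": panel["city"],
                        "pollutant": pollutant, "value": panel["x"]})
    met = pd.concat(
        [pd.DataFrame({"date": date_str, "city": panel["city"]}),
         panel[list(MET_COLUMNS)].reset_index(drop=True)],
        axis=1,
    )
    paths = {
        "admissions": out / "admissions.csv",
        "airquality": out / "airquality.csv",
        "meteorology": out / "meteorology.csv",
    }
    adm.to_csv(paths["admissions"], index=False)
    air.to_csv(paths["airquality"], index=False)
    met.to_csv(paths["meteorology"], index=False)
    if config is not None:
        sidecar = out / "truth.json"
        payload = asdict(config)
        payload["surface"] = asdict(config.surface)
        sidecar.write_text(json.dumps(payload, indent=2, default=str))
        paths["truth"] = sidecar
    return paths
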