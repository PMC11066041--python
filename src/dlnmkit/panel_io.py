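"""Reading, validating and merging the three daily input tables.

An analysis panel is one disease x one pollutant x one city: daily
admission counts joined with the pollutant concentration and the five
meteorological covariates on (date, city).  Validation is strict — schema
problems, duplicate keys, calendar gaps and impossible values all raise
typed errors rather than silently dropping rows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic_data import MET_COLUMNS

REQUIRED = {
    "admissions": ["date", "city", "disease", "count"],
    "airquality": ["date", "city", "pollutant", "value"],
    "meteorology": ["date", "city", *MET_COLUMNS],
}


class SchemaError(ValueError):
    """A required column is missing."""


class IntegrityError(ValueError):
    """Duplicate keys or calendar gaps in an input table."""


class ValidationError(ValueError):
    """A value violates its domain (negative count, humidity > 100, ...)."""


@dataclass(frozen=True)
class PeriodSplit:
    """Two disjoint date intervals, e.g. pre-pandemic vs pandemic year."""

    pre_start: str = "2016-01-01"
    pre_end: str = "2019-12-31"
    post_start: str = "2020-01-01"
    post_end: str = "2020-12-31"

    def __post_init__(self):
        pre = (pd.Timestamp(self.pre_start), pd.Timestamp(self.pre_end))
        post = (pd.Timestamp(self.post_start), pd.Timestamp(self.post_end))
        if pre[0] > pre[1] or post[0] > post[1]:
            raise ValueError("each interval must have start <= end")
        if pre[1] >= post[0]:
            raise ValueError("pre interval must precede the post interval")


def _read_csv(path, table: str) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED[table] if c not in df.columns]
    if missing:
        raise SchemaError(f"{table} table {path} missing column(s): {missing}")
    df["date"] = pd.to_datetime(df["date"], format="%Y-%m-%d")
    return df


def _check_dates(dates: pd.Series, label: str):
    if dates.duplicated().any():
        dups = dates[dates.duplicated()].dt.strftime("%Y-%m-%d").unique()
        raise IntegrityError(f"duplicate (date, city) keys in {label}: {list(dups)}")
    full = pd.date_range(dates.min(), dates.max(), freq="D")
    missing = full.difference(pd.DatetimeIndex(dates))
    if len(missing):
        raise IntegrityError(
            f"gap in the daily date sequence of {label}; missing dates: "
            f"{[d.strftime('%Y-%m-%d') for d in missing]}"
        )


def read_panel(
    admissions_path,
    airquality_path,
    meteorology_path,
    city: str,
    disease: str,
    pollutant: str,
    interpolate_short_gaps: bool = False,
) -> pd.DataFrame:
    """Read and merge the three tables into one city's analysis panel.

    Inner-joins on (date, city) after filtering to the requested city,
    disease and pollutant; returns rows sorted by date with columns
    ``city, date, y, x, tavg, rh, wind, dtr, precip``.

    ``interpolate_short_gaps`` linearly fills pollutant/meteorology gaps of
    at most 2 consecutive days; by default any missing value is an error.
    """
    adm = _read_csv(admissions_path, "admissions")
    adm = adm[(adm["city"] == city) & (adm["disease"] == disease)]
    air = _read_csv(airquality_path, "airquality")
    air = air[(air["city"] == city) & (air["pollutant"] == pollutant)]
    met = _read_csv(meteorology_path, "meteorology")
    met = met[met["city"] == city]
    for df, label in ((adm, "admissions"), (air, "airquality"),
                      (met, "meteorology")):
        if df.empty:
            raise IntegrityError(
                f"no rows for city={city!r} in the {label} table "
                f"(disease={disease!r}, pollutant={pollutant!r})"
            )
        _check_dates(df["date"], f"{label} ({city})")

    panel = (
        adm[["date", "count"]]
        .merge(air[["date", "value"]], on="date", how="inner")
        .merge(met[["date", *MET_COLUMNS]], on="date", how="inner")
        .sort_values("date")
        .reset_index(drop=True)
    )
    if panel.empty:
        raise IntegrityError("the three tables share no (date, city) keys")
    _check_dates(panel["date"], f"merged panel ({city})")
    panel = panel.rename(columns={"count": "y", "value": "x"})
    panel.insert(0, "city", city)

    value_cols = ["x", *MET_COLUMNS]
    if interpolate_short_gaps:
        for c in value_cols:
            filled = panel[c].interpolate(limit=2, limit_area="inside")
            panel[c] = filled
    if panel[["y", *value_cols]].isna().any().any():
        bad = [c for c in ["y", *value_cols] if panel[c].isna().any()]
        raise ValidationError(f"missing values in column(s): {bad}")

    y = panel["y"].to_numpy()
    if np.any(y < 0) or np.any(y != np.round(y)):
        raise ValidationError("admission counts must be non-negative integers")
    panel["y"] = y.astype(int)
    checks = [
        ("x", panel["x"] < 0, "pollutant concentration must be >= 0"),
        ("rh", (panel["rh"] < 0) | (panel["rh"] > 100),
         "relative humidity must lie in [0, 100]"),
        ("dtr", panel["dtr"] < 0, "diurnal temperature range must be >= 0"),
        ("precip", panel["precip"] < 0, "precipitation must be >= 0"),
    ]
    for col, bad, msg in checks:
        if bad.any():
            raise ValidationError(f"{msg} (column {col!r})")
    return panel


def split_periods(
    panel: pd.DataFrame, split: PeriodSplit = PeriodSplit()
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition a panel into the pre and post intervals of ``split``."""
    d = pd.to_datetime(panel["date"])
    pre_mask = (d >= pd.Timestamp(split.pre_start)) & (
        d <= pd.Timestamp(split.pre_end)
    )
    post_mask = (d >= pd.Timestamp(split.post_start)) & (
        d <= pd.Timestamp(split.post_end)
    )
    if not pre_mask.any():
        raise IntegrityError(
            f"panel has no rows in the pre period "
            f"{split.pre_start}..{split.pre_end}"
        )
    if not post_mask.any():
        raise IntegrityError(
            f"panel has no rows in the post period "
            f"{split.post_start}..{split.post_end}"
        )
    return (
        panel[pre_mask].reset_index(drop=True),
        panel[post_mask].reset_index(drop=True),
    )
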