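"""Reduce a fitted cross-basis block to relative-risk summaries.

A fitted DLNM stores the exposure-lag-response surface as a coefficient
block over the cross-basis columns.  This module turns that block (from a
single city fit or a pooled meta-analysis estimate) into the three standard
summaries, all expressed as relative risks against a reference
concentration x_ref (by convention the reference city's median):

* the overall cumulative exposure-response curve (effects summed over the
  whole lag window 0..L);
* the full exposure-lag surface as a long-format table;
* per-lag contrasts of extreme concentrations (default 90th and 10th
  percentile, each versus the median).

Standard errors come from the delta method: log RR is linear in the
coefficient block, se = sqrt(c' V c); 95% limits are Wald on the log scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .basis import CrossBasis

Z95 = 1.959963984540054


class ShapeError(ValueError):
    """Coefficient block does not match the cross-basis specification."""


@dataclass(frozen=True)
class Association:
    """An exposure-response or lag-response summary on the RR scale."""

    kind: str  # overall_cumulative | lag_specific | surface
    table: pd.DataFrame
    x_ref: float

    def __post_init__(self):
        if not ((self.table["rr_low"] <= self.table["rr"] + 1e-12).all()
                and (self.table["rr"] <= self.table["rr_high"] + 1e-12).all()):
            raise AssertionError("confidence limits must bracket the estimate")


@dataclass(frozen=True)
class ExtremeContrast:
    """Per-lag RRs of extreme concentrations versus the median."""

    table: pd.DataFrame  # columns: lag, contrast, rr, rr_low, rr_high
    quantiles: dict[str, float]


def _block(fit_or_pooled, spec):
    """Extract (beta, vcov) for the cross-basis block from a city fit or a
    pooled estimate."""
    if hasattr(fit_or_pooled, "block"):  # QPFit
        beta, vcov = fit_or_pooled.block("crossbasis")
    else:  # PooledEstimate-like: beta_pooled / vcov_pooled attributes
        beta, vcov = fit_or_pooled.beta_pooled, fit_or_pooled.vcov_pooled
    beta = np.asarray(beta, dtype=float)
    vcov = np.asarray(vcov, dtype=float)
    d = spec.n_columns
    if beta.shape != (d,) or vcov.shape != (d, d):
        raise ShapeError(
            f"cross-basis block of dimension {beta.shape} does not match "
            f"spec df_p*df_l={d}"
        )
    return beta, vcov


def _rr_frame(first_cols: dict, log_rr, se) -> pd.DataFrame:
    log_rr = np.asarray(log_rr, dtype=float)
    se = np.asarray(se, dtype=float)
    return pd.DataFrame({
        **first_cols,
        "log_rr": log_rr,
        "se": se,
        "rr": np.exp(log_rr),
        "rr_low": np.exp(log_rr - Z95 * se),
        "rr_high": np.exp(log_rr + Z95 * se),
    })


def _contrast_rows(cb: CrossBasis, x, lag_rows: np.ndarray) -> np.ndarray:
    """Rows c(x) with column order matching the cross-basis (predictor index
    outermost): c = R(x) (x) lag_rows, one row per exposure value."""
    R = cb.predictor_basis(x)
    return np.einsum("ij,k->ijk", R, lag_rows).reshape(R.shape[0], -1)


def default_grid(exposure, n: int = 100) -> np.ndarray:
    """Equally spaced evaluation grid over an observed exposure range."""
    x = np.asarray(exposure, dtype=float)
    return np.linspace(x.min(), x.max(), n)


def overall_cumulative(fit, cb: CrossBasis, grid, x_ref: float) -> Association:
    """Overall cumulative exposure-response curve.

    For each grid concentration x, the log RR sums the lag-specific
    contributions over the full window 0..L and subtracts the same sum at
    x_ref, so the curve is exactly 1 at the reference.
    """
    beta, vcov = _block(fit, cb.spec)
    grid = np.asarray(grid, dtype=float)
    csum = cb.lag_basis().sum(axis=0)  # sum_l C(l), length df_l
    c_x = _contrast_rows(cb, grid, csum)
    c_ref = _contrast_rows(cb, [x_ref], csum)
    c = c_x - c_ref
    log_rr = c @ beta
    se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", c, vcov, c), 0.0))
    return Association(
        kind="overall_cumulative",
        table=_rr_frame({"x": grid}, log_rr, se),
        x_ref=float(x_ref),
    )


def exposure_lag_surface(fit, cb: CrossBasis, grid, lags=None,
                         x_ref: float | None = None) -> Association:
    """Exposure-lag RR surface as a long-format table (x, lag, rr, ci).

    Each cell is the lag-l log RR of concentration x versus x_ref.
    """
    if x_ref is None:
        raise ValueError("x_ref is required")
    beta, vcov = _block(fit, cb.spec)
    grid = np.asarray(grid, dtype=float)
    if lags is None:
        lags = np.arange(cb.spec.max_lag + 1)
    lags = np.asarray(lags)
    lag_mat = cb.lag_basis()[lags]  # rows C(l)
    rows_x, rows_l, vals, ses = [], [], [], []
    R_ref = cb.predictor_basis([x_ref])
    for li, l in enumerate(lags):
        c_x = _contrast_rows(cb, grid, lag_mat[li])
        c_ref = np.einsum("ij,k->ijk", R_ref, lag_mat[li]).reshape(1, -1)
        c = c_x - c_ref
        vals.append(c @ beta)
        ses.append(np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", c, vcov, c), 0.0)))
        rows_x.append(grid)
        rows_l.append(np.full(len(grid), l))
    table = _rr_frame(
        {"x": np.concatenate(rows_x), "lag": np.concatenate(rows_l)},
        np.concatenate(vals), np.concatenate(ses),
    )
    return Association(kind="surface", table=table, x_ref=float(x_ref))


def extreme_effects(fit, cb: CrossBasis, exposure,
                    levels=(0.10, 0.50, 0.90)) -> ExtremeContrast:
    """Per-lag RRs of the extreme-percentile concentrations vs the median.

    ``levels`` is (low, reference, high); quantiles use the
    linear-interpolation convention.
    """
    x = np.asarray(exposure, dtype=float)
    if len(x) == 0:
        raise ValueError("exposure series is empty")
    lo_q, ref_q, hi_q = levels
    q_lo, q_ref, q_hi = np.quantile(x, [lo_q, ref_q, hi_q])
    if x.min() == x.max():
        raise ValueError("degenerate exposure series: quantile contrast undefined")
    beta, vcov = _block(fit, cb.spec)
    lag_mat = cb.lag_basis()
    lags = np.arange(cb.spec.max_lag + 1)
    frames = []
    for label, q in (("high_vs_median", q_hi), ("low_vs_median", q_lo)):
        R_diff = cb.predictor_basis([q]) - cb.predictor_basis([q_ref])
        # per-lag contrast rows: R_diff (x) C(l)
        c = np.einsum("j,lk->ljk", R_diff[0], lag_mat).reshape(len(lags), -1)
        log_rr = c @ beta
        se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", c, vcov, c), 0.0))
        frame = _rr_frame({"lag": lags}, log_rr, se)
        frame.insert(1, "contrast", label)
        frames.append(frame)
    return ExtremeContrast(
        table=pd.concat(frames, ignore_index=True),
        quantiles={"low": float(q_lo), "median": float(q_ref),
                   "high": float(q_hi)},
    )
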