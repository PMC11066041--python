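"""QAIC-driven model optimization for single-pollutant DLNMs.

The search crosses best-subset enumeration over the meteorological
covariates (2^k subsets) with a hyperparameter grid over the maximum lag L
and the two spline degrees of freedom (df_p, df_l).  Every candidate is fit
on a common usable-day window (full lag history for the *largest* L in the
grid) so QAIC values are comparable, using a shared reference dispersion
estimated from the most complex candidate.  The winner is chosen by the
parsimony rule: among candidates within 2 QAIC units of the minimum, the
simplest model is selected.

Defaults mirror the published search: maximum lag 7..31 days, df_p and
df_l each 2..5, and the five meteorological covariates.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .basis import CrossBasisSpec, build_cross_basis, fourier_basis
from .qp_glm import QPFit, fit_quasipoisson, qaic
from .synthetic_data import MET_COLUMNS

log = logging.getLogger(__name__)

QAIC_PARSIMONY_THRESHOLD = 2.0


class SpecError(ValueError):
    pass


@dataclass(frozen=True)
class SearchGrid:
    """Hyperparameter and covariate search space."""

    max_lags: tuple[int, ...] = tuple(range(7, 32))
    df_p_values: tuple[int, ...] = (2, 3, 4, 5)
    df_l_values: tuple[int, ...] = (2, 3, 4, 5)
    covariates: tuple[str, ...] = MET_COLUMNS

    def __post_init__(self):
        for name, vals in (("max_lags", self.max_lags),
                           ("df_p_values", self.df_p_values),
                           ("df_l_values", self.df_l_values)):
            if len(vals) == 0:
                raise SpecError(f"empty grid component: {name}")
        if min(self.max_lags) < 1:
            raise SpecError("max lag must be >= 1")
        if min(self.df_p_values) < 2 or min(self.df_l_values) < 2:
            raise SpecError("spline degrees of freedom must be >= 2")

    @property
    def n_candidates(self) -> int:
        return (2 ** len(self.covariates) * len(self.max_lags)
                * len(self.df_p_values) * len(self.df_l_values))


@dataclass
class CandidateModel:
    """One (covariate subset, L, df_p, df_l) configuration."""

    covariate_mask: tuple[str, ...]
    max_lag: int
    df_p: int
    df_l: int
    order: int = 0
    qaic: float = float("nan")
    fit: QPFit | None = None
    failure: str | None = None

    @property
    def spec(self) -> CrossBasisSpec:
        return CrossBasisSpec(max_lag=self.max_lag, df_p=self.df_p,
                              df_l=self.df_l)

    @property
    def complexity(self) -> tuple:
        """Simplicity ordering: covariates, then df sum, then lag, then QAIC."""
        return (len(self.covariate_mask), self.df_p + self.df_l,
                self.max_lag, self.qaic, self.order)

    @property
    def n_params(self) -> int:
        return self.fit.n_params if self.fit is not None else -1


def enumerate_candidates(grid: SearchGrid) -> list[CandidateModel]:
    """All candidate shells, in deterministic order.

    Covariate subsets are enumerated as a binary counter over the covariate
    list (empty set first), crossed lexicographically with (L, df_p, df_l).
    """
    shells = []
    order = 0
    for bits in range(2 ** len(grid.covariates)):
        mask = tuple(c for i, c in enumerate(grid.covariates) if bits >> i & 1)
        for L, dfp, dfl in itertools.product(
            grid.max_lags, grid.df_p_values, grid.df_l_values
        ):
            shells.append(CandidateModel(
                covariate_mask=mask, max_lag=L, df_p=dfp, df_l=dfl,
                order=order,
            ))
            order += 1
    return shells


def select_best(candidates: list[CandidateModel]) -> CandidateModel:
    """Apply the parsimony rule to fitted candidates.

    Among candidates whose QAIC lies within ``QAIC_PARSIMONY_THRESHOLD`` of
    the minimum, the simplest wins (fewest covariates, then smallest
    df_p + df_l, then smallest L; QAIC and enumeration order break ties
    deterministically).
    """
    live = [c for c in candidates if c.failure is None]
    if not live:
        raise ValueError("no successfully fitted candidates to select from")
    if any(not np.isfinite(c.qaic) for c in live):
        raise ValueError("all candidates must carry a finite QAIC")
    qmin = min(c.qaic for c in live)
    near = [c for c in live if c.qaic - qmin < QAIC_PARSIMONY_THRESHOLD]
    return min(near, key=lambda c: c.complexity)


def design_for_candidate(
    panel: pd.DataFrame,
    cand: CandidateModel,
    common_max_lag: int,
    seasonal_harmonics: int = 6,
    seasonal_period: float = 365.0,
):
    """Assemble (y, X, column_map, crossbasis) for one candidate.

    The response window drops the first ``common_max_lag`` days so every
    candidate in a search is fit to the identical observations.
    """
    x = panel["x"].to_numpy(dtype=float)
    y_all = panel["y"].to_numpy()
    n = len(panel)
    if n <= common_max_lag:
        raise ValueError("panel shorter than the largest lag window")
    cb = build_cross_basis(x, cand.spec)
    window = np.arange(common_max_lag, n)
    # cb rows start at cand.max_lag; re-index onto the common window
    cb_rows = cb.matrix[window - cand.max_lag]
    blocks = [np.ones((len(window), 1)), cb_rows]
    names = ["intercept"] + [f"cb{j}" for j in range(cb_rows.shape[1])]
    col_map = {"intercept": slice(0, 1),
               "crossbasis": slice(1, 1 + cb_rows.shape[1])}
    pos = 1 + cb_rows.shape[1]
    if cand.covariate_mask:
        cov = panel.iloc[window][list(cand.covariate_mask)].to_numpy(dtype=float)
        blocks.append(cov)
        names += list(cand.covariate_mask)
        col_map["covariates"] = slice(pos, pos + cov.shape[1])
        pos += cov.shape[1]
    seas = fourier_basis(window, m=seasonal_period, K=seasonal_harmonics)
    blocks.append(seas.matrix)
    names += [f"s{k}" for k in range(seas.matrix.shape[1])]
    col_map["seasonal"] = slice(pos, pos + seas.matrix.shape[1])
    X = np.hstack(blocks)
    return y_all[window], X, col_map, names, cb


def most_complex(grid: SearchGrid) -> CandidateModel:
    """The reference candidate supplying the shared dispersion."""
    return CandidateModel(
        covariate_mask=tuple(grid.covariates),
        max_lag=max(grid.max_lags),
        df_p=max(grid.df_p_values),
        df_l=max(grid.df_l_values),
    )


def optimize(
    panel: pd.DataFrame,
    grid: SearchGrid = SearchGrid(),
    seasonal_harmonics: int = 6,
    seasonal_period: float = 365.0,
) -> tuple[CandidateModel, list[CandidateModel]]:
    """Run the full QAIC search on one city's panel.

    Returns the selected candidate (with its fit attached) and the complete
    fitted candidate list (the QAIC table).  Candidates whose fit fails
    numerically are excluded with the reason recorded on the shell.  The
    result is a pure function of (panel, grid, seasonal spec); evaluation
    order of the candidates does not matter.
    """
    common_L = max(grid.max_lags)
    ref = most_complex(grid)
    y_ref, X_ref, map_ref, names_ref, _ = design_for_candidate(
        panel, ref, common_L, seasonal_harmonics, seasonal_period
    )
    ref_fit = fit_quasipoisson(y_ref, X_ref, map_ref, names_ref)
    phi_ref = ref_fit.dispersion
    log.info("reference dispersion phi=%.4f from the most complex candidate",
             phi_ref)

    shells = enumerate_candidates(grid)
    n_fit = None
    for cand in shells:
        try:
            y, X, col_map, names, _ = design_for_candidate(
                panel, cand, common_L, seasonal_harmonics, seasonal_period
            )
            fit = fit_quasipoisson(y, X, col_map, names)
        except Exception as exc:  # noqa: BLE001 - candidate-level isolation
            cand.failure = f"{type(exc).__name__}: {exc}"
            log.warning("candidate %s excluded: %s", cand, cand.failure)
            continue
        if n_fit is None:
            n_fit = fit.n_obs
        assert fit.n_obs == n_fit, "candidates must share one fitting window"
        cand.fit = fit
        cand.qaic = qaic(fit, phi_ref)
        log.debug("candidate mask=%s L=%d df_p=%d df_l=%d QAIC=%.2f",
                  cand.covariate_mask, cand.max_lag, cand.df_p, cand.df_l,
                  cand.qaic)
    best = select_best(shells)
    return best, shells


def frozen_grid(best: CandidateModel, covariates: tuple[str, ...] | None = None
                ) -> SearchGrid:
    """A singleton grid that re-fits other cities at the selected
    hyperparameters and covariate subset (reference-city transfer)."""
    return SearchGrid(
        max_lags=(best.max_lag,),
        df_p_values=(best.df_p,),
        df_l_values=(best.df_l,),
        covariates=covariates if covariates is not None else best.covariate_mask,
    )


def fit_frozen(
    panel: pd.DataFrame,
    best: CandidateModel,
    seasonal_harmonics: int = 6,
    seasonal_period: float = 365.0,
):
    """Fit one city at frozen hyperparameters (no selection re-run).

    Returns (fit, crossbasis).  The fitting window drops ``best.max_lag``
    days, the candidate's own lag window.
    """
    cand = replace(best, fit=None, qaic=float("nan"), failure=None)
    y, X, col_map, names, cb = design_for_candidate(
        panel, cand, cand.max_lag, seasonal_harmonics, seasonal_period
    )
    fit = fit_quasipoisson(y, X, col_map, names)
    return fit, cb
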