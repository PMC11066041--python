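"""Quasi-Poisson GLM fitting and QAIC.

The model is a log-linear count regression with Poisson mean structure and
variance inflated by a dispersion factor, V(Y) = phi * mu.  Point estimates
coincide with Poisson maximum likelihood; the dispersion phi (Pearson
chi-square over residual degrees of freedom) rescales the covariance matrix
only.  Model comparison uses QAIC, the quasi-likelihood analogue of AIC:

    QAIC = -2 * loglik_Poisson / phi_ref + 2 * p

with a *shared* reference dispersion ``phi_ref`` supplied by the caller so
that candidate models are ranked on a common scale (model_selection takes
phi_ref from the most complex candidate in a search).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm

#: dispersion floor for numerically perfect fits, keeps QAIC finite
PHI_FLOOR = 1e-8


class RankError(ValueError):
    """Design matrix is rank deficient."""


class ConvergenceError(RuntimeError):
    """IRLS failed to converge within the iteration budget."""


@dataclass
class QPFit:
    """A fitted quasi-Poisson GLM.

    Attributes
    ----------
    coefficients : ndarray
        Point estimates (identical to Poisson ML).
    vcov : ndarray
        Dispersion-scaled covariance: phi * (Fisher information)^-1.
    dispersion : float
        Pearson chi-square / (n - p).
    poisson_loglik : float
        Poisson log-likelihood at the fitted mean (including the y!
        normalizing term).
    n_params : int
        Number of estimated regression coefficients (intercept included;
        the dispersion is not counted).
    column_map : dict
        Maps block names (e.g. "intercept", "crossbasis", "covariates",
        "seasonal") to column slices of the design matrix.
    """

    coefficients: np.ndarray
    vcov: np.ndarray
    dispersion: float
    poisson_loglik: float
    n_params: int
    n_obs: int
    column_map: dict[str, slice] = field(default_factory=dict)

    def block(self, name: str) -> tuple[np.ndarray, np.ndarray]:
        """Return (coefficients, vcov) restricted to a named column block."""
        s = self.column_map[name]
        return self.coefficients[s], self.vcov[s, s]

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.vcov))


def _check_rank(design: np.ndarray, names=None):
    n, p = design.shape
    if n <= p:
        raise RankError(f"more columns ({p}) than observations ({n})")
    # pivoted QR exposes (near-)collinear columns by tiny R diagonals
    from scipy.linalg import qr

    _, r, piv = qr(design, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(n, p) * np.finfo(float).eps
    bad = piv[diag < tol]
    if len(bad):
        labels = (
            [names[i] for i in bad] if names is not None else [str(i) for i in bad]
        )
        raise RankError(f"design is rank deficient; collinear columns: {labels}")


def fit_quasipoisson(
    y,
    design,
    column_map: dict[str, slice] | None = None,
    column_names=None,
    maxiter: int = 100,
    tol: float = 1e-9,
) -> QPFit:
    """Fit the quasi-Poisson log-linear model by IRLS.

    ``design`` must include the intercept column explicitly if one is
    wanted.  Convergence is declared when the relative deviance change
    falls below ``tol``.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(design, dtype=float)
    if y.ndim != 1 or X.ndim != 2 or X.shape[0] != len(y):
        raise ValueError("design rows must align with the response vector")
    if np.any(y < 0) or np.any(y != np.round(y)):
        raise ValueError("response must be non-negative integer counts")
    _check_rank(X, column_names)

    model = sm.GLM(y, X, family=sm.families.Poisson())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(method="IRLS", maxiter=maxiter, tol=tol)
    if not res.converged:
        raise ConvergenceError(
            f"IRLS did not converge in {maxiter} iterations "
            f"(final deviance {res.deviance:.6g})"
        )

    n, p = X.shape
    mu = res.fittedvalues
    pearson = float(np.sum((y - mu) ** 2 / mu))
    phi = pearson / (n - p)
    if phi < PHI_FLOOR:
        warnings.warn(
            "near-perfect fit: Pearson dispersion floored at "
            f"{PHI_FLOOR:g}", RuntimeWarning, stacklevel=2,
        )
        phi = PHI_FLOOR
    vcov = phi * np.asarray(res.normalized_cov_params)
    return QPFit(
        coefficients=np.asarray(res.params),
        vcov=vcov,
        dispersion=phi,
        poisson_loglik=float(res.llf),
        n_params=p,
        n_obs=n,
        column_map=column_map or {"all": slice(0, p)},
    )


def qaic(fit: QPFit, phi_ref: float) -> float:
    """Quasi-AIC of a fit under a caller-supplied reference dispersion."""
    if phi_ref <= 0:
        raise ValueError(f"reference dispersion must be positive, got {phi_ref}")
    return -2.0 * fit.poisson_loglik / phi_ref + 2.0 * fit.n_params
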