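"""Fixed-effect multivariate meta-analysis of cross-basis coefficients.

Each city contributes the coefficient vector of its cross-basis block and
the matching covariance matrix (all cities having been fit at identical
hyperparameters).  Pooling is generalized inverse-variance weighting under
a common-effect assumption:

    beta_pooled = (sum_j V_j^-1)^-1 (sum_j V_j^-1 beta_j)
    vcov_pooled = (sum_j V_j^-1)^-1

with Cochran's multivariate Q = sum_j (beta_j - beta_pooled)' V_j^-1
(beta_j - beta_pooled) as a heterogeneity diagnostic.  Inversions go
through Cholesky solves, never explicit inverses of ill-conditioned
matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve

COND_LIMIT = 1e12


class ConditioningError(ValueError):
    """A study covariance matrix is numerically singular."""


@dataclass(frozen=True)
class StudyEstimate:
    """One city's cross-basis coefficient block and covariance."""

    label: str
    beta: np.ndarray
    vcov: np.ndarray

    def __post_init__(self):
        beta = np.asarray(self.beta, dtype=float)
        vcov = np.asarray(self.vcov, dtype=float)
        object.__setattr__(self, "beta", beta)
        object.__setattr__(self, "vcov", vcov)
        d = beta.shape[0]
        if beta.ndim != 1 or vcov.shape != (d, d):
            raise ValueError(
                f"study {self.label!r}: vcov shape {vcov.shape} does not "
                f"match coefficient length {d}"
            )


@dataclass(frozen=True)
class PooledEstimate:
    """The pooled coefficient block, its covariance, weights and Q."""

    beta_pooled: np.ndarray
    vcov_pooled: np.ndarray
    weights: dict[str, np.ndarray] = field(repr=False, default_factory=dict)
    q_statistic: float = 0.0
    n_studies: int = 0


def fixed_effect_mvmeta(studies: list[StudyEstimate]) -> PooledEstimate:
    """Pool city-level estimates under the fixed-effect model."""
    if not studies:
        raise ValueError("at least one study is required")
    d = studies[0].beta.shape[0]
    for s in studies:
        if s.beta.shape[0] != d:
            raise ValueError(
                f"study {s.label!r} has dimension {s.beta.shape[0]}, "
                f"expected {d}"
            )
        if np.linalg.cond(s.vcov) > COND_LIMIT:
            raise ConditioningError(
                f"study {s.label!r} covariance is numerically singular "
                f"(condition number > {COND_LIMIT:g})"
            )

    precisions = {}
    w_sum = np.zeros((d, d))
    wb_sum = np.zeros(d)
    for s in studies:
        c = cho_factor(s.vcov)
        prec = cho_solve(c, np.eye(d))
        prec = 0.5 * (prec + prec.T)
        precisions[s.label] = prec
        w_sum += prec
        wb_sum += prec @ s.beta

    c_sum = cho_factor(w_sum)
    beta = cho_solve(c_sum, wb_sum)
    vcov = cho_solve(c_sum, np.eye(d))
    vcov = 0.5 * (vcov + vcov.T)
    weights = {lab: cho_solve(c_sum, p) for lab, p in precisions.items()}
    q = 0.0
    for s in studies:
        r = s.beta - beta
        q += float(r @ precisions[s.label] @ r)
    return PooledEstimate(
        beta_pooled=beta, vcov_pooled=vcov, weights=weights,
        q_statistic=max(q, 0.0), n_studies=len(studies),
    )
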