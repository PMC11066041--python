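"""Shared fixtures and independent oracle implementations.

The oracles here deliberately re-derive each quantity by a different route
than the package (truncated-power splines, brute-force double loops,
Newton-Raphson scoring, scalar inverse-variance formulas) so agreement is
evidence of correctness rather than repetition.
"""

import numpy as np
import pytest


def truncated_power_natural_basis(x, interior, lo, hi):
    """Natural cubic spline basis via the truncated-power representation.

    With knots xi_1 < ... < xi_K (boundary knots included), the natural
    spline space of dimension K (with intercept) is spanned by
    {1, x, N_1, ..., N_{K-2}} where N_k = d_k - d_{K-1} and
    d_k(x) = ((x - xi_k)_+^3 - (x - xi_K)_+^3) / (xi_K - xi_k).
    Returns the K-1 columns without the intercept.
    """
    x = np.asarray(x, dtype=float)
    knots = np.concatenate([[lo], np.asarray(interior, dtype=float), [hi]])

    def d(k):
        num = np.clip(x - knots[k], 0, None) ** 3 - np.clip(
            x - knots[-1], 0, None) ** 3
        return num / (knots[-1] - knots[k])

    cols = [x]
    K = len(knots)
    for k in range(K - 2):
        cols.append(d(k) - d(K - 2))
    return np.column_stack(cols)


def brute_force_cross_basis(exposure, R, C, L):
    """Naive double-sum cross-basis: entry (t, j*df_l + k) =
    sum_l R[t-l, j] * C[l, k], for t = L..n-1."""
    n, df_p = R.shape
    df_l = C.shape[1]
    out = np.zeros((n - L, df_p * df_l))
    for ti, t in enumerate(range(L, n)):
        for j in range(df_p):
            for k in range(df_l):
                out[ti, j * df_l + k] = sum(
                    R[t - l, j] * C[l, k] for l in range(L + 1)
                )
    return out


def newton_poisson(y, X, maxiter=200, tol=1e-12):
    """Independent Poisson ML fit by damped Newton-Raphson scoring.

    Returns (coefficients, se) with quasi-Poisson (Pearson-scaled)
    standard errors.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    beta = np.zeros(p)
    # start from the intercept solution if column 0 is constant
    if np.allclose(X[:, 0], X[0, 0]):
        beta[0] = np.log(y.mean() + 0.5) / X[0, 0]

    def loglik(b):
        eta = X @ b
        return float(y @ eta - np.exp(eta).sum())

    ll = loglik(beta)
    for _ in range(maxiter):
        mu = np.exp(X @ beta)
        grad = X.T @ (y - mu)
        hess = X.T @ (X * mu[:, None])
        step = np.linalg.solve(hess, grad)
        # halving keeps the concave objective increasing
        scale = 1.0
        while scale > 1e-8:
            cand = beta + scale * step
            if loglik(cand) >= ll - 1e-12:
                break
            scale /= 2.0
        beta = beta + scale * step
        new_ll = loglik(beta)
        if abs(new_ll - ll) < tol * (abs(ll) + 1.0):
            ll = new_ll
            break
        ll = new_ll
    mu = np.exp(X @ beta)
    pearson = float(np.sum((y - mu) ** 2 / mu))
    phi = pearson / (n - p)
    cov = phi * np.linalg.inv(X.T @ (X * mu[:, None]))
    return beta, np.sqrt(np.diag(cov))


def scalar_inverse_variance(betas, variances):
    """Classic univariate fixed-effect pooling."""
    w = 1.0 / np.asarray(variances, dtype=float)
    beta = float(np.sum(w * betas) / np.sum(w))
    var = float(1.0 / np.sum(w))
    q = float(np.sum(w * (np.asarray(betas) - beta) ** 2))
    return beta, var, q


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240502)


@pytest.fixture(scope="session")
def small_panel():
    """One simulated city, two years, default truth; reused across tests."""
    from dlnmkit import SimConfig, simulate_panel

    cfg = SimConfig(n_cities=1, start_date="2016-01-01",
                    end_date="2017-12-31", seed=11)
    panel, surface = simulate_panel(cfg)
    return panel, surface


@pytest.fixture(scope="session")
def small_fit(small_panel):
    """A frozen-spec quasi-Poisson DLNM fit on the small panel."""
    from dlnmkit import CandidateModel, fit_frozen

    panel, surface = small_panel
    cand = CandidateModel(covariate_mask=("tavg",), max_lag=10, df_p=4,
                          df_l=3)
    fit, cb = fit_frozen(panel, cand)
    return fit, cb, panel, surface
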