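"""Design-matrix building blocks for distributed lag non-linear models.

Three constructions live here:

* natural cubic spline bases with equally spaced interior knots
  (:func:`natural_cubic_basis`), the smooth used in both dimensions of the
  exposure-lag-response surface;
* Fourier harmonic pairs for within-year seasonality of daily counts
  (:func:`fourier_basis`);
* the cross-basis (:func:`build_cross_basis`): the bi-dimensional design
  matrix that represents an exposure's effect simultaneously along the
  concentration axis and along a window of lags 0..L, obtained by summing
  the tensor product of a predictor basis and a lag basis over the lag
  window.

Conventions
-----------
Bases carry no intercept column in the predictor dimension (the GLM
intercept absorbs the constant).  The lag basis *does* contain a constant
column, counted inside ``df_l``: an interceptless natural spline on the lag
axis would vanish identically at lag 0 and force the same-day effect to
zero, which is not a restriction the exposure-lag-response model intends.
Lag knots are equally spaced on the untransformed lag scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline


class SpecError(ValueError):
    """Invalid basis specification (df, period or harmonic count)."""


class RankError(ValueError):
    """Input data cannot support the requested basis dimension."""


@dataclass(frozen=True)
class SplineSpec:
    """Natural cubic spline specification.

    Parameters
    ----------
    df : int
        Number of basis columns.  Without an intercept this equals the
        number of interior knots plus one; ``df=1`` degenerates to a single
        linear column.
    intercept : bool
        If True, the first column is constant and counts toward ``df``.
    boundary : tuple of float, optional
        Boundary knots.  Defaults to the min/max of the data the basis is
        evaluated on; fixing them explicitly makes the basis reusable on new
        values (prediction grids).
    """

    df: int
    intercept: bool = False
    boundary: tuple[float, float] | None = None

    def __post_init__(self):
        if self.df < 1:
            raise SpecError(f"spline df must be >= 1, got {self.df}")
        if self.intercept and self.df < 1:
            raise SpecError("intercept basis needs df >= 1")

    def interior_knots(self, lo: float, hi: float) -> np.ndarray:
        """Equally spaced interior knots strictly inside (lo, hi)."""
        n_interior = self.df - 1 - (1 if self.intercept else 0)
        if n_interior <= 0:
            return np.empty(0)
        return lo + (hi - lo) * np.arange(1, n_interior + 1) / (n_interior + 1)


def _ns_design(x: np.ndarray, interior: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Natural cubic spline design matrix without intercept.

    Follows the classical construction: the cubic B-spline design on the
    augmented knot sequence is projected onto the null space of the
    second-derivative constraints at the two boundary knots (QR of the
    constraint matrix), after dropping the intercept column.  Values outside
    the boundary knots are extended linearly (first-order Taylor expansion
    at the nearest boundary), preserving the natural-spline property.
    """
    knots = np.concatenate([[lo] * 4, interior, [hi] * 4])
    n_b = len(knots) - 4
    eye = np.eye(n_b)
    splines = [BSpline(knots, eye[i], 3, extrapolate=False) for i in range(n_b)]

    def eval_all(pts, nu=0):
        out = np.empty((len(pts), n_b))
        for i, s in enumerate(splines):
            f = s if nu == 0 else s.derivative(nu)
            out[:, i] = f(pts)
        return np.nan_to_num(out)

    x = np.asarray(x, dtype=float)
    inside = np.clip(x, lo, hi)
    basis = eval_all(inside)
    below, above = x < lo, x > hi
    for mask, b in ((below, lo), (above, hi)):
        if mask.any():
            v = eval_all([b])[0]
            d = eval_all([b], nu=1)[0]
            basis[mask] = v + np.outer(x[mask] - b, d)

    # drop intercept column, then impose f''(lo) = f''(hi) = 0
    const = np.column_stack([
        np.array([s.derivative(2)(b) for s in splines]) for b in (lo, hi)
    ]).T[:, 1:]
    basis = basis[:, 1:]
    q, _ = np.linalg.qr(const.T, mode="complete")
    return basis @ q[:, 2:]


def natural_cubic_basis(values, spec: SplineSpec) -> np.ndarray:
    """Evaluate a natural cubic spline basis at ``values``.

    Returns an ``n x spec.df`` matrix.  Boundary knots come from
    ``spec.boundary`` or, failing that, the observed range of ``values``;
    interior knots are equally spaced between them.  The implied spline
    space is linear beyond the boundary knots.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise SpecError("values must be a 1-d vector")
    if not np.all(np.isfinite(x)):
        raise ValueError("values must be finite")
    if spec.boundary is not None:
        # fixed knots: evaluation at arbitrary points (e.g. a prediction
        # grid of any size) is legitimate
        lo, hi = spec.boundary
    else:
        lo, hi = float(x.min()), float(x.max())
        n_distinct = len(np.unique(x))
        if n_distinct < spec.df + 1:
            raise RankError(
                f"need at least df+1={spec.df + 1} distinct values, "
                f"got {n_distinct}"
            )
    if hi <= lo:
        raise RankError("degenerate boundary knots (constant values)")

    df_spline = spec.df - (1 if spec.intercept else 0)
    cols = []
    if spec.intercept:
        cols.append(np.ones((len(x), 1)))
    if df_spline >= 1:
        interior = spec.interior_knots(lo, hi)
        cols.append(_ns_design(x, interior, lo, hi))
    out = np.hstack(cols)
    assert out.shape == (len(x), spec.df)
    return out


@dataclass(frozen=True)
class SeasonalBasis:
    """Fourier seasonal design: columns sin/cos per harmonic."""

    matrix: np.ndarray
    period: float
    harmonics: int

    @property
    def n_columns(self) -> int:
        return 2 * self.harmonics


def fourier_basis(day_index, m: float, K: int) -> SeasonalBasis:
    """Fourier seasonal terms for daily data.

    Column order is ``sin(2*pi*k*t/m), cos(2*pi*k*t/m)`` for k = 1..K, so
    day 0 maps to (0, 1) in every harmonic pair.  The default analysis uses
    the first six harmonics of an annual period (m = 365).
    """
    if m <= 0:
        raise SpecError(f"period m must be positive, got {m}")
    if K < 1:
        raise SpecError(f"need at least one harmonic, got K={K}")
    t = np.asarray(day_index, dtype=float)
    cols = np.empty((len(t), 2 * K))
    for k in range(1, K + 1):
        ang = 2.0 * np.pi * k * t / m
        cols[:, 2 * (k - 1)] = np.sin(ang)
        cols[:, 2 * (k - 1) + 1] = np.cos(ang)
    return SeasonalBasis(matrix=cols, period=float(m), harmonics=K)


@dataclass(frozen=True)
class CrossBasisSpec:
    """Hyperparameters of the bi-dimensional exposure-lag basis.

    ``max_lag`` is the furthest lag L (inclusive window 0..L), ``df_p`` the
    predictor-space degrees of freedom, ``df_l`` the lag-dimension degrees
    of freedom (intercept column included in the count).
    """

    max_lag: int
    df_p: int
    df_l: int

    def __post_init__(self):
        if self.max_lag < 0:
            raise SpecError(f"max_lag must be >= 0, got {self.max_lag}")
        if self.df_p < 1:
            raise SpecError(f"df_p must be >= 1, got {self.df_p}")
        if self.df_l < 1:
            raise SpecError(f"df_l must be >= 1, got {self.df_l}")
        if self.max_lag == 0 and self.df_l != 1:
            raise SpecError("max_lag=0 requires df_l=1 (constant lag basis)")

    @property
    def n_columns(self) -> int:
        return self.df_p * self.df_l

    def predictor_spec(self, boundary=None) -> SplineSpec:
        return SplineSpec(df=self.df_p, intercept=False, boundary=boundary)

    def lag_spec(self) -> SplineSpec:
        return SplineSpec(
            df=self.df_l, intercept=True, boundary=(0.0, float(self.max_lag))
        )


@dataclass(frozen=True)
class CrossBasis:
    """A realized cross-basis: matrix plus everything needed to reduce it.

    ``matrix`` has one row per usable day (days with a complete lag window,
    i.e. t >= L, 0-based) and ``df_p * df_l`` columns ordered with the
    predictor index outermost: column ``j*df_l + k`` pairs predictor basis
    function j with lag basis function k.
    """

    matrix: np.ndarray
    spec: CrossBasisSpec
    exposure_range: tuple[float, float]
    usable_index: np.ndarray = field(repr=False)

    def predictor_basis(self, x) -> np.ndarray:
        """Predictor basis at new exposure values, with the fitted knots."""
        return natural_cubic_basis(
            np.atleast_1d(np.asarray(x, dtype=float)),
            self.spec.predictor_spec(boundary=self.exposure_range),
        )

    def lag_basis(self) -> np.ndarray:
        """Lag basis evaluated on the integer grid 0..L ((L+1) x df_l)."""
        lags = np.arange(self.spec.max_lag + 1, dtype=float)
        if self.spec.max_lag == 0:
            return np.ones((1, 1))
        return natural_cubic_basis(lags, self.spec.lag_spec())


def build_cross_basis(exposure, spec: CrossBasisSpec) -> CrossBasis:
    """Build the exposure-lag cross-basis for a daily exposure series.

    Row t (for usable days t >= L) of the result is
    ``sum_{l=0..L} R(x[t-l]) (x) C(l)`` where R is the predictor natural
    spline (boundary knots at the observed range of the full series) and C
    the lag basis on 0..L.  Days 0..L-1 lack a full lag window and are
    dropped; callers align the response accordingly.
    """
    x = np.asarray(exposure, dtype=float)
    if x.ndim != 1:
        raise SpecError("exposure must be a 1-d series")
    if not np.all(np.isfinite(x)):
        raise ValueError("exposure must be finite")
    L = spec.max_lag
    if len(x) < L + 1:
        raise ValueError(
            f"exposure series of length {len(x)} shorter than max_lag+1={L + 1}"
        )
    lo, hi = float(x.min()), float(x.max())
    if hi <= lo:
        # constant series: the construction stays defined (rows identical)
        # even though a fit on it would be singular
        lo, hi = lo - 0.5, hi + 0.5
    rmat = natural_cubic_basis(x, spec.predictor_spec(boundary=(lo, hi)))
    if L == 0:
        cmat = np.ones((1, 1))
    else:
        cmat = natural_cubic_basis(
            np.arange(L + 1, dtype=float), spec.lag_spec()
        )
    n = len(x)
    usable = np.arange(L, n)
    # lagged[t, l, :] = R(x[t-l]) for usable t
    lagged = np.empty((len(usable), L + 1, spec.df_p))
    for l in range(L + 1):
        lagged[:, l, :] = rmat[usable - l]
    mat = np.einsum("tlj,lk->tjk", lagged, cmat).reshape(len(usable), -1)
    return CrossBasis(
        matrix=mat, spec=spec, exposure_range=(lo, hi), usable_index=usable
    )
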