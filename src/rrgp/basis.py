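"""Legendre polynomial basis for random regression on standardized time.

Random regression models express trait trajectories as regressions on a small
set of orthogonal polynomials of time. Time points (days of imaging) are mapped
linearly onto [-1, 1] and the basis columns are normalized Legendre polynomials

    phi_k(x) = sqrt(2) * sqrt((2k+1)/2) * P_k(x) = sqrt(2k+1) * P_k(x),

so that the intercept column phi_0 is identically 1. The basis matrix satisfies
``Phi = M @ Lambda`` where ``M`` holds monomials of standardized time and
``Lambda`` the (scaled) Legendre coefficients; both construction paths are kept
so they can be cross-checked.

All variance components estimated on this basis are convention dependent: with
a different scaling of the columns the coefficient covariance matrices change
conformably while day-level quantities (genetic variance at day t, genomic
correlation, heritability) are invariant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial import legendre as npleg

__all__ = ["TimeGrid", "BasisMatrix", "standardize_time", "legendre_basis"]


@dataclass(frozen=True)
class TimeGrid:
    """Ordered integer measurement days plus the standardization bounds.

    ``t_min``/``t_max`` default to the observed range. They are kept separate
    from ``days`` because forecasting evaluates the basis at days outside the
    training range while keeping the standardization of the full design: a
    model trained on days 1-10 of a 20-day experiment still standardizes time
    over (1, 20) so that extrapolated rows live on the same polynomial.
    """

    days: tuple[int, ...]
    t_min: float = field(default=None)  # type: ignore[assignment]
    t_max: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        days = tuple(self.days)
        if len(days) == 0:
            raise ValueError("TimeGrid needs at least one day")
        if any(b <= a for a, b in zip(days, days[1:])):
            raise ValueError("days must be strictly increasing")
        object.__setattr__(self, "days", days)
        t_min = min(days) if self.t_min is None else float(self.t_min)
        t_max = max(days) if self.t_max is None else float(self.t_max)
        if t_min > min(days) or t_max < max(days):
            raise ValueError("standardization bounds must cover the days")
        if not t_min < t_max:
            raise ValueError("t_min must be strictly below t_max")
        object.__setattr__(self, "t_min", t_min)
        object.__setattr__(self, "t_max", t_max)

    @property
    def n_days(self) -> int:
        return len(self.days)


def standardize_time(t, t_min: float, t_max: float):
    """Map time ``t`` linearly onto [-1, 1]: x = -1 + 2 (t - t_min)/(t_max - t_min).

    Values outside ``[t_min, t_max]`` are allowed (extrapolation when
    forecasting beyond the training window) and map outside [-1, 1].
    """
    if not t_min < t_max:
        raise ValueError("t_min must be strictly below t_max")
    t = np.asarray(t, dtype=float)
    x = -1.0 + 2.0 * (t - t_min) / (t_max - t_min)
    return x if x.ndim else float(x)


def _lambda_matrix(order: int) -> np.ndarray:
    """Monomial coefficients of the scaled normalized Legendre polynomials.

    Column k holds the coefficients of sqrt(2k+1) * P_k(x) on 1, x, x^2, ...;
    column 0 is the constant 1.
    """
    lam = np.zeros((order + 1, order + 1))
    for k in range(order + 1):
        ck = np.zeros(k + 1)
        ck[k] = 1.0
        poly = npleg.leg2poly(ck) * np.sqrt(2.0 * k + 1.0)
        lam[: k + 1, k] = poly
    return lam


@dataclass(frozen=True)
class BasisMatrix:
    """Legendre basis Phi = M @ Lambda evaluated on a time grid."""

    grid: TimeGrid
    order: int
    phi: np.ndarray      # n_days x (order+1)
    M: np.ndarray        # n_days x (order+1) monomials of standardized time
    Lambda: np.ndarray   # (order+1) x (order+1)

    @property
    def n_coef(self) -> int:
        return self.order + 1

    def standardize(self, t):
        return standardize_time(t, self.grid.t_min, self.grid.t_max)

    def row(self, day) -> np.ndarray:
        """Basis row phi(t) at an arbitrary day (grid membership not required)."""
        return self.evaluate([day])[0]

    def evaluate(self, days) -> np.ndarray:
        """Evaluate the basis at arbitrary days through the recurrence path."""
        x = np.atleast_1d(np.asarray(self.standardize(days), dtype=float))
        return _eval_normalized(x, self.order)

    def subset(self, days) -> "BasisMatrix":
        """Basis on a sub- or super-set of days, same standardization bounds."""
        grid = TimeGrid(tuple(int(d) for d in days),
                        t_min=min(self.grid.t_min, float(min(days))),
                        t_max=max(self.grid.t_max, float(max(days))))
        # keep the original bounds when they already cover the new days
        if float(min(days)) >= self.grid.t_min and float(max(days)) <= self.grid.t_max:
            grid = TimeGrid(tuple(int(d) for d in days), self.grid.t_min, self.grid.t_max)
        return legendre_basis(grid, self.order)

    def day_index(self) -> dict:
        return {d: i for i, d in enumerate(self.grid.days)}


def _eval_normalized(x: np.ndarray, order: int) -> np.ndarray:
    """phi_k(x) = sqrt(2k+1) P_k(x) via the three-term recurrence."""
    n = x.shape[0]
    P = np.empty((n, order + 1))
    P[:, 0] = 1.0
    if order >= 1:
        P[:, 1] = x
    for k in range(1, order):
        P[:, k + 1] = ((2 * k + 1) * x * P[:, k] - k * P[:, k - 1]) / (k + 1)
    scale = np.sqrt(2.0 * np.arange(order + 1) + 1.0)
    return P * scale


def legendre_basis(grid: TimeGrid, order: int = 2) -> BasisMatrix:
    """Build the basis matrix Phi on ``grid`` with polynomial degree ``order``.

    Phi is assembled as M @ Lambda (monomials times Legendre coefficients) and
    the result agrees to machine precision with direct evaluation of the
    normalized polynomials through the recurrence.
    """
    if order < 0:
        raise ValueError("order must be >= 0")
    x = np.asarray([standardize_time(d, grid.t_min, grid.t_max) for d in grid.days])
    M = np.vander(x, order + 1, increasing=True)
    Lambda = _lambda_matrix(order)
    phi = M @ Lambda
    return BasisMatrix(grid=grid, order=order, phi=phi, M=M, Lambda=Lambda)
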