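"""Bivariate polynomial surrogate of the numerically solved t_g surface.

Solving the transcendental crossing equation takes an iterative root search
per step — cheap on a workstation, expensive on embedded sports-watch
hardware.  The solved surface t_g(t_ce, t_fe) is smooth and increasing in
both arguments, so it is approximated by a full bivariate polynomial
``P_n(t_ce, t_fe) = sum_{i+j<=n} alpha_ij t_ce^i t_fe^j`` fitted by ordinary
least squares on the solvable grid points.  An order scan (1..15) picks the
smallest order whose held-out RMSE beats a target threshold (0.5 ms by
default, which bounds the error on the reconstructed contact time by 1 ms,
since t_c = t_ce + 2 t_g doubles any t_g error).

All regression is done with times in SECONDS.  Monomials of order up to 15
in milliseconds (values up to 505) would span ~40 orders of magnitude and
wreck the conditioning; in seconds all features stay below 1.  The design
matrix is still ill-conditioned at high order, so the normal equations are
avoided in favour of a pivoted-QR least-squares solve.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.preprocessing import PolynomialFeatures
from sklearn.utils.validation import check_is_fitted, validate_data

from ._split import DEFAULT_SEED, DEFAULT_TRAIN_FRACTION, split_indices
from .model import TimingPair, boundary_ratio_analytic
from .solver import GridSolution, GridSpec, solve_grid

__all__ = [
    "PolynomialSurrogate",
    "OrderScan",
    "OperationCount",
    "FeasibilityError",
    "ExtrapolationWarning",
    "SurrogateFitError",
    "polynomial_features",
    "fit_surrogate",
    "order_scan",
    "predict_tg",
    "operation_count",
    "grid_sensitivity",
]


class FeasibilityError(ValueError):
    """Prediction requested below the feasibility boundary, where t_g is undefined."""


class SurrogateFitError(RuntimeError):
    """Least-squares fit failed (e.g., rank deficiency)."""


class ExtrapolationWarning(UserWarning):
    """Prediction outside the training envelope of the surrogate."""


def n_terms(order: int) -> int:
    """Number of monomials t_ce^i t_fe^j with i + j <= order: C(order+2, 2)."""
    if order < 1:
        raise ValueError(f"order must be >= 1, got {order!r}")
    return math.comb(order + 2, 2)


def polynomial_features(X, order: int) -> tuple[np.ndarray, np.ndarray]:
    """Monomial design matrix and exponent table for the bivariate basis.

    Term order is graded lexicographic with t_ce before t_fe:
    1, t_ce, t_fe, t_ce^2, t_ce*t_fe, t_fe^2, ...  Returns ``(A, powers)``
    where ``A`` is (n_samples, C(order+2, 2)) and ``powers[k] = (i, j)``.
    """
    if order < 1:
        raise ValueError(f"order must be >= 1, got {order!r}")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != 2:
        raise ValueError("expected two columns (t_ce, t_fe)")
    pf = PolynomialFeatures(degree=order)
    A = pf.fit_transform(X)
    return A, pf.powers_


class PolynomialSurrogate(RegressorMixin, BaseEstimator):
    """scikit-learn regressor for the polynomial t_g surrogate.

    Parameters
    ----------
    order : int, default 8
        Total polynomial degree; the basis has C(order+2, 2) monomials.

    Attributes
    ----------
    coef_ : ndarray of shape (C(order+2, 2),)
        Coefficients alpha_ij in graded-lexicographic term order.
    powers_ : ndarray of shape (n_terms, 2)
        Exponents (i, j) of each term.
    envelope_ : tuple or None
        ((t_ce_min, t_ce_max), (t_fe_min, t_fe_max)) of the training data;
        predictions outside it raise :class:`ExtrapolationWarning`.

    Times are in seconds throughout.
    """

    def __init__(self, order: int = 8):
        self.order = order

    def fit(self, X, y):
        X, y = validate_data(self, X, y, ensure_min_samples=2)
        if X.shape[1] != 2:
            raise ValueError("expected two feature columns (t_ce, t_fe)")
        A, powers = polynomial_features(X, self.order)
        if A.shape[0] < A.shape[1]:
            raise SurrogateFitError(
                f"order {self.order} needs >= {A.shape[1]} points, got {A.shape[0]}"
            )
        # pivoted QR (LAPACK gelsy): stable on the ill-conditioned monomial basis
        coef, _, rank, _ = scipy.linalg.lstsq(A, y, lapack_driver="gelsy")
        self.rank_ = int(rank)
        if rank < A.shape[1]:
            # distinguish structural deficiency (too few distinct points) from
            # the near-collinearity inherent to high-order monomials, which the
            # pivoted QR handles by truncation
            n_unique = len(np.unique(X, axis=0))
            if n_unique < A.shape[1]:
                raise SurrogateFitError(
                    f"rank-deficient design matrix at order {self.order}: "
                    f"{n_unique} distinct points < {A.shape[1]} terms"
                )
        if not np.all(np.isfinite(coef)):
            raise SurrogateFitError(
                f"least-squares solve produced non-finite coefficients at order "
                f"{self.order} ({A.shape[0]} points)"
            )
        self.coef_ = coef
        self.powers_ = powers
        self.envelope_ = (
            (float(X[:, 0].min()), float(X[:, 0].max())),
            (float(X[:, 1].min()), float(X[:, 1].max())),
        )
        return self

    def predict(self, X, *, check_feasible: bool = True):
        check_is_fitted(self)
        X = validate_data(self, X, reset=False)
        if check_feasible:
            ratio = boundary_ratio_analytic()
            if np.any(X[:, 1] < ratio * X[:, 0]):
                raise FeasibilityError(
                    "t_fe below the feasibility boundary (~0.784*t_ce); "
                    "t_g is undefined there and the surrogate does not apply"
                )
            (ce_lo, ce_hi), (fe_lo, fe_hi) = self.envelope_
            if np.any(
                (X[:, 0] < ce_lo) | (X[:, 0] > ce_hi) | (X[:, 1] < fe_lo) | (X[:, 1] > fe_hi)
            ):
                warnings.warn(
                    "prediction outside the surrogate's training envelope",
                    ExtrapolationWarning,
                    stacklevel=2,
                )
        A, _ = polynomial_features(X, self.order)
        return A @ self.coef_


def fit_surrogate(
    grid: GridSolution,
    order: int = 8,
    train_fraction: float = DEFAULT_TRAIN_FRACTION,
    seed: int = DEFAULT_SEED,
) -> PolynomialSurrogate:
    """Fit a surrogate on a random split of the grid's solved points.

    Held-out metrics and split metadata are attached to the estimator as
    ``rmse_test_`` (seconds), ``r_squared_test_``, ``seed_``,
    ``train_fraction_`` and ``grid_spec_``.
    """
    X, y = grid.solved_points()
    if len(y) == 0:
        raise SurrogateFitError("grid has no solved points")
    train, test = split_indices(len(y), train_fraction, seed)
    model = PolynomialSurrogate(order=order).fit(X[train], y[train])
    pred = model.predict(X[test], check_feasible=False)
    resid = y[test] - pred
    model.rmse_test_ = float(np.sqrt(np.mean(resid**2)))
    ss_tot = float(np.sum((y[test] - y[test].mean()) ** 2))
    model.r_squared_test_ = 1.0 - float(resid @ resid) / ss_tot
    model.seed_ = seed
    model.train_fraction_ = train_fraction
    model.grid_spec_ = grid.spec
    return model


@dataclass
class OrderScan:
    """Held-out RMSE/R^2 per polynomial order and the selected order."""

    orders: list[int]
    rmse: list[float]  # seconds
    r_squared: list[float]
    threshold: float  # seconds
    selected_order: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "order": self.orders,
                "rmse_ms": [r * 1e3 for r in self.rmse],
                "r_squared": self.r_squared,
            }
        )


def order_scan(
    grid: GridSolution,
    orders=range(1, 16),
    threshold: float = 0.0005,
    train_fraction: float = DEFAULT_TRAIN_FRACTION,
    seed: int = DEFAULT_SEED,
) -> OrderScan:
    """Scan polynomial orders on one shared random split; select the smallest
    order whose held-out RMSE falls below ``threshold`` (seconds)."""
    orders = list(orders)
    if not orders:
        raise ValueError("orders must be non-empty")
    rmses, r2s = [], []
    for n in orders:
        m = fit_surrogate(grid, order=n, train_fraction=train_fraction, seed=seed)
        rmses.append(m.rmse_test_)
        r2s.append(m.r_squared_test_)
    passing = [n for n, r in zip(orders, rmses) if r < threshold]
    if not passing:
        raise SurrogateFitError(
            f"no order in {orders} reaches RMSE < {threshold*1e3:.3g} ms; "
            f"best achieved {min(rmses)*1e3:.3g} ms"
        )
    return OrderScan(
        orders=orders,
        rmse=rmses,
        r_squared=r2s,
        threshold=threshold,
        selected_order=min(passing),
    )


def predict_tg(model: PolynomialSurrogate, pair: TimingPair) -> float:
    """Evaluate the surrogate at one timing pair (seconds in, seconds out)."""
    return float(model.predict(np.array([[pair.t_ce, pair.t_fe]]))[0])


@dataclass(frozen=True)
class OperationCount:
    """Arithmetic cost of one surrogate evaluation at a given order."""

    order: int
    features: int
    multiplications: int
    additions: int

    @property
    def total(self) -> int:
        return self.features + self.multiplications + self.additions


def operation_count(order: int) -> OperationCount:
    """Operations to evaluate P_n once, with C = C(n+2, 2) terms.

    Building the monomials incrementally costs C - 3 multiplications (the
    terms 1, t_ce, t_fe are free), then the dot product with the
    coefficients costs C - 1 multiplications and C - 1 additions:
    3C - 5 in total (130 at order 8, 25 at order 3).
    """
    c = n_terms(order)
    return OperationCount(
        order=order, features=c - 3, multiplications=c - 1, additions=c - 1
    )


def grid_sensitivity(
    axis_sizes,
    orders=range(1, 16),
    threshold: float = 0.0005,
    train_fraction: float = DEFAULT_TRAIN_FRACTION,
    seed: int = DEFAULT_SEED,
    start: float = 0.0025,
    stop: float = 0.505,
) -> pd.DataFrame:
    """Held-out RMSE by grid size and polynomial order.

    For each axis size m, a square m x m grid over the default limits is
    re-solved and the order scan refitted.  Returns a long DataFrame with
    columns n_points, axis_size, order, rmse_ms.  Orders whose basis exceeds
    the available training points are skipped.
    """
    rows = []
    for m in axis_sizes:
        if m < 2:
            raise ValueError("axis size must be >= 2")
        spacing = (stop - start) / (m - 1)
        grid = solve_grid(GridSpec(start=start, stop=stop, spacing=spacing))
        X, y = grid.solved_points()
        n_train = int(round(train_fraction * len(y)))
        for n in orders:
            if n_terms(n) > n_train:
                continue
            model = fit_surrogate(grid, order=n, train_fraction=train_fraction, seed=seed)
            rows.append(
                {
                    "n_points": grid.n_total,
                    "axis_size": m,
                    "order": n,
                    "rmse_ms": model.rmse_test_ * 1e3,
                }
            )
    return pd.DataFrame(rows)
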